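import numpy as np
import pytest

import sulfassim as sa

FIG3E_YLL058W = sa.KineticParams("Yll058w", 1.62, 4.29)
FIG3E_MET15 = sa.KineticParams("Met15", 89.21, 8.03)
OAH_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 15.0)

THREE_CLASSES = (
    sa.HomologClass("yll058w_like", 0.05, 0.03),
    sa.HomologClass("str2_like", 0.35, 0.03),
    sa.HomologClass("outgroup", 0.60, 0.03),
)


@pytest.fixture
def default_layout():
    return sa.generate_plate_layout(["FY4", "met15D"], 16, 24, "interleaved")


@pytest.fixture
def growth_params():
    return {
        "FY4": sa.StrainGrowthParams("FY4", 1000.0, 0.25, noise_cv=0.0),
        "met15D": sa.StrainGrowthParams("met15D", 500.0, 0.25, noise_cv=0.0),
    }


@pytest.fixture
def toy_panel():
    """Six toy genomes with planted homolog classes and their ground truth."""
    return sa.generate_toy_genomes(6, THREE_CLASSES, seed=7)


def brute_force_orfs(seq: str, min_len: int = 300):
    """Independent ORF oracle: walk stop codons per frame/strand and take the
    first ATG after the previous stop; filter on strict length."""
    from Bio.Seq import Seq

    stops = {"TAA", "TAG", "TGA"}
    found = set()
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        L = len(s)
        for frame in range(3):
            codon_starts = list(range(frame, L - 2, 3))
            stop_positions = [i for i in codon_starts
                              if s[i:i + 3] in stops and "N" not in s[i:i + 3]]
            prev = frame - 3
            for sp in stop_positions:
                atg = next((i for i in range(prev + 3, sp, 3) if s[i:i + 3] == "ATG"), None)
                if atg is not None and sp - atg > min_len:
                    if strand == "+":
                        found.add((atg + 1, sp, "+"))
                    else:
                        found.add((L - sp + 1, L - atg, "-"))
                prev = sp
    return found


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
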