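"""Synthetic inputs with known ground truth.

Three generators cover the package's input space: 384-position colony grids
growing logistically (with a border growth advantage and multiplicative
lognormal noise), Michaelis-Menten rate assays with additive Gaussian noise,
and toy genomes carrying planted homolog families in a near-end gene cluster.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import COLONY_COLUMNS

# ---------------------------------------------------------------------------
# Plate layout and colony growth


@dataclasses.dataclass(frozen=True)
class PlateLayout:
    """Who grows where on an n_rows x n_cols grid (positions 1-based)."""

    n_rows: int
    n_cols: int
    assignment: Mapping[tuple[int, int], tuple[str, int]]  # (row, col) -> (strain, replicate)
    border_mask: frozenset[tuple[int, int]]

    def positions(self) -> list[tuple[int, int]]:
        return sorted(self.assignment)

    def interior_positions(self) -> list[tuple[int, int]]:
        return [p for p in self.positions() if p not in self.border_mask]


@dataclasses.dataclass
class StrainGrowthParams:
    """Ground-truth logistic growth parameters for one strain.

    ``r = 0`` encodes a non-grower (auxotroph-like); ``border_boost``
    multiplies the carrying capacity at border positions, mimicking the
    nutrient-access advantage of edge colonies.
    """

    strain: str
    carrying_capacity: float  # K, px
    growth_rate: float  # r, per hour
    initial_size: float = 5.0  # N0, px
    border_boost: float = 1.3
    noise_cv: float = 0.0

    def __post_init__(self):
        if not (self.carrying_capacity > self.initial_size > 0):
            raise ValueError(f"require K > N0 > 0 for strain {self.strain}")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.border_boost < 1:
            raise ValueError("border_boost must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_plate_layout(
    strains: Sequence[str],
    n_rows: int = 16,
    n_cols: int = 24,
    scheme: str = "interleaved",
) -> PlateLayout:
    """Deterministic layout with four biological replicates per strain.

    ``interleaved`` places replicate ``2*(row % 2) + (col % 2) + 1`` (0-based
    row/col parity), the maximally uniform 2x2 spatial interleave; each
    replicate then covers exactly one quarter of the plate. ``quadrant``
    assigns contiguous quarters instead. Strains cycle row-major across
    positions.
    """
    if scheme not in ("interleaved", "quadrant"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "interleaved" and (n_rows % 2 or n_cols % 2):
        raise ValueError("interleaved scheme requires even n_rows and n_cols")
    if scheme == "quadrant" and (n_rows % 2 or n_cols % 2):
        raise ValueError("quadrant scheme requires even n_rows and n_cols")
    if not strains:
        raise ValueError("need at least one strain")

    assignment = {}
    for i, (row, col) in enumerate(
        (r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)
    ):
        strain = strains[i % len(strains)]
        if scheme == "interleaved":
            rep = 2 * ((row - 1) % 2) + ((col - 1) % 2) + 1
        else:
            rep = 2 * ((row - 1) // (n_rows // 2)) + ((col - 1) // (n_cols // 2)) + 1
        assignment[(row, col)] = (strain, rep)

    border = frozenset(
        (r, c)
        for r in range(1, n_rows + 1)
        for c in range(1, n_cols + 1)
        if r in (1, n_rows) or c in (1, n_cols)
    )
    return PlateLayout(n_rows, n_cols, assignment, border)


def logistic_size(t, K: float, r: float, N0: float):
    """size(t) = K / (1 + ((K - N0)/N0) * exp(-r t))"""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def simulate_colony_growth(
    layout: PlateLayout,
    params: Mapping[str, StrainGrowthParams],
    timepoints: Sequence[float],
    seed: int,
    plate: str = "plate1",
) -> pd.DataFrame:
    """Simulate colony sizes over time for every position on the plate.

    Border positions grow toward ``K * border_boost``; interior positions
    toward ``K``. Observation noise is multiplicative lognormal with the
    strain's coefficient of variation (unit mean, so noise-free expectations
    match the logistic closed form). Identical seeds reproduce identical
    tables bit-for-bit.
    """
    tp = np.asarray(timepoints, dtype=float)
    if np.any(tp < 0):
        raise ValueError("timepoints must be non-negative")
    if np.any(np.diff(tp) < 0):
        raise ValueError("timepoints must be sorted")
    for (row, col), (strain, _) in layout.assignment.items():
        if strain not in params:
            raise KeyError(f"no growth parameters for strain {strain!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for (row, col) in layout.positions():
        strain, rep = layout.assignment[(row, col)]
        p = params[strain]
        boost = p.border_boost if (row, col) in layout.border_mask else 1.0
        K = p.carrying_capacity * boost
        size = logistic_size(tp, K, p.growth_rate, p.initial_size)
        if p.noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + p.noise_cv**2))
            size = size * rng.lognormal(-0.5 * sigma**2, sigma, size=tp.shape)
        for t, s in zip(tp, size):
            rows.append((plate, row, col, strain, rep, t, s))
    return pd.DataFrame(rows, columns=COLONY_COLUMNS)


# ---------------------------------------------------------------------------
# Enzyme assay

DEFAULT_OAH_GRID_MM = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 15.0)  # spans 0-15 mM


def simulate_mm_assay(
    params,
    substrate_concs: Sequence[float] = DEFAULT_OAH_GRID_MM,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Michaelis-Menten rates with additive Gaussian noise.

    ``params`` is a :class:`sulfassim.kinetics.KineticParams`. Returns a frame
    with columns S_mM, rate, replicate.
    """
    S = np.asarray(substrate_concs, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentrations must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        v = params.vmax * S / (params.km + S)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=S.shape)
        rows.extend(zip(S, v, [rep] * len(S)))
    return pd.DataFrame(rows, columns=["S_mM", "rate", "replicate"])


# ---------------------------------------------------------------------------
# Toy genomes with planted homolog families

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass(frozen=True)
class HomologClass:
    """A divergence class of one homolog family.

    ``divergence`` is the per-codon substitution probability separating the
    class ancestor from the family root; ``within_divergence`` the additional
    per-taxon substitution probability around the class ancestor.
    """

    name: str
    divergence: float
    within_divergence: float = 0.0

    def __post_init__(self):
        for d in (self.divergence, self.within_divergence):
            if not (0.0 <= d < 1.0):
                raise ValueError("divergence must lie in [0, 1)")


def _random_orf_codons(rng, n_codons: int) -> list[str]:
    codons = ["ATG"]
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 1)
    codons += [_NON_STOP_CODONS[i] for i in idx]
    return codons


def _mutate_codons(rng, codons: list[str], divergence: float) -> list[str]:
    out = [codons[0]]  # ATG start never mutated
    for cod in codons[1:]:
        if rng.random() < divergence:
            new = cod
            while new == cod:
                new = _NON_STOP_CODONS[rng.integers(0, len(_NON_STOP_CODONS))]
            out.append(new)
        else:
            out.append(cod)
    return out


_CODON_TABLE = {}


def translate_codons(codons: Iterable[str]) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for cod in _NON_STOP_CODONS:
            _CODON_TABLE[cod] = str(Seq(cod).translate())
    return "".join(_CODON_TABLE[c] for c in codons)


def _random_dna(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def generate_toy_genomes(
    n_taxa: int,
    classes: Sequence[HomologClass],
    seed: int,
    n_codons: int = 120,
    n_sulfur_decoys: int = 3,
    n_far_decoys: int = 4,
    spacer_len: int = 80,
    flank_len: int = 400,
):
    """Build ``n_taxa`` toy genomes carrying planted homolog families.

    Each genome carries, near one sequence end (a stand-in for a telomere),
    a gene cluster holding one member of every divergence class plus
    ``n_sulfur_decoys`` shared sulfur-related genes; ``n_far_decoys``
    unrelated decoy ORFs sit far from the cluster. Planted ORFs exceed 300 bp
    (``n_codons`` codons incl. ATG, stop excluded from the span) and are
    framed by an in-frame upstream stop so an exact ORF scan recovers them.

    Returns ``(genomes, truth, references)``: genomes as id->sequence,
    a truth table (one row per planted ORF, 1-based forward coordinates),
    and reference proteins (family root, per-class ancestors, decoys).
    """
    if len(classes) < 1:
        raise ValueError("need at least one homolog class")
    if n_codons * 3 <= 300:
        raise ValueError("planted ORFs must exceed 300 bp")
    rng = np.random.default_rng(seed)

    root = _random_orf_codons(rng, n_codons)
    ancestors = {c.name: _mutate_codons(rng, root, c.divergence) for c in classes}
    sulfur_refs = {
        f"sulfur_decoy_{i+1}": _random_orf_codons(rng, n_codons)
        for i in range(n_sulfur_decoys)
    }
    far_refs = {
        f"decoy_{i+1}": _random_orf_codons(rng, n_codons) for i in range(n_far_decoys)
    }

    references = {"family_root": translate_codons(root)}
    for name, cod in {**ancestors, **sulfur_refs, **far_refs}.items():
        references[name] = translate_codons(cod)

    genomes: dict[str, str] = {}
    truth_rows = []
    for taxon in range(1, n_taxa + 1):
        gid = f"taxon{taxon:02d}"
        parts = [_random_dna(rng, flank_len)]
        pos = flank_len  # 0-based length so far

        def plant(codons, family, cls, strand):
            nonlocal pos
            orf_nt = "".join(codons)
            stop = _STOPS[rng.integers(0, 3)]
            cassette = "TAA" + orf_nt + stop  # in-frame stop pins the ORF start
            if strand == "-":
                cassette = _revcomp(cassette)
            parts.append(cassette)
            start = pos + 3 + 1  # 1-based, forward strand
            end = pos + 3 + len(orf_nt)
            pos += len(cassette)
            truth_rows.append(
                {
                    "genome": gid,
                    "family": family,
                    "class": cls,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "length": len(orf_nt),
                    "protein": translate_codons(codons),
                }
            )
            spacer = _random_dna(rng, spacer_len)
            parts.append(spacer)
            pos += spacer_len

        # near-end cluster: family members interleaved with sulfur genes
        strand_cycle = ["+", "-"]
        for i, c in enumerate(classes):
            member = _mutate_codons(rng, ancestors[c.name], c.within_divergence)
            plant(member, c.name, c.name, strand_cycle[i % 2])
        for i, (name, cod) in enumerate(sulfur_refs.items()):
            plant(cod, name, "sulfur", strand_cycle[(i + 1) % 2])

        # long neutral stretch, then far decoys mid/far from the cluster end
        middle = _random_dna(rng, 6000)
        parts.append(middle)
        pos += len(middle)
        for i, (name, cod) in enumerate(far_refs.items()):
            plant(cod, name, "decoy", strand_cycle[i % 2])
        parts.append(_random_dna(rng, flank_len))
        genomes[gid] = "".join(parts)

    truth = pd.DataFrame(truth_rows)
    return genomes, truth, references
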