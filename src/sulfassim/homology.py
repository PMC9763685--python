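"""Homolog discovery and clustering: ORF scan, pairwise alignment with
Karlin-Altschul e-values, best-hit family assignment with gene-neighborhood
profiles, sulfur-cluster detection, identity distances, classical MDS, and
K-means.

BLASTP-style search is realised as Smith-Waterman local alignment under
BLOSUM62 with affine gaps 11/1 so the pipeline needs no external binary;
precomputed tabular hits can be supplied instead.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from sklearn.cluster import KMeans

# gapped BLOSUM62 (11/1) Karlin-Altschul parameters
_KA_LAMBDA = 0.267
_KA_K = 0.041

_DNA_OK = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF; coordinates are 1-based inclusive on the forward
    strand, length excludes the stop codon."""

    genome: str
    start: int
    end: int
    strand: str
    length: int
    protein: str

    @property
    def key(self) -> str:
        return f"{self.genome}:{self.start}-{self.end}({self.strand})"


@dataclasses.dataclass
class HomologHit:
    orf: OrfRecord
    best_reference: str
    bitscore: float
    e_value: float
    neighborhood: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass(frozen=True)
class ClusterAssignment:
    sequence_id: str
    cluster: int  # 1..K
    coordinates: tuple[float, ...]


# ---------------------------------------------------------------------------
# ORF scanning


def _scan_strand(seq: str, genome: str, strand: str, min_len: int, L: int):
    """Longest ORF (most upstream ATG) per (stop codon, frame)."""
    out = []
    for frame in range(3):
        start = None  # 0-based index of first ATG since last stop, this frame
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                continue  # N codons neither start nor stop an ORF
            if codon in _STOPS:
                if start is not None:
                    length = i - start
                    if length > min_len:
                        nt = seq[start:i]
                        protein = str(Seq(nt).translate())
                        if strand == "+":
                            s, e = start + 1, i
                        else:
                            s, e = L - i + 1, L - start
                        out.append(OrfRecord(genome, s, e, strand, length, protein))
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return out


def scan_orfs(sequence: str, genome: str = "genome", min_len: int = 300) -> list[OrfRecord]:
    """Scan both strands, all three frames each, for ORFs longer than
    ``min_len`` bp (strict inequality; stop codon excluded from the length).

    An ORF runs from an ATG to the next in-frame stop; per (stop, frame,
    strand) the most upstream ATG after the previous stop is reported, i.e.
    the longest ORF. Only A, C, G, T and N are accepted.
    """
    seq = sequence.upper()
    bad = set(seq) - _DNA_OK
    if bad:
        raise ValueError(f"non-DNA characters in genome {genome!r}: {sorted(bad)}")
    L = len(seq)
    fwd = _scan_strand(seq, genome, "+", min_len, L)
    rc = str(Seq(seq).reverse_complement())
    rev = _scan_strand(rc, genome, "-", min_len, L)
    return sorted(fwd + rev, key=lambda o: (o.start, o.end, o.strand))


# ---------------------------------------------------------------------------
# Pairwise alignment and e-values


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_and_score(
    query: str, reference: str, n_effective: int | None = None
) -> tuple[float, float]:
    """Smith-Waterman local alignment score as (bitscore, e-value).

    bitscore = (lambda * S - ln K) / ln 2 with the gapped BLOSUM62 (11/1)
    Karlin-Altschul parameters; E = m * n * 2^-bitscore with m the query
    length and n the reference-set size (defaults to the reference length).
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    raw = _ALIGNER.score(query, reference)
    bits = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2.0)
    n = n_effective if n_effective is not None else len(reference)
    e_value = len(query) * n * 2.0 ** (-bits)
    return bits, e_value


def assign_best_hits(
    orfs: Sequence[OrfRecord],
    references: Mapping[str, str],
    families: Sequence[str],
    cutoff: float = 1e-4,
    neighborhood_size: int = 5,
) -> list[HomologHit]:
    """Retain ORFs whose lowest-e-value reference is one of the families of
    interest and passes the cutoff; attach each retained ORF's neighborhood
    (up to ``neighborhood_size`` matched ORFs in each genomic direction,
    best-reference ids in genomic order, no padding at contig edges).
    """
    missing = [f for f in families if f not in references]
    if missing:
        raise KeyError(f"family id(s) {missing} absent from references")
    if not references:
        raise ValueError("empty reference set")
    n_eff = sum(len(s) for s in references.values())

    best: dict[str, tuple[str, float, float]] = {}
    for orf in orfs:
        scored = []
        for ref_id, ref_seq in references.items():
            bits, e = align_and_score(orf.protein, ref_seq, n_effective=n_eff)
            scored.append((e, -bits, ref_id))
        e, neg_bits, ref_id = min(scored)
        if e <= cutoff:
            best[orf.key] = (ref_id, -neg_bits, e)

    by_genome: dict[str, list[OrfRecord]] = {}
    for orf in orfs:
        by_genome.setdefault(orf.genome, []).append(orf)
    for lst in by_genome.values():
        lst.sort(key=lambda o: (o.start, o.end))

    hits = []
    fam = set(families)
    for orf in orfs:
        entry = best.get(orf.key)
        if entry is None or entry[0] not in fam:
            continue
        ref_id, bits, e = entry
        sibs = by_genome[orf.genome]
        idx = sibs.index(orf)
        matched_left = [o for o in sibs[:idx] if o.key in best]
        matched_right = [o for o in sibs[idx + 1:] if o.key in best]
        nb = [best[o.key][0] for o in matched_left[-neighborhood_size:]] + \
             [best[o.key][0] for o in matched_right[:neighborhood_size]]
        hits.append(HomologHit(orf, ref_id, bits, e, nb))
    return hits


def detect_sulfur_cluster(
    hit: HomologHit,
    sulfur_labels: Mapping[str, bool],
    genome_length: int,
    m: int = 3,
    w: int = 10,
    d: int = 30_000,
) -> tuple[bool, tuple[int, int] | None]:
    """Is the focal homolog inside a near-end sulfur gene cluster?

    True when at least ``m`` sulfur-related matches occur among the ``w``
    nearest matched neighbors and the focal ORF lies within ``d`` bp of a
    sequence end (the stand-in for telomere proximity). Every neighborhood
    reference must carry a sulfur/not-sulfur label.
    """
    if m == 0:
        warnings.warn("m=0 makes the cluster test degenerate (always true)")
    nb = hit.neighborhood[:w]
    missing = [r for r in nb if r not in sulfur_labels]
    if missing:
        raise KeyError(f"missing sulfur labels for {missing}")
    n_sulfur = sum(bool(sulfur_labels[r]) for r in nb)
    near_end = hit.orf.start <= d or (genome_length - hit.orf.end) <= d
    ok = n_sulfur >= m and near_end
    span = (hit.orf.start, hit.orf.end) if ok else None
    return ok, span


# ---------------------------------------------------------------------------
# Alignment distances, MDS, K-means


def alignment_distance_matrix(msa: Sequence[tuple[str, str]]) -> np.ndarray:
    """Pairwise identity distance over an aligned FASTA.

    d(i, j) = 1 - (identical columns / comparable columns), where columns
    with a gap in both rows are not comparable. A pair with no comparable
    columns gets d = 1 with a warning.
    """
    ids = [name for name, _ in msa]
    rows = [seq for _, seq in msa]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows must have equal length")
    n = len(rows)
    arr = np.array([list(r) for r in rows])
    gaps = arr == "-"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gaps[i] & gaps[j])
            total = int(comparable.sum())
            if total == 0:
                warnings.warn(f"no comparable columns for pair ({ids[i]}, {ids[j]})")
                D[i, j] = D[j, i] = 1.0
                continue
            ident = int(((arr[i] == arr[j]) & comparable).sum())
            D[i, j] = D[j, i] = 1.0 - ident / total
    return D


def mds_embed(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distances and takes the top-k eigenpairs;
    reproduces Euclidean inputs of rank <= k exactly. Warns when negative
    eigenvalue mass exceeds half the spectrum (strongly non-Euclidean input).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(np.abs(evals[evals < 0]).sum())
    pos_mass = float(evals[evals > 0].sum())
    if pos_mass > 0 and neg_mass > 0.5 * (neg_mass + pos_mass):
        warnings.warn("negative eigenvalue mass > 50%: input is far from Euclidean")
    coords = np.zeros((n, k))
    for i in range(min(k, n)):
        if evals[i] > 0:
            coords[:, i] = evecs[:, i] * math.sqrt(evals[i])
    return coords


def kmeans_cluster(
    coordinates: np.ndarray,
    K: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    ids: Sequence[str] | None = None,
) -> list[ClusterAssignment]:
    """K-means (k-means++ init, Lloyd iterations, best of ``n_restarts`` by
    within-cluster SSE); deterministic given the seed. Labels are 1..K."""
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if K > X.shape[0]:
        raise ValueError("K exceeds the number of points")
    if np.unique(X, axis=0).shape[0] < K:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_restarts,
                tol=1e-8, random_state=seed)
    labels = km.fit_predict(X)
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    return [
        ClusterAssignment(sid, int(lab) + 1, tuple(map(float, row)))
        for sid, lab, row in zip(ids, labels, X)
    ]


def progressive_align(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Small star-progressive aligner (test utility, not a MUSCLE substitute).

    Aligns every sequence globally to the longest one and merges the pairwise
    alignments by gap propagation in the center sequence.
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return list(seqs)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    center_idx = max(range(len(seqs)), key=lambda i: len(seqs[i][1]))
    center = seqs[center_idx][1]
    Lc = len(center)

    # per sequence: insertions[p] = characters inserted after p center residues
    def decompose(center_aln: str, seq_aln: str):
        ins = {p: "" for p in range(Lc + 1)}
        aligned = [""] * Lc  # character opposite each center residue
        p = 0
        for ca, sa in zip(center_aln, seq_aln):
            if ca == "-":
                ins[p] += sa
            else:
                aligned[p] = sa
                p += 1
        return ins, aligned

    decomposed = []
    for name, s in seqs:
        if s == center:
            ins = {p: "" for p in range(Lc + 1)}
            decomposed.append((name, ins, list(center)))
            continue
        aln = aligner.align(center, s)[0]
        ins, aligned = decompose(str(aln[0]), str(aln[1]))
        decomposed.append((name, ins, aligned))

    width = {p: max(len(ins[p]) for _, ins, _ in decomposed) for p in range(Lc + 1)}
    out = []
    for name, ins, aligned in decomposed:
        row = []
        for p in range(Lc + 1):
            row.append(ins[p].ljust(width[p], "-"))
            if p < Lc:
                row.append(aligned[p] or "-")
        out.append((name, "".join(row)))
    lens = {len(s) for _, s in out}
    assert len(lens) == 1, "progressive merge produced ragged rows"
    return out
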