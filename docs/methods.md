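# Methods

`sulfassim` bundles four analyses that together characterise how budding
yeast lacking the canonical homocysteine synthase Met15 can still assimilate
inorganic sulfur through the inefficient paralogous enzyme Yll058w:
colony-grid fitness quantification, Michaelis–Menten kinetics,
enzyme-constrained flux balance analysis (FBA) of the sulfur assimilation
pathway, and homolog-neighborhood clustering. A synthetic-data module
generates every input with known ground truth so the full pipeline is
testable without external downloads. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Colony-grid fitness

**Plate model.** Colonies grow on a 16×24 grid (384 positions). Four
biological replicates each occupy one quarter of the plate; the default
`interleaved` scheme assigns replicate `2·(row mod 2) + (col mod 2) + 1`
(0-based parities), the maximally uniform 2×2 spatial interleave, with a
contiguous-`quadrant` scheme as the alternative. Border positions (the outer
ring, 76 of 384) enjoy greater nutrient access and are removed before any
statistic is computed; the 14×22 interior then holds exactly 77 positions
per replicate.

**Processing order** is fixed: border removal → outlier filter →
normalization → (per-time summaries, or loess → logistic fit → AUC) →
statistics.

- *Outlier filter*: keep `|x − median| ≤ k·MAD` with the **unscaled** median
  absolute deviation and `k = 2` by default. The normal-consistency constant
  1.4826 is deliberately not applied (configurable); "two median-adjusted
  deviations" is read literally as the raw MAD. When MAD = 0 (a majority of
  ties at the median) only the median value survives, which still strips
  gross outliers from near-constant groups. Pooling is per strain × plate ×
  time point by default, with per strain × plate exposed as an option.
- *Normalization*: relative colony size = size ÷ median size of the
  reference strain (the prototroph FY4 in the worked examples) on the same
  plate at the same time point. Strata missing the reference are dropped
  with a logged warning. Plate-level (not experiment-level) reference
  medians are used: they absorb plate-to-plate pinning and imaging offsets.
- *Saturation* defaults to the final three observed time points; an explicit
  time window can be supplied instead.
- *Growth curves*: observed series are smoothed onto exactly 100 equally
  spaced time points with a degree-2 local polynomial (tricube weights over
  a span fraction of the points, default 0.75; the span is not dictated by
  the procedure this reproduces, so it is exposed in the API). A logistic
  model `N(t) = K / (1 + ((K−N0)/N0)·e^{−rt})` is then fitted by bounded
  least squares and the fitness summary is the trapezoidal area under the
  *fitted* curve over the observed time range only. If the fit fails to
  converge the empirical trapezoid is reported and flagged.
- *Statistics*: effect size = (median_A − median_B) / median_reference.
  Significance comes from the Kruskal–Wallis H with mid-ranks and tie
  correction and the chi-square approximation (df = groups − 1). For groups
  of ≤ 10 observations an exact permutation p is added by exhaustive
  enumeration, in two conventions: the inclusive exact p (counts the
  observed statistic's full probability mass; the standard, conservative
  definition) and the mid-p (counts half that mass). The mid-p is the right
  quantity to compare against the continuous chi-square approximation: at
  n = 8 per group the inclusive p differs from the chi-square p by up to
  0.046 purely through discreteness, while the mid-p tracks it within about
  0.02 over ≥ 95% of the null distribution.

**What the synthetic plates emulate.** Logistic growth toward a per-strain
carrying capacity, a ×1.3 border growth advantage (multiplying K at border
positions), and multiplicative lognormal observation noise with unit mean at
a stated coefficient of variation. Defaults used throughout the tests:
reference K = 1000 px, mutant K = 500 px (a 0.5 fitness ratio, matching the
reduced-but-stable growth regime the analysis is meant to resolve), r = 0.25
h⁻¹, N0 = 5 px, seven time points over 120 h, noise CV 10%. Real colony data
additionally carry spatial nutrient-competition gradients, pinning failures
and image-segmentation artifacts that the generator does not model, so
passing tests demonstrate the *statistical machinery*, not robustness to
every plate pathology.

## Michaelis–Menten kinetics

The rate law is `v = Vmax·S/(Km + S)`. `MichaelisMentenModel.fit()` performs
nonlinear least squares with Hanes–Woolf initialisation (`S/v` regressed on
`S`), positivity bounds, and standard errors from the Jacobian at the
optimum. Rate units are opaque "assay units/min" and never converted; Km is
in mM. All-zero rate vectors return Vmax = 0 with Km flagged unidentifiable
(the catalytically dead mutant case) rather than an error. A warning is
issued when the fitted Km falls outside the observed substrate range.

The default substrate grid {0.25, 0.5, 1, 2, 4, 8, 15} mM spans the 0–15 mM
assay range with roughly log-spaced points bracketing both printed Km values
(4.29 and 8.03 mM); the exact grid used in the original assay is not
printed, so this grid is a stated stand-in. Assay noise is additive Gaussian
on rates. Progress curves integrate `dP/dt = Vmax·(S0−P)/(Km+S0−P)` with an
adaptive Runge–Kutta scheme (absolute tolerance 1e-9 on P, fixed-step RK4
fallback), which enforces the mass balance S + P = S0 by construction.
Standard curves are ordinary least-squares lines (optionally log-log)
inverted for unknowns, with extrapolations flagged; the canonical
seven-member 1:5 dilution series runs from 15 mM down to 0.00096 mM plus a
separate 0 mM blank.

## Enzyme-constrained FBA

FBA maximises flux through a biomass reaction subject to steady state
(S·v = 0) and flux bounds. The enzyme constraint treats each catalysed
unidirectional flux v_i as consuming v_i / kcat_i of its enzyme, with total
weighted usage capped by a single shared pool P (unit cost weights by
default; per-enzyme weights are configurable but molecular-weight costing is
out of scope for the compact model). Reversible reactions are split into
forward and reverse non-negative fluxes, each drawing capacity. The LP is
delegated to a HiGHS solver behind a narrow interface; the module owns model
construction, splitting, pooling and all contracts. Feasibility tolerance
1e-9; fluxes below 1e-7 are reported as zero.

**Built-in sulfur network.** Sulfate uptake → Met3 → Met14 → Met16 →
Met5/Met10 (one lumped complex) reduces sulfate to sulfide; Met2 acetylates
a homoserine precursor to O-acetylhomoserine (OAH); Met15 — and, far less
efficiently, Yll058w (modelled bidirectional; only forward flux is ever
observed) — condenses OAH with sulfide into homocysteine plus acetate and
hydrogen; Met6 methylates homocysteine to methionine, Cys4/Cys3 transsulfurate
it to cysteine; biomass consumes 0.6 Met + 0.4 Cys (an arbitrary but fixed
split — all conclusions rest on orderings and zeros, not absolute biomass).
Sulfur atoms balance across every non-exchange reaction. Alternative media
enable methionine/cysteine uptake instead of (or alongside) sulfate.

Default capacities: kcat = 100 for every canonical enzyme, kcat = 1 for
Yll058w (anchoring the ~100× efficiency gap), pool P = 1, sulfate uptake
bound 1. Under these values the sulfate uptake bound binds the wild type
while the enzyme pool binds Yll058w-dependent growth, which produces the
expected phenotype ordering — biomass(WT) > biomass(met15Δ) > 0,
biomass(met15Δ yll058wΔ) = 0, rescued by organosulfur uptake — and gives the
kcat scan (kcat = kcat_Met15 / factor) its plateau-then-decline shape, with
the decline beginning near factor ≈ 100. The absolute scale is arbitrary;
only the shape and orderings are claimed. The scan over the *published
genome-scale* enzyme-constrained model is supported through the JSON model
format (`sulfassim-model-v1`) but that model must be supplied by the user.

A deliberate simplification: with an intact assimilation pathway the model
predicts zero biomass for a sulfate-reduction knockout (e.g. MET3) on
sulfate-only medium. This is the textbook prediction; organisms can harbour
residual routes the compact network does not represent.

## Homolog discovery and clustering

- *ORF scan*: both strands, all three frames; an ORF runs from an ATG to the
  next in-frame stop, reporting per (stop, frame, strand) the most upstream
  ATG after the previous stop (the longest ORF); length excludes the stop and
  must strictly exceed 300 bp; coordinates are 1-based inclusive on the
  forward strand. Codons containing N neither start nor stop an ORF. Nested
  same-stop ORFs are therefore collapsed to the longest — an explicit
  convention, since scan procedures rarely state how they treat them.
- *Search*: Smith–Waterman local alignment under BLOSUM62 with affine gap
  costs 11/1 (the classic protein-search defaults), bitscore
  `(λ·S − ln K)/ln 2` with gapped Karlin–Altschul parameters λ = 0.267,
  K = 0.041, and `E = m·n·2^(−bitscore)` against the total reference-set
  length. This replaces an external BLASTP binary; precomputed tabular hits
  can be substituted. E-value cutoff 1e-4. An ORF is retained when its
  *best* (lowest-e-value) reference belongs to the families of interest; its
  neighborhood records the best-match ids of up to five matched ORFs in each
  genomic direction, unpadded at contig edges.
- *Sulfur-cluster call*: true when ≥ m (default 3) sulfur-labelled matches
  occur among the w (default 10) nearest matched neighbors **and** the focal
  ORF lies within d (default 30 kb) of a sequence end — the stand-in for
  telomere proximity, since synthetic contigs carry no telomere annotation.
- *Clustering*: pairwise identity distance over the alignment
  (`d = 1 − identical/comparable` columns, double-gap columns excluded),
  classical Torgerson MDS (double-centred squared distances,
  top-k eigenpairs — exact for Euclidean inputs of rank ≤ k), then K-means
  (k-means++ initialisation, Lloyd iterations, best of 20 restarts).
  K defaults to 3, the observed number of homolog groups, but is a free
  parameter. A small star-progressive aligner is included strictly as a test
  utility for unequal-length inputs; production alignments should come from
  a real MSA tool.

**What the toy genomes emulate.** Each genome plants, near one sequence end,
a cluster holding one member of each homolog divergence class plus three
shared sulfur-related genes, with unrelated decoy ORFs mid-sequence. Classes
derive from a single root protein: the class ancestor is the root mutated at
the class divergence (codon-wise substitutions, never creating stops or
touching the start codon), and each taxon's member adds a small within-class
divergence. The clustering panels use class divergences 0.05 / 0.35 / 0.60
with within-class divergence 0.03 — separations chosen to mimic
"recent paralog / pre-duplication paralog / distant outgroup" tiers while
keeping within-class variation realistic for congeneric species. Planted
ORFs are framed by an in-frame upstream stop so an exact scanner recovers
their exact spans. Real genomes add introns, frameshifts, composition bias
and assembly gaps that the generator does not model.

## Numerical and reproducibility choices

- Every generator is a pure function of an integer seed (numpy
  `default_rng`); the CLI derives named substreams from its single `--seed`.
- Logistic and Michaelis–Menten fits are deterministic given data (fixed
  initialisation rules, bounded `curve_fit`).
- LP degeneracy: alternative optima may differ in non-objective fluxes; only
  the objective value is contract-stable.
- Lognormal colony noise uses σ² = ln(1 + CV²) with mean 1, so noise-free
  expectations match the logistic closed form exactly.
- Tie-breaking in K-means is resolved by restart selection on within-cluster
  SSE under a fixed seed.

## Problem sizes in the test suite

The suite exercises: full 384-position plates at seven time points; 200
seeded noisy kinetics datasets; exhaustive permutation enumeration at up to
C(16,8) = 12,870 assignments; LP-versus-vertex-enumeration cross-checks on
networks of ≤ 6 reactions; ORF-scanner-versus-oracle comparison on 200
random sequences of 1–10 kb; and 20 seeded 12-taxon clustering panels.
These sizes give stable statistics for every claim the tests make while
keeping the whole suite fast enough to run routinely.

## Known limitations

- The fitness module starts from colony-size tables; image quantification,
  spatial competition correction and multiple-testing control are out of
  scope (raw Kruskal–Wallis p-values are reported).
- The compact sulfur network is a teaching-scale model: orderings and
  zero/nonzero growth calls transfer to genome-scale models, absolute
  biomass values do not.
- The Karlin–Altschul e-value uses fixed gapped BLOSUM62 parameters rather
  than composition-adjusted ones, so e-values near the cutoff can differ
  from a real BLASTP run; the planted-truth tests show the decision rule,
  not e-value equality.
- The kinetics module fits initial-rate data only; no global progress-curve
  fitting, background models or inhibitor terms.
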