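# Methods

This note documents the statistical procedures implemented in
`prefexpr`, the assumptions behind them, and the design choices made
where more than one reasonable reading existed.

## Expression units and normalisation

All screening is done in FPKM (fragments per kilobase of exon per
million mapped reads): `FPKM[g,s] = counts[g,s] · 10⁹ / (libsize[s] ·
length[g])`. Library sizes default to the column sums of the supplied
count matrix, which keeps a `CountMatrix` self-contained; externally
determined mapped-read totals can be passed to override. No pseudocount
enters the FPKM itself — zero counts map to zero FPKM — so the
screening rules below act on unshrunk values; pseudocounts appear only
where logarithms are taken.

## The two-tier screen

**Tier 1 (preferential expression).** A gene passes if (i) its FPKM
strictly exceeds `min_fpkm` (default 1) in the target samples and
(ii) its target-level FPKM is at least `fold` (default 2) times the
FPKM of every comparator sample individually. Fold comparisons are
multiplicative (`target ≥ fold · comparator`), so a zero-FPKM
comparator is passed vacuously and no division is ever performed; a
ratio of exactly `fold` passes, since "two times higher" names the
boundary.

**Tier 2 (specific expression).** Tier-1 genes whose target-level FPKM
is additionally at least `fold` times every developing-stage sample.
Tier 2 is a subset of tier 1 by construction.

**Aggregation modes.** "Two times higher than the other samples" admits
two readings of the target level, and both are implemented:

* `strict` (library default): the *minimum* FPKM over target samples
  must clear every bar, and every target sample must individually
  exceed `min_fpkm`. This is the conservative, per-sample conjunction;
  it makes tier membership a pure AND of per-sample rules.
* `mean`: the target *mean* is used instead. This is the reading under
  which the simulator's performance band (below) is stated: with only
  two target libraries, the minimum of two noisy draws against the
  maximum of seven comparator draws is dominated by extreme-value
  noise, and the mean statistic is markedly more sensitive at the same
  false-positive cost.

Every gene receives an audit record naming the first rule it failed
(`low-expression in <sample>` or `insufficient-fold vs <sample>`),
which in practice is the most useful output when thresholds are being
chosen.

## The synthetic-data generator

The simulator emulates a single-library-per-stage bulk RNA-seq survey
of 13 sample groups: two early-ovule (MMC-stage) target libraries, a
seven-tissue comparator panel (leaf, root, mature flower, two early-
and one mature-stamen stages, mature ovule) and four developing-ovule
stages for the tier-2 filter. An `n_replicates` option expands each
group into replicate libraries.

Truth is stated as per-group mean FPKM. Planted preferential genes have
target means `planted_fold` (default 4) times the baseline (default
20 FPKM) in the target groups; planted *specific* genes keep developing
groups at baseline, while preferential-only genes have elevated
developing groups too, so they fail tier 2 by construction. Background
genes violate a tier-1 rule explicitly rather than by chance — one
third are low-expressed in the targets (0.5 FPKM), one third flat, and
one third "near-misses" whose target sits at `fold/1.2` times the
comparators — so truth labels are deterministic and false-positive
rates are measured against genuinely negative genes, including hard
ones near the decision boundary.

Expected counts invert the FPKM formula per library (uniform library
sizes 20–30 M reads, gene lengths 0.5–3 kb), then are drawn
negative-binomially with variance `μ + φμ²`. At `φ = 0` counts are the
rounded means, making recovery exact and every run byte-reproducible —
the basis of the end-to-end recovery tests. At the reference noise
level `φ = 0.05` (coefficient of variation ≥ 22% per library), the
mean-mode screen holds sensitivity ≥ 0.95 and FPR ≤ 0.01 over 20 seeds;
this band is regression-tested.

What the generator does **not** emulate: count correlation between
genes, GC/length biases, compositional (library-normalisation) effects,
and mapping artefacts. Passing the recovery tests therefore shows the
screen implements its rules correctly and tolerates NB-level noise; it
does not show robustness to systematic biases in real libraries.

## Differential expression and the consensus rule

The analysis pattern reproduced here takes the intersection of two
independent DE callers' gene lists, each filtered at
|log₂FC| ≥ 2 and adjusted p ≤ 0.05. `consensus_deg` implements exactly
that set operation on any two `(gene_id, log2fc, p, q)` tables; the
thresholds are anti-monotone by construction (tightening either never
grows the set).

`simple_de` is the built-in caller that lets the pipeline run without
external software. Fold changes are `log2((meanFPKM_A + 1)/(meanFPKM_B + 1))`
— the 1-FPKM pseudocount bounds fold changes for unexpressed genes.
P-values come from a two-group rate score test on counts: with group
rates `λ = Σcounts/Σlibsize`, the statistic is
`(λ_A − λ_B)/√(V_A + V_B)` with model-based variances evaluated at the
pooled null rate under an NB variance `μ + φμ²`. The common dispersion
`φ` is estimated by pooling a method-of-moments ratio across all genes
and groups with ≥ 2 replicates (with the `n/(n−1)` small-sample
correction); without replicates it falls back to `φ = 0` (Poisson).
This common-dispersion score test is calibrated — on simulated null
genes at `φ = 0.05` with 3 replicates per group, the rejection rate at
nominal 0.05 stays within 0.05 ± 0.02 — but it deliberately does not
reproduce the shrinkage machinery of dedicated DE packages; it is a
stand-in caller, and the package's contribution is the consensus
operator and screen, not the test. BH q-values are computed within each
table.

## Enrichment

Per term, the one-sided upper-tail hypergeometric p
`P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` (scipy), with both
Benjamini–Hochberg and Benjamini–Yekutieli adjustments (statsmodels);
BY multiplies BH by `c(m) = Σ 1/i` and is the adjustment used for the
significance flag (level 0.05), alongside a raw-p cutoff of 10⁻⁵ used
for GO-style screens. The universe defaults to the annotated genes
present in the expression matrix and is configurable, since published
enrichment runs rarely state theirs. No GO-graph propagation is
performed: terms are treated as flat sets, as in the GMT format.
Because the hypergeometric distribution is discrete, null p-values are
super-uniform rather than uniform; the calibration tests check for the
absence of anti-conservatism accordingly.

## Neighbor-joining homolog assignment

Distances are p-distances (mismatch fraction with pairwise deletion of
gap/ambiguous columns) — the distance model of the original tree-based
disambiguation is not recorded, so the simplest one is the default and
is called out here as an assumption. Trees are built by the Saitou–Nei
agglomeration: join the pair minimising `Q(i,j) = (n−2)d(i,j) − r_i − r_j`,
with ties broken by the lowest current index pair for determinism;
negative branch lengths are clamped to zero with the deficit moved to
the sister branch (the silent behaviour of standard tree software). On
an additive matrix no clamping triggers and the output tree reproduces
the input distances exactly (regression-tested to 1e-9 on random trees
of up to 12 leaves; observed error is at machine precision). The
nearest homolog is the candidate hit with the smallest patristic
distance to the query, ties broken by E-value then id. Alignments and
hit tables are inputs; alignment and similarity search are external.

## qPCR (2^−ΔΔCT)

Replicates are averaged in Ct space first; `ΔCT = Ct_gene − Ct_ref`
per sample, `ΔΔCT = ΔCT_sample − ΔCT_calibrator`, relative expression
`2^−ΔΔCT`. Amplification efficiency is fixed at 2 per cycle — the
method's defining assumption — with no efficiency correction. The
replicate SD of the sample's ΔCT (gene and reference SDs combined in
quadrature) is exponentiated to an asymmetric fold range
`2^−(ΔΔCT ± SD)`. Identities that follow from the algebra — the
reference gene and the calibrator sample both map to 1, and adding one
cycle to a gene's Ct halves its relative expression — are tested
exactly. Note the one-cycle property applies to the *target* gene's Ct:
a shift applied to every well of a sample, reference included, cancels
in ΔCT by design — that cancellation is precisely why a reference gene
is used.

## Morphometric staging

The 12-stage floral-bud timeline is embedded verbatim. Stages 1–8 are
matched on (width, height) within ±0.5 mm per dimension (the tabulated
sizes are averages; the tolerance is configurable); stages 9–12 are
matched on petal length when petal information is supplied, which then
takes precedence ("petal just visible" maps to stage 9). Records tying
at the best distance are all returned with an ambiguity flag — stages 7
and 8 genuinely share 8×8 mm buds and can only be separated by
dissection, so the classifier reports both rather than guessing. The
narrative description places the functional-megaspore stage at ~9 mm
width where the table says 8; the tabulated value is authoritative in
the embedded data. Measurements matching no record within tolerance
yield an explicit out-of-range result.

## Problem sizes

The validation suite and the acceptance script run entirely on
synthetic data at desk scale: 500–2000 genes × 13–39 libraries per
simulated experiment, 20 seeds for the noisy-screen band, 1000 null
genes for DE calibration, 200 replicates each for the enrichment-null
and neighbor-joining checks. These sizes give the Monte-Carlo bands
quoted above while keeping a full run in well under a minute per
component. The published gene counts of the motivating study (hundreds
of preferential genes out of ~27k) are not reproduction targets: they
depend on the original raw libraries and alignment stack, which are out
of scope here.

## Known limitations

* The built-in DE test assumes a common dispersion across genes; with
  strong mean–dispersion trends its per-gene calibration will drift.
* The screen takes FPKM at face value; no between-library normalisation
  beyond library size is applied.
* p-distance saturates for divergent sequences; model-based distances
  are not implemented.
* The stage classifier does not interpolate between stages and inherits
  the tabulated averages' granularity.
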