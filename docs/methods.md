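# Methods

## The cross-tissue co-expression statistic

For a seed transcript *s* and each tissue *t* with expression matrix
X_t (genes × donors), the package computes the sample Pearson coefficient
r_t(s, g) between the seed and every transcript *g*, then

R_sum(g) = Σ_t r_t(s, g).

With T tissues, |R_sum| ≤ T, and R_sum(s) = T exactly whenever the seed
has positive variance in every tissue (each self-correlation is set to
exactly 1.0, so the identity holds in floating point, not just in
theory). Transcripts are sorted by descending R_sum; ties are broken by
lexicographic gene id so ranks are a reproducible permutation of
1..n_genes. The top-k "extreme" of the ranking is the seed's
co-expression module; the seed itself is excluded from the reported
module by default (a flag includes it).

Summing correlations rather than averaging them keeps the statistic on
the familiar 0..T scale and makes the self-correlation identity a sharp
end-to-end check of the whole pipeline (normalization included). A gene
whose correlation is undefined in some tissue (zero variance there)
contributes 0 for that tissue under the default `zero` policy; a
`drop-gene` policy that removes such genes entirely is available. The
gene universe is the intersection of gene ids across tissues, with the
number of dropped genes logged.

Individual pairs of interest are confirmed with Spearman's rank
correlation: Pearson applied to mid-ranks (average ranks for ties), with
a two-sided p-value from the t approximation on n − 2 degrees of
freedom. The t approximation is appropriate here because the intended
donor counts are ≥ 90 per tissue; an exact permutation p-value would add
cost without changing any decision at that sample size.

## Normalization

Counts are TMM-normalized before correlation. For each sample against a
reference sample: genes with a zero in either sample are excluded
pairwise; M = log2 ratio of library-scaled proportions; A = mean of the
two log2 proportions; genes in the upper/lower 30% tails of M or 5%
tails of A are trimmed; the scaling factor is 2 raised to the
precision-weighted mean of the remaining M-values, with weights equal to
the inverse approximate (delta-method binomial) variance of M. The
reference sample is the one whose 75th-percentile library-scaled
proportion is closest to the across-sample mean (a fixed reference can
be named instead). Factors are rescaled to geometric mean 1. This
parameterization was verified against edgeR's `calcNormFactors(method =
"TMM")` on a fixed 50 × 6 matrix (agreement to ~5 × 10⁻¹³; the reference
factors are frozen into the test suite).

Correlations run by default on log2(CPM + 1), where CPM uses
TMM-adjusted library sizes (count / (library size × factor) × 10⁶). The
+1 pseudo-count maps zero counts to exactly 0 and keeps all values
finite. Unlogged CPM is available via the `correlation_scale` option;
the choice of scale is configuration, not a hidden constant, because
correlation analyses of heterogeneous bulk samples are commonly run on
either. All-zero gene rows are tolerated everywhere (they drop out of
TMM's pairwise comparisons and correlate as undefined).

Tissues with fewer donors than `min_donors` (default 90) are excluded
from the sweep with a logged warning rather than an error, mirroring the
donor-count inclusion rule such multi-tissue sweeps use.

## Synthetic data generator

The generator emulates the data regime the analysis is designed for — a
GTEx-like panel — without attempting to match GTEx marginals; only the
co-variation structure the analysis consumes is modeled.

Per tissue, each donor j receives a latent regulator activity
z_j ~ N(0, 1) and a depth factor d_j ~ logNormal(0, σ_lib). Gene g in
donor j has mean μ_gj = exp(b_g + β_g z_j) · d_j, where baseline
log-means b_g ~ N(ln 50, 1.5²) are drawn once and shared across tissues
(so the universe is comparable between tissues), and β_g = effect_size
for the planted module (seed included), 0 otherwise. Counts are drawn
gamma-Poisson: λ ~ Gamma(1/φ, μφ), count ~ Poisson(λ), i.e. negative
binomial with dispersion φ (variance μ + φμ²).

Defaults: 20 tissues × 100 donors, 5,000 genes, 50-gene module,
effect_size 1.0, active_tissue_fraction 0.9 (the 2 inactive tissues have
effect exactly 0, emulating tissues — e.g. brain — where the seed's
co-expression is weak), dispersion φ = 0.1, σ_lib = 0.3. The 5,000-gene
universe is the routine working scale; the transcriptome-scale universe
(56,202) is supported but only used for arithmetic accounting, since the
sweep's cost is linear in genes × tissues. Dispersion 0.1 and library
σ 0.3 are typical mid-range values for bulk RNA-Seq of homogeneous
cohorts.

Each tissue draws from its own RNG stream keyed (rng_seed, 1, t), and
universe-level quantities (baselines, module membership) from
(rng_seed, 0), so adding tissues never perturbs earlier tissues and
every output is reproducible from one integer.

What the generator does **not** model: donor covariates, isoform
structure, gene length, GC/batch effects, tissue-specific baselines, or
correlated non-module gene groups. Passing recovery tests therefore
demonstrates that the pipeline recovers a planted single-factor module
under realistic count noise — not that it would resolve overlapping
regulatory programs in real tissue panels.

At the defaults the planted-module recovery precision (top-50 ranks vs
truth, seed included) is 1.0 with rng_seed = 1; that exact value is kept
as a frozen regression number, while the asserted property is the looser
bound that precision exceed the chance baseline (module_size / n_genes =
0.01) by at least 10×.

## Module probability statistics

Chance co-occurrence of m marker genes in a top-k module from a universe
of N is computed under two null models: independent placement, (k/N)^m,
and placement without replacement, Π_{i=0..m−1} (k−i)/(N−i). The two
agree in the large-universe limit and without-replacement is never
larger for m ≥ 2; both are always reported side by side, because which
model a given published "estimated P" used is generally not stated.
Enrichment of a gene set in a module is the upper-tail hypergeometric
probability P(overlap ≥ observed). Binomial coefficients are evaluated
in log space (lgamma), so transcriptome-scale N is safe from overflow.

## CArG-box scanning

The scanner matches the strict SRF consensus CC(A/T)₆GG over every
10-base window (overlaps included, via regex lookahead), case-insensitive,
with N and other ambiguity codes never matching (conservative).
Coordinates are 0-based half-open (BED convention). The consensus family
is closed under reverse complement, so plus- and minus-strand hits
occupy identical intervals; both strands are still reported (with the
strand-oriented matched string) so downstream annotation can keep
orientation. On iid uniform sequence the per-window match probability is
(1/4)⁴(1/2)⁶ = 1/16,384, which the tests use as a Poisson-rate check on
100 kb of background. Degenerate one-mismatch "CArG-like" boxes and
PWM scoring are out of scope.

## RT-qPCR fold changes

The Pfaffl equation FC = E_target^ΔCt(target) / E_ref^ΔCt(ref), with
ΔCt = Ct(control) − Ct(treated) and assay efficiencies E ∈ [1, 2].
Efficiencies default to 2 (perfect doubling), under which the expression
reduces to the 2^−ΔΔCt convention; real assay efficiencies can be
supplied per call. The table interface averages Ct within (gene, group)
before differencing.

## Pipeline and reproducibility

`coexmod.pipeline.run` chains simulate/load → TMM → Pearson sweep →
R_sum ranking → extreme extraction → probability statistics → optional
CArG scan, writing the ranking TSV, module list/JSON, statistics JSON,
BED, a run log, and a report JSON (tissues used/excluded with donor
counts, universe size, number of correlations computed, seed R_sum,
top-k listing). The report contains no timestamps, so identical
configurations produce byte-identical reports. Configuration files are
flat YAML with unknown keys rejected (fail-fast). Default k is ~1% of
the universe when not set explicitly, reflecting the usual choice of
extreme size; any fixed k is accepted.

## Numerical choices and edge cases

- Pearson coefficients are clipped to [−1, 1] to absorb last-ulp
  overshoot; the seed's own entry is assigned exactly 1.0.
- Zero-variance seed in any tissue is an error (no profile is possible);
  zero-variance non-seed genes are flagged undefined, never silently 0
  in per-tissue output (only the R_sum accumulation maps them to 0 under
  the default policy).
- TMM returns factor 1 when all M-values are below 1e-6 in magnitude,
  when trimming leaves nothing, or for the reference itself; a sample
  sharing no nonzero genes with the reference raises an error naming the
  sample.
- Spearman on a constant vector returns an explicitly flagged undefined
  result rather than 0.

## Problem sizes

The test suite exercises the full 20-tissue layout with reduced gene and
donor counts (120 genes × 25 donors) for fixtures, and one full
default-scale run (5,000 genes × 20 tissues × 100 donors, ~10 s) for the
planted-module recovery check; the acceptance script repeats that
default-scale run from scratch. Transcriptome-scale numbers (56,202
genes) enter only as exact arithmetic (correlation counts, extreme
share, co-occurrence probabilities), which is how they appear in the
original sweep's accounting.
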