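# coexmod

Cross-tissue seed-gene co-expression analysis for bulk RNA-Seq panels,
built around the **R_sum** statistic: for a chosen seed transcript *s*,
compute the Pearson correlation r_t(s, g) against every transcript *g*
within each of *T* tissues, and sum across tissues,

    R_sum(g) = Σ_{t=1..T} r_t(s, g),   so  |R_sum| ≤ T  and  R_sum(s) = T.

Sorting transcripts by descending R_sum and taking the positive extreme
(the top *k*, typically ≈1% of the universe) yields the seed's
**co-expression module** — the set of transcripts that track the seed
across many tissues at once, which is how shared transcriptional drivers
(e.g. myocardin-related transcription factors acting through SRF and its
CArG-box element CC(A/T)₆GG) reveal themselves in resources like GTEx.

The package is aimed at transcriptomics analysts who want this sweep as a
tested, reproducible pipeline rather than a spreadsheet exercise. It
provides:

- `coexmod.simulate` — a negative-binomial multi-tissue count simulator
  with a planted, regulator-driven module (known ground truth), plus
  synthetic promoters with planted CArG boxes;
- `coexmod.normalize` — TMM (trimmed mean of M-values) scaling factors
  and log2-CPM conversion; reads plain TSV count matrices and GCT 1.2;
- `coexmod.coexpression` — per-tissue seed-versus-all Pearson profiles,
  the R_sum ranking, extreme extraction, and Spearman confirmation of
  individual pairs;
- `coexmod.module_stats` — chance co-occurrence of marker sets in a
  top-k module (independent and without-replacement null models) and
  upper-tail hypergeometric enrichment;
- `coexmod.carg` — a strict-consensus CArG-box scanner with BED output;
- `coexmod.qpcr` — Pfaffl-method RT-qPCR fold changes;
- `coexmod.pipeline` / the `coexmod` CLI — orchestration with a
  machine-readable run report.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with a planted 50-gene module (seed `G00000`, 5,000 transcripts,
20 tissues × 100 donors, module active in 18/20 tissues):

```sh
python analysis/01_simulate_panel.py
python analysis/02_rank_coexpression.py
python analysis/03_module_probabilities.py
python analysis/04_scan_promoters.py
python analysis/05_qpcr_fold_changes.py
```

Output of `02_rank_coexpression.py`:

```
tissues used: 20, excluded: 0
universe: 5000 transcripts; 100000 correlations computed
seed G00000 R_sum = 20.0 (theoretical maximum = number of tissues)
top-50 extreme recovers 49/49 planted module genes
```

The seed reaches the theoretical R_sum maximum of 20 (self-correlation
contributes exactly 1 per tissue), and the top-50 extreme recovers all 49
non-seed planted genes. `03_module_probabilities.py` then puts numbers on
chance co-detection at transcriptome scale (56,202 transcripts, top-600
extreme):

```
P(all 2 markers in top-600 of 56,202 by chance): independent 1.140e-04, without replacement 1.138e-04
P(all 3 markers in top-600 of 56,202 by chance): independent 1.217e-06, without replacement 1.211e-06
hypergeometric enrichment of the planted module in the top-50 extreme: p = 2.168e-117
```

and `04_scan_promoters.py` confirms the CArG scanner recovers 10/10
planted boxes with a background hit rate matching the iid expectation of
(L−9)/16,384 matches per strand.

The same stages are scriptable through the CLI (`coexmod simulate`,
`coexmod rank`, `coexmod module`, `coexmod scan`, `coexmod stats`,
`coexmod qpcr`, `coexmod all`); see `coexmod --help`.

## Layout

```
src/coexmod/     library (simulation, normalization, co-expression,
                 module statistics, CArG scanning, qPCR, pipeline, CLI)
analysis/        numbered narrative drivers over the library
tests/           pytest suite (unit, property, end-to-end)
scripts/         acceptance script
docs/methods.md  models, parameters, and design notes
```
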