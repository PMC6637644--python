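# Methods

## The decision rule

Each biological replicate of a SILAC co-culture comparison yields one
positive ratio H/X per protein group (heavy = co-cultured condition, X =
the medium or light mono-cultured channel; ratio > 1 means more abundant
after co-culture). The analysis treats the replicate's quality-filtered
proteins as a single population:

- Ratios are transformed to log2 space. The population mean of the log2
  ratios equals the log2 of the geometric mean of the raw ratios, so
  centering in log space is geometric-mean normalization.
- Each protein's z-score is its log2 ratio minus the population mean,
  divided by the population standard deviation — the number of population
  σ it lies from the center.
- A protein is regulated in a replicate only if it passes **both**
  criteria with consistent sign: |log2 ratio| strictly greater than 0.58
  (ratio > 1.5 up, < 0.67 down) and z ≥ +1.960 (up) or z ≤ −1.960 (down).
  The z inequality is inclusive, the fold inequality strict; boundary
  inputs resolve exactly that way. A large positive z with a negative
  fold change (or vice versa) is contradictory and yields no call.
- |z| ≥ 1.960 / 2.576 / 3.291 — the two-sided standard-normal quantiles
  at 95/99/99.9% — grade calls into confidence tiers ci95/ci99/ci999.
- The final call intersects the two replicates: same direction in both,
  or unchanged. Conflicting directions across replicates yield unchanged.
  The reported average ratio is the geometric mean of the two replicate
  ratios (consistent with the log-space analysis; the arithmetic mean
  differs only for very asymmetric pairs) and the combined tier is the
  weaker of the two per-replicate tiers, a deliberately conservative
  summary.

The z criterion assumes the null log2-ratio population is approximately
normal; the fold criterion protects against populations so tight that
statistically extreme proteins are biologically trivial.

### Statistical conventions

- Standard deviation uses the sample (n−1) denominator; with thousands of
  proteins the distinction from the population denominator is far below
  any threshold's resolution. `population_stats(..., ddof=0)` switches it.
- Population statistics include every quality-filtered protein, extreme
  ratios included — no trimming. A robust mode (median / 1.4826·MAD) is
  available via `robust=True` but off by default: with ~1–3% regulated
  proteins the plain SD is inflated only marginally, and the plain rule is
  the reference behaviour. The robust mode matters when a few extreme
  ratios (hundreds-fold) would otherwise widen σ.
- A zero-variance population raises an explicit degenerate-population
  error rather than emitting infinities.

## Enrichment

Over-representation of each gene set among the called proteins is the
hypergeometric upper tail P(X ≥ k) (one-sided Fisher's exact test) with
the background universe defaulting to all quantified, quality-filtered
proteins of the experiment — not the genome; a whole-genome background
overstates enrichment of anything detectable by proteomics. Gene-set
members are intersected with the universe before testing, and identifier
matching is case-insensitive exact matching on accession or gene symbol.
P-values are adjusted across sets by the Benjamini–Hochberg step-up
procedure; sets with q < 0.05 are flagged significant. A set whose
overlapping proteins are all up-called (down-called) is labelled
up (down), otherwise mixed. The hypergeometric tail and the BH
adjustment are delegated to scipy and statsmodels respectively; the test
suite checks both against exhaustive enumeration and a hand-rolled
step-up loop.

## Synthetic data

`simulate_experiment` generates what the pipeline consumes: a
MaxQuant-dialect table per replicate plus a ground-truth table. Per
protein i and replicate r:

    observed log2 ratio = δ_i + N(0, null_sd_log2) + N(0, replicate_noise_sd_log2)

with δ_i = 0 for null proteins and ±|N(effect_log2_mean, effect_log2_sd)|
for up/down proteins, identical in both replicates — the biological
effect is the replicate-stable component, which is exactly what the
both-replicates intersection rule exploits. Exported ratios are
2^observed. Cells are blanked independently at `missing_rate`;
contaminant and decoy rows are appended at `contaminant_rate` /
`reverse_rate` with ratios drawn from the null distribution, so a
pipeline that fails to filter them perturbs its population statistics
measurably. Identical configs (including the seed) give byte-identical
outputs.

Defaults emulate one comparison of a hematopoietic/stromal co-culture
study at proteome scale: 5,500 proteins, ~1% up and ~1.5% down (the order
of magnitude such experiments report after intersection), 4-fold mean
effects with spread 0.5 in log2, null spread 0.5 log2 units, technical
replicate noise 0.2, 5% missing cells, ~3% decoy rows. An optional
stress mode (`n_extreme`) spikes proteins with |log2 effect| ≥ 7 —
ratios in the hundreds, as the most extreme validated proteins in such
studies show — to probe SD inflation.

What the generator does **not** emulate: peptide-level variation and
protein inference, intensity-dependent variance (low-abundance proteins
are noisier in reality), ratio compression, arginine-to-proline label
conversion, or correlated missingness. Passing recovery tests therefore
demonstrate the decision rule's behaviour under its own distributional
assumptions, not performance on any specific real dataset.

## Verification problem sizes

The suite checks, at sizes chosen to make each property sharp yet quick:

- z-scoring against an element-wise brute-force loop (100 random
  populations of 5–3000, agreement to 1e−12) and the standardization
  identity (mean 0, sd 1 within 1e−9) as a hypothesis property.
- Null calibration: 5,000 simulated null log2 ratios put 95% ± 1% of
  proteins inside |z| < 1.960; across 20 seeds the per-replicate flagged
  fraction stays ≤ 5.5% and the intersected fraction ≤ 1%.
- Recovery: 2,000 proteins, 5% up + 5% down at |log2 effect| = 2, total
  per-observation noise sd 0.3, 10 seeds — mean sensitivity ≥ 0.95 with
  false-discovery proportion ≤ 0.10.
- Fisher enrichment against exhaustive hypergeometric enumeration for
  every 2×2 table with margins ≤ 15 (1e−10).

## Design notes and limitations

- Exactly two replicates are supported; the intersection rule does not
  generalize gracefully and >2-replicate designs deserve a proper
  moderated-variance model instead.
- MaxQuant "normalized" ratio columns are the default input
  (`Ratio H/M normalized` / `Ratio H/L normalized`); the column map is
  fully overridable for other dialects, including raw ratio columns.
- Multi-accession protein groups ("P1;P2") use the first accession as the
  canonical key; the full group string is retained in the description.
- Contaminant/reverse flags accept any non-empty, non-"0" cell, matching
  the "+" convention while tolerating exports that write `1`/`TRUE`.
- Ranking ties (equal average ratios) are broken by accession order so
  top-N tables are deterministic.
- No peptide-level statistics, permutation or moderated-variance tests,
  >2-replicate designs, network inference, or live ontology access.
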