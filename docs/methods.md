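# Methods

## Scope and model

The package implements the measurement-to-report chain of a batch-culture
nitrate-starvation experiment on an oleaginous green microalga: two
treatments (NS, nitrate-starved; NR, nitrate-replete), sampling days
{0, 1, 2, 3, 6, 9, 12} with day 0 as the pre-treatment baseline, and three
biological replicates (flasks) per cell. All models are the simple
published correlations of this field — linear calibrations, two-wavelength
pigment equations, finite-difference productivities, and per-term linear
fuel-property models on FAME percentages. No mechanistic growth or lipid
kinetics is fitted anywhere.

## Physiology

* **Cell density.** density(10⁸ cells mL⁻¹) = slope·OD₆₈₁ + intercept. The
  built-in fixed model is slope 4.7151, intercept −0.0605; `fit_calibration`
  produces a model by ordinary least squares from ≥ 3 (OD, count) pairs
  with non-constant OD and reports r². ODs below the calibration root
  predict negative densities; these are clamped to 0 with a warning
  (a count cannot be negative, but the event is worth flagging). ODs are
  expected at four-decimal precision or better and are never rounded by
  the package.
* **Chlorophyll.** Ca = 16.72·OD₆₆₅.₂ − 9.16·OD₆₅₂.₄ and
  Cb = 34.09·OD₆₅₂.₄ − 15.28·OD₆₆₅.₂ (µg mL⁻¹, methanol extract); total is
  their sum. Negative components are *reported as-is* with a warning:
  clamping would silently hide a bad extraction.
* **Productivities.** Biomass productivity is the signed finite difference
  (B₂ − B₁)/(T₂ − T₁); oil productivity is BP × (oil %/100) × 1000, i.e.
  the percentage applied as a fraction so g → mg closes the units. Rates
  are computed against the fixed day-0 baseline by default — that is what
  makes the early-exposure biomass decline appear as negative
  productivity — with consecutive intervals available
  (`baseline_day=None`). Rates are computed per replicate flask and then
  averaged by default (`aggregate="replicate"`); computing from replicate-
  mean biomass is available (`aggregate="mean"`) because either reading of
  a mean ± SD table is defensible.

## FAME composition

* Species are keyed by Cn:d shorthand with an optional omega suffix
  (`C18:3n3`); class follows the double-bond count (SFA d=0, MUFA d=1,
  PUFA d≥2). Profiles are percent-of-total-oil vectors; totals need not
  reach 100 (unannotated chromatogram peaks exist) but totals above
  100 + tolerance (default 1 percentage point) are rejected, as are
  negative entries and duplicate keys.
* The minor-species reporting filter splits at 1 % by default, compared at
  reporting precision (one decimal), so a species printed as "1.0 %"
  counts as major. The filter affects *reporting only*: fuel-property
  estimation always uses the full profile, since the correlations are sums
  over whatever is present.
* The treatment-contrast heat-map statistic is log₂(mean_NS/mean_NR) per
  species and day, over replicate means (the default `log2_ratio` mode).
  A legacy mode `as_written_legacy` computes
  log₂(mean_NS)/log₂(mean_NR) − 1, preserving a literal reading of an
  ambiguous verbal definition of the quantity; the ratio form is the
  default because the quantity is named a log₂ fold-change ratio. Zero
  means on either side make the cell NaN (flagged missing, never ±inf),
  except the exact-identity case mean_NS = mean_NR which is 0 by
  definition. Display clipping to [−1, 1] mirrors a symmetric heat-map
  colour scale and never touches the raw matrix.

## Fuel properties

* **Methyl-ester mass.** M is the formula mass of the methyl ester
  C₍ₙ₊₁₎H₍₂₍ₙ₊₁₎₋₂d₎O₂, with atomic masses fixed at C 12.011, H 1.008,
  O 15.999 for bit-stable output. Chemically impossible shorthand
  (d > n/2) is rejected.
* **Cetane number.** The eight-term linear model is applied exactly as
  published: species outside its eight named terms contribute zero, and
  the C18:3 term aggregates all trienoic C18 isomers (n3, n6) because the
  omega position does not enter the model.
* **LCSF coefficient sets.** The published weighted sum
  0.6·C16:0 + 0.5·C18:0 + 1·C20:0 + 1.5·C22:0 + 2·C24:0 cannot reproduce
  the tabulated LCSF magnitudes from the same study family: a typical
  ≈ 40 % palmitic profile alone would give LCSF ≥ 24, whereas tabulated
  values run 7.2–16.4, and the companion CFPP column is exactly
  3.1417·LCSF − 16.477 of those tabulated values. A C16 weight of 0.1
  reproduces them. Both sets are first-class:
  `table_consistent` (0.1, default) and `as_printed` (0.6); every
  report row records which set produced it, and a regression test pins
  the discrepancy. Only saturated species enter LCSF.
* Reported values round half-up to one decimal (the table convention);
  raw double precision is retained internally.
* **Standards.** The registry (YAML, user-extensible) carries CN minima
  and CFPP windows: EN 14214: 2008 (CN ≥ 51, CFPP −18..0 °C), ASTM D6751
  (≥ 47, −18..3), RANP/2008 (≥ 47, no CFPP bound), SIRIM MS 123: 2005
  (≥ 51, ≤ 15). An absent bound is unconstrained.

## Synthetic data generator

The generator emulates the *measurement layer* of the design, nothing
deeper: per (treatment, day) it draws each underlying quantity (cell
density, total chlorophyll, biomass, oil %, each FAME percentage) as
mean·(1 + CV·z) with z standard normal, truncated at zero, then converts to
raw observables by inverting the very equations the analysis applies —
OD₆₈₁ from the calibration line, the two extract ODs from the 2×2
chlorophyll system (with a fixed chlorophyll-a fraction, default 0.75),
and oil mass over a fixed 0.3 g extracted dry mass. FAME vectors are
renormalized to the configured total. Replicates are drawn independently
within and between days (between-day within-flask correlation is not
characterizable from summary data and is not modelled).

The default configuration (`default_study_config`) embeds the reported
anchor means — NS day-12 oil 57.9 % DW, NR day-9 oil 44.0 %, NR day-12
biomass 0.8 g L⁻¹ vs NS 0.46, chlorophyll 8.9 µg mL⁻¹ (NR day 6) down to
3.3 (NS day 12), inoculum 1×10⁸ cells mL⁻¹ with the 1.8/2.1-fold day-1
jump, and a C16:0/C18:1-dominated composition with minor C18:0, C21:0,
C24:0 and C18:2/C18:3n3 — and interpolates the unreported intermediate
days so the derived rates land in the reported ranges (day-0 biomass
0.30 g L⁻¹ gives the NR oil-productivity plateau near 16–18 mg L⁻¹ day⁻¹
and negative rates on days 1–3). Replicate CV defaults to 0.03 per
measurement family. Noise is Gaussian-multiplicative because only
mean ± SD summaries exist to emulate; passing round-trip tests therefore
demonstrates pipeline correctness under that noise model, not robustness
to the skew, drift or between-day correlation of real instrument series.

## Statistics

One-way ANOVA is the classical between/within mean-square F test
(scipy's implementation behind the module surface); groups need ≥ 2 values
each and nonzero pooled within-group variance. Post-hoc pairwise
comparison offers Tukey's HSD (studentized-range) and Fisher's LSD
(pooled-t with N − k df, uncorrected). LSD is never more conservative than
Tukey for k > 2 and the two coincide at k = 2; the default is LSD to match
the asterisk convention of per-day NS-vs-NR tables, and every result
carries its method tag. Comparisons are run within each day
(matching a per-row asterisk layout) rather than across days jointly.
Report tables print mean ± SD at one decimal with a star on the *larger*
mean of a significant pair.

## Problem sizes

The acceptance checks use 1,000 random profiles for the brute-force
property-model equivalence, 20 seeds × 3 replicates for synthetic
round-trip recovery, and 1,000 null ANOVA replicates (n = 3 per group) for
type-I calibration — sizes at which the Monte-Carlo standard errors are
comfortably inside the asserted bands while the whole suite runs in
seconds.

## Known limitations

* The fuel-property models are published linear correlations; they are not
  engine measurements and carry the biases of their source regressions.
* The generator reproduces means and replicate CVs only — no growth
  kinetics, no correlated errors, no chromatogram-level artifacts.
* Profiles with more than three double bonds contribute zero to DU and CN
  (the models name no such terms); IV and SV handle any d.
* The chlorophyll split (a-fraction 0.75) in the generator is a fixed
  convention; the analysis side never depends on it beyond the total.
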