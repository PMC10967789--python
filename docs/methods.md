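# Methods

## The size-adjustment chain

CT scanners report CTDIvol and DLP referenced to a 32-cm PMMA cylinder.
For a patient of effective diameter `Deff = sqrt(AP × LAT)` (geometric
mean of the anterior–posterior and lateral dimensions at the most
extensive cross-section — per-slice diameter series are out of scope),
the size-specific dose estimate is `SSDE = CTDIvol × k(Deff)` and its
whole-scan analogue is `DLPss = DLP × k(Deff)`. Because both are the
same linear rescaling, `DLPss/DLP == SSDE/CTDIvol == k` holds exactly
for every record; the test suite asserts it to 1e-12 relative error.
Effective dose is `ED = DLP × f` with the AAPM-96 chest coefficient
f = 0.014 mSv/(mGy·cm); other protocols (head, neck, abdomen, pelvis)
are registered in a small YAML table.

DLPss and ED use the diagnostic-scan DLP only by default. The topogram
contributes ~2% and is tabulated separately in audit practice; a
`dlp_source="total"` switch includes it.

Lengths are carried in mm and dose-length products in mGy·cm
throughout; the only mm→cm conversion happens inside the synthetic
generator's DLP model. All arithmetic is full precision; rounding to two
decimals happens only at the presentation layer.

## Conversion factors

The k(Deff) table for the 32-cm body phantom is transcribed from AAPM
Report 204 (effective diameter 8–45 cm, two-decimal factors) and shipped
as a commented TSV. Lookup is linear interpolation between knots — the
way the printed table is read in practice — with the report's
exponential fit `k = 3.704369·exp(−0.03671937·d)` stored alongside as a
cross-check (`use_fit=True` selects it; fit-vs-table agreement is within
0.6% over the range, asserted ≤ 1%). Outside the tabulated range the
lookup clamps to the nearest endpoint and logs a warning rather than
extrapolating, which would produce k < 1 nonsense at very large
diameters. Whether interpolation or nearest-row reading was used in the
audits this mirrors is not documented; interpolation is this package's
choice.

## Cohort statistics

Summaries are mean, sample SD (n−1), min, max per stratum (all/F/M).
Sex comparisons run Shapiro–Wilk on each arm at α = 0.05: if both are
compatible with normality, the equal-variance two-sided Student t-test
is used (Welch available behind a flag), otherwise the two-sided
Mann–Whitney U. A zero-variance arm leaves Shapiro–Wilk undefined and
routes to Mann–Whitney with a warning. Correlations are Spearman rank
with average-rank ties (constant variables are reported as missing with
a reason, not as NaN). No multiple-testing correction is applied by
default, matching dose-audit reporting practice of raw per-test
p-values; a Holm adjustment is available (`holm_adjust`).

Audit percentages: scan-change categories use the sign of
(diagnostic − topogram), with "unchanged" requiring exact mm equality —
published audits report shortened/extended shares that leave a small
unnamed residual, and exact equality is the only partition consistent
with that. Effective diameters exactly at the 32-cm phantom count as
"below" so the two classes always partition to 100%. Length-to-height
ratios are reported under both conventions — ratio of stratum means
(which reproduces the published female value of 22.9%) and per-patient
mean of ratios — because audit reports are ambiguous about which they
use.

## Synthetic cohort generator

The generator emulates an adult chest-CT audit cohort of 134 studies
(68 F / 66 M) with, per sex: age 65.89 ± 12.91 / 63.15 ± 13.15 y,
height 161.04 ± 5.97 / 175.8 ± 7.10 cm, BMI 26.88 ± 5.70 / 27.8 ± 5.93
kg/m² truncated to the inclusion window [18, 35], effective diameter
28.74 ± 3.43 / 31.13 ± 3.05 cm, CTDIvol 7.38 ± 3.23 / 8.30 ± 2.49 mGy,
Spearman targets BMI↔Deff 0.82/0.90 and CTDIvol↔Deff 0.79/0.87 (F/M),
scan-length change 4.54 ± 11.35% clipped to the observed extremes
[−27.2, +36.86]%, topogram-to-height ratio 0.23 ± 0.022, and expected
DLPs of 286.51 (diagnostic) and 5.28 (topogram) mGy·cm.

Only marginals and rank correlations are available as targets, so a
Gaussian copula with matched marginals is used — the minimal joint
structure consistent with them. Spearman targets convert to latent
Pearson correlations via `r = 2·sin(π·ρ/6)`, which Gaussian copulas hit
exactly in population; monotone marginal transforms (the
truncated-normal BMI quantile map) preserve them. CTDIvol follows an
ATCM-style model `c0·exp(g·(Deff − 32))·ε` with lognormal mean-one
noise; `g`, the noise scale and `c0` are solved in closed form from the
configured mean, SD and rank target (`c0` carries the lognormal Jensen
correction `exp(−g·μ_d' − (g·σ_d)²/2)` so means are exact in
expectation). AP and LAT are split from Deff with a noisy aspect ratio
around 0.73 so `sqrt(AP·LAT)` reproduces the drawn Deff to machine
precision, and `weight := BMI·(height/100)²` exactly. The diagnostic DLP
is `efficiency · CTDIvol · length`, with the single efficiency factor
solved analytically so the expected diagnostic DLP matches its target
(it absorbs overranging and pitch effects the model does not resolve).
Randomness uses one master seed with per-stage, per-sex `SeedSequence`
child streams, so adding a stage never perturbs earlier draws.

Two calibration adjustments are location solves: the pre-truncation BMI
mean is chosen so the truncated mean equals the target, and the
scan-change location so the post-clip mean equals 4.54%.

### What the generator does and does not reproduce

- The BMI target SD of 5.70 kg/m² is **not attainable** by any normal
  truncated to [18, 35] (the supremum is 17/√12 ≈ 4.91); the realized SD
  is ≈ 4.2 and `calibration_report` flags it. A real cohort with that SD
  inside that window must be heavier-shouldered than a truncated normal.
- The **pooled** BMI↔Deff Spearman is emergent, not a knob. With per-sex
  targets 0.82/0.90 and the per-sex Deff marginals above, the pooled
  correlation settles near 0.835 at large n; the whole-group value of
  0.77 reported alongside those per-sex values is reachable only within
  n = 134 sampling spread (the 500-seed distribution at n = 134 covers
  it). The three rank targets plus the marginals jointly over-determine
  any copula model; this package prioritises the per-sex pipeline and
  reports the pooled gap honestly rather than distorting the within-sex
  structure.
- Scan-length changes are drawn continuously, so exactly-unchanged scans
  have measure zero in synthetic cohorts, whereas real audits show a
  small unchanged share; and the shortened share comes out near 35%
  under a normal Δ model versus ~29% in real data (mild non-normality).
- Topogram DLP variability is driven by the CTDIvol noise and is wider
  than real topogram DLP SDs; only its mean is calibrated.
- AP↔LAT joint behaviour beyond the mean aspect ratio, pathology-based
  exclusions, and body-composition effects are not modelled.

Passing recovery tests therefore show that the pipeline measures what
the generator encodes — marginal levels, monotone dose–size structure,
rank correlations — not that real registries satisfy the Gaussian-copula
assumptions.

## Numerical and interface choices

- Degenerate configs (any SD = 0) collapse to point masses rather than
  erroring, so exactness tests can run on them; infeasible rank targets
  (|ρ| ≥ 1) and means outside their windows are configuration errors.
- Defensive floors: drawn Deff ≥ 1 cm, topogram ratio ≥ 0.05, age ≥ 18 —
  inactive under any realistic configuration, they only guard pathological
  ones.
- CSV dialect is strict: comma delimiter, dot decimal, mandatory header,
  `#` comments. Ambiguous locales (comma decimals) are rejected row by
  row with line numbers; the rest of the file loads. Sex codes are F/M,
  case-insensitive on read, uppercase on write.
- `derive_all` collects per-record failures with ids and fails only if
  every record fails; every compute bundle contains the serialized run
  configuration and a manifest naming its inputs and outputs.
- Test problem sizes: recovery checks run at n = 10,000 per sex (means
  within 3 Monte-Carlo SEs, rank correlations within ±0.03) and the
  sampling-spread check at n = 134 over 500 seeds; both complete in
  seconds.

## Known limitations

Single-slice Deff only (no water-equivalent diameter, no per-slice
series); no organ dosimetry or Monte-Carlo transport; no DICOM RDSR
ingestion — input is the documented CSV schema; the cohort layer tests
exactly the comparisons described above and is not a general statistics
framework.
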