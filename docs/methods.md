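# Methods

## Event definition and onset parameters

A liver-injury event is the first study day on which ALT or AST reaches
3× the upper limit of normal (ULN) or ALP or total bilirubin reaches
2×ULN, thresholds inclusive. The detector scans study days in order, so
the reported onset is minimal by construction and independent of input
row order. Latency uses the first-dose-equals-day-1 convention
(latency = onset study day); a `day_offset` on `DetectionThresholds`
switches conventions. At onset the R-value is computed from same-day
ALT and ALP in ×ULN, the de Ritis ratio from same-day raw AST and ALT.
Degenerate inputs are flagged rather than coerced: a missing or zero
same-day ALP (or ALT) leaves the R-value (or ratio) undefined and the
case is excluded from that parameter's phenotype profile with a
warning; bilirubin-only triggers carry a `bilirubin_only_trigger` flag
because the phenotype describes enzyme patterns. When several analytes
qualify on one day the trigger label follows the fixed priority
ALT > AST > ALP > TBIL; the choice is cosmetic — it never changes the
three parameters.

## Phenotype profiles and quantile dialects

A phenotype summarises each parameter over n ≥ 5 same-drug cases (the
minimum is configurable; five is the smallest seed set the method has
been demonstrated on, and `force=True` lowers it with a warning). Two
interpolation dialects are implemented because spreadsheet practice —
and the published reference tables — mix them: *inclusive* (Hyndman &
Fan type 7, rank 1+(n−1)q) and *exclusive* (type 6, rank (n+1)q,
clamped to the data range). Both delegate to `numpy.quantile`
(`method="linear"` / `"weibull"`) and are property-tested against an
independent hand-rolled interpolation oracle. The reproduction
configuration pins the preliminary phenotype to inclusive and
refinements to exclusive, which is the only combination that reproduces
the published reference tables digit for digit; the package default
elsewhere is inclusive. Outlier fences are asymmetric —
Q3 + 150 %·IQR above, Q1 − 75 %·IQR below — reflecting the right skew
of latency and R. Fences may fall inside the observed range; range
membership and outlier status are therefore judged independently.
All statistics are kept at full float precision; rounding happens only
in reports.

## Scoring

Band percentages are fixed: IQR 100 %, 15–25/75–85 band 50 %,
10–15/85–90 band 25 %, in-range tails 0 %, outside range or beyond a
fence −25 %, both −50 %. Edge conventions: IQR endpoints score 100 %
(forced by a published case sitting exactly on Q3 and scoring full
points); each outer band edge belongs to the band nearer the median;
range endpoints are in-range. Points are percentage × maximum / 100
with integer results kept exact (the 20/40 maxima and 25 %-step
percentages always yield integers). One historical reading of the
rubric assigns in-range outliers a fixed −10 points instead of −25 %;
it is available as `table_outlier_compat` but is off by default since
the percentage rule reproduces every published worked-example score.

## Statistics

The Mann–Whitney test is the asymptotic variant with midranks, the
standard tie-corrected variance, and *no* continuity correction — the
only variant consistent with all published reference p-values at
n = 5 vs 3. It is implemented from the rank formulas (ranks via
`scipy.stats.rankdata`) because the decomposition into U, z and the
tie term drives the weighting rule; `scipy.stats.mannwhitneyu` serves
as an independent cross-check in the tests, alongside a brute-force
pair-count oracle. When both groups are one constant the variance is
zero; p is set to 1 with a warning. The trend test is the
linear-by-linear association chi-square (N−1)·r² on the binary arm
indicator versus the total score, 1 df; it is undefined (and raises)
for constant scores or a single represented arm. Incidence uses the
Pearson chi-square without continuity correction. The weighted
parameter is the one with the smallest Mann–Whitney p rounded to three
decimals, ties broken by the smaller U, gated at α = 0.05
(configurable); latency is the a-priori default when no comparator
cases exist or nothing is significant.

## Stepwise pipeline

Batches are processed in order: the first non-empty batch seeds the
phenotype from its drug-arm cases; each later batch is scored against
the *current* phenotype before its drug cases are merged in, and an
explicit guard refuses to score any case against a phenotype version it
helped build. Weighting is selected per validation batch by default
(`pooled` and `frozen` modes exist because the right choice in a long
programme is genuinely open; per-batch mirrors the demonstrated
procedure). The cumulative phenotype after k batches equals a single
build over the union of their drug cases — no path dependence — and
identical inputs produce byte-identical JSON reports.

## Synthetic data

The generator emulates a two-arm trial in which the drug arm overlays a
clustered hepatocellular phenotype on a background elevation rate.
Per arm: events are Bernoulli per patient; latency and R are log-normal
(median 69 days / dispersion 0.25, median 8.7 / dispersion 0.5 for the
drug arm — the demonstrated phenotype at its ~6 % phase-2 event rate);
the ratio is normal(0.61, 0.08) truncated at zero. The comparator
defaults are diffuse: 2 % rate, latency median 120 days with dispersion
1.0, R median 1.5 with dispersion 1.0, ratio normal(1.0, 0.3).
Latencies snap to a fortnightly-then-monthly visit schedule by default
(trial labs are drawn at visits; the characteristic onsets fall on
visits 6–7), with a continuous-time option. Lab panels are constructed
so the detector recovers the drawn parameters exactly (onset-day ALT =
R × ALP in ×ULN, AST = ratio × ALT; all other days below threshold),
and the shipped ground-truth table is itself recomputed through the
detector, making the round-trip property exact rather than
approximate. The generator does not model assay noise, missed visits,
dropout, de-challenge kinetics, Hy's-Law bilirubin trajectories or
concomitant-medication effects — passing tests demonstrate the
*machinery* on idealised data, not clinical performance.

`estimate_power` runs a two-batch stepwise analysis per replicate using
the case-feature fast path (no lab materialisation): batch 1 seeds the
phenotype, batch 2 is scored with batch-level weighting, and the trend
p is compared to α. With identical arm models it estimates the
procedure's type-I error; the calibration test uses 150 patients per
arm at a 15 % event rate (≈22 cases per arm per batch, enough for the
chi-square asymptotics while keeping 1000 replicates to a few seconds)
and checks the rejection rate stays near the nominal 5 % despite the
adaptive weighting step. Replicates with too few cases to complete the
run count as non-detections and are tallied separately.

## Known limitations

* The phenotype treats the three parameters independently; joint
  (multivariate) structure is ignored by design.
* The asymptotic rank test is used at very small n (5 vs 3), where
  exact methods would normally be preferred; this mirrors the reference
  analysis it reproduces.
* Host factors, concomitant medications, de-challenge/re-challenge and
  severity (Hy's Law) are out of scope.
* The adaptive choice of the weighted parameter reuses the validation
  batch, which can mildly inflate the trend test's type-I error; the
  Monte-Carlo calibration keeps it within the tested band under the
  null configuration above, but users comparing many drugs should
  prefer the `frozen` weighting mode.
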