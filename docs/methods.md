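# Methods

## Scope and data model

The package compares two rival treatment techniques for the same cohort of
patients using only per-structure dose-volume histograms plus a little
plan-level metadata (prescription, fraction count, conformity volumes).  It
does not compute dose, contour structures, or optimize plans; DVHs are its
universal input currency.

The canonical DVH representation is **cumulative, absolute cc, on a uniform
dose grid starting at 0 Gy(RBE)** with a 0.05 Gy default bin width:
clinical constraints mix absolute ("≤16 cc receive 50 Gy(RBE)") and
relative ("≤10% receive 50") quantities, and cc is the lossless base unit
from which percent is derived.  Differential DVHs keep the representative
dose of each bin in the same `dose` array; the cumulative→differential
conversion assigns the volume between grid points `dᵢ` and `dᵢ₊₁` to dose
`dᵢ`, so with the default 0.05 Gy grid any left-edge bias in mean dose or
gEUD is below 0.025 Gy.  All doses are Gy(RBE): a constant proton RBE of
1.1 is assumed applied upstream by the planning system and never rescaled
here.

V\_x and D\_v use linear interpolation of the cumulative curve.  No
interpolation convention is universal in planning systems; linear is the
de-facto standard and makes the two lookups mutually inverse on grid
points.  D\_v resolves flat curve segments to their high-dose end (the
largest dose still covering the queried volume), and V\_x beyond the last
grid point is 0.  Worst-case (robustness) evaluation takes the maximum of a
metric over scenario DVHs for organs at risk and the minimum for
target-coverage metrics; the direction travels with the metric spec.

## Radiobiological chain

NTCP evaluation composes three steps, each exposed separately:

1. **EQD2**: every bin dose is converted with the linear-quadratic model,
   `EQD2(D) = D·(D/n_fx + α/β)/(2 + α/β)`, i.e. each bin's dose is assumed
   delivered over the plan's full fraction count.  α/β defaults to 4 Gy for
   the upper-GI organs modelled here and is configurable.  The map is
   strictly increasing, so DVH validity is preserved; the resulting dose
   grid is no longer uniform, which the DVH container allows (metrics
   interpolate, nothing assumes uniform spacing).
2. **gEUD**: `gEUD = (Σ (vᵢ/V)·Dᵢ^(1/n))^n`, the Kutcher–Burman histogram
   reduction with volume-effect exponent `n` (`n = 1` → mean dose, serial
   organs have small `n` and their gEUD approaches the maximum dose).  It
   is computed in log space (log-sum-exp) so exponents as small as
   `n = 10⁻³` (1/n = 1000) do not overflow; zero-dose and zero-volume bins
   are excluded, and an entirely unirradiated organ has gEUD 0.
3. **Probit response**: `NTCP = Φ((gEUD − TD₅₀)/(m·TD₅₀))`, evaluated via
   the error function.  The test suite carries an independent trapezoid
   integration of the normal density as oracle (agreement to 1e-8 over
   t ∈ [−6, 6]).

The shipped parameter registry holds the six published upper-GI sets used
for gastric bleed (Pan et al.: stomach 62/0.30/0.07, duodenum
180/0.49/0.12, stomach+duodenum composite 52.5/0.35/0.21),
ulceration/perforation (Burman et al.: stomach 65/0.14/0.15),
obstruction/perforation (Burman et al.: small bowel 55/0.16/0.15) and
grade ≥3 GI toxicity (Holyoake et al.: duodenum 299.1/0.51/0.193).  The
duodenal TD₅₀ values far exceed clinical dose levels; they are kept exactly
as published — the resulting NTCPs are meaningful only for *relative*
technique comparison, which is how the pipeline uses them.  Users can load
additional sets from JSON/YAML without code changes.

## Plan quality

HI uses the RTOG convention `(D2% − D98%)/D50%` with the same inverse
interpolation as D\_v.  CN = CTV95²/(CTV·V95) needs the patient-level 95%
isodose volume, which a target DVH alone cannot supply; the cohort manifest
(and the synthetic generator) therefore carries `v95_body_cc` per plan.
The "no target volume at ≥107% of prescription" goal is checked with a
0.01 cc tolerance, since a discretized DVH never yields an exact zero.

## Paired statistics

The cohort design is paired (every patient planned with both techniques),
so per-metric comparisons use the **exact Wilcoxon signed-rank test**:
zero differences are dropped (and counted in the report), absolute
differences are ranked with midranks for ties, `W` is the smaller of the
positive/negative rank sums, and the exact null distribution of the
positive rank sum is built by dynamic programming over all `2ⁿ` sign
assignments of the *realized* rank multiset — a correct conditional test
in the presence of ties, which off-the-shelf exact implementations refuse.
Ranks are doubled internally so midranks stay integer.  The two-sided p
doubles the lower tail and caps at 1; at n = 9 the smallest attainable
value is 2/512 ≈ 0.0039, which is why strongly concordant nine-patient
cohorts report p = 0.004.  Above 25 informative pairs the normal
approximation is used and flagged.  The test is invariant under increasing
affine transforms of both arms (verified property); it is *not* invariant
under arbitrary monotone transforms, which can reorder absolute
differences.

Cohort summaries use sample SD (n−1).  Relative risk is the **mean of
per-patient ratios** (rival/reference), not the ratio of means — only the
former has a patient-level SD.  ΔNTCP bins follow the convention
≤5 / >5 to ≤10 / >10 percentage points, with 5.0 in the first bin.

## Synthetic cohort: what it emulates and what it does not

The generator stands in for a nine-patient pancreatic-head cohort
(59.4 Gy(RBE) in 33 fractions) whose per-patient DVHs were never published
— only cohort means and SDs.  Each organ's cumulative DVH is a
two-component survival curve: a Weibull "bath" `b·exp(−(D/λ)^γ)` for the
low/intermediate-dose region, truncated at a maximum physically plausible
bath dose (no bath volume above ~55 Gy(RBE); lower caps for kidneys, liver
and spinal cord), plus a probit "hot region" `h·Φ((μ−D)/σ)` abutting the
target near the prescription.  Technique-level parameters were set
analytically so that the cohort-mean V₁₀…V₅₅, D₀.₁cc and mean-dose values
approximate the published photon/proton arm means (e.g. stomach V₁₀ ≈ 45%
photon-like vs ≈ 17% proton-like; duodenum deliberately near-null at
intermediate doses, where the published comparison was non-significant),
then frozen.  Target DVHs are truncated-normal survival curves whose
spread reproduces HI ≈ 0.04 (photon-like) and ≈ 0.07 (proton-like), and
conformity volumes reproduce CN ≈ 0.43 vs ≈ 0.58.  The composite
stomach+duodenum structure is the cc-wise sum of the same patient's two
curves, not an independent draw.

Patient-to-patient variability is lognormal on the component fractions and
(damped, at 40% strength — dose percentiles respond exponentially to the
scale, so full-strength scatter there would inflate the high-dose metrics'
cohort SD far beyond the published values) on the Weibull scale, plus a
shared normal shift of the hot-region centre.  Both arms share these
anatomy effects and differ only through technique parameters and a small
independent per-arm jitter, making paired differences positively
correlated — the property that powers the signed-rank test.  Randomness
derives from keyed substreams of one root seed, per patient and per organ,
so adding organs or patients never perturbs existing draws.

What the generator does **not** emulate: real anatomical geometry, dose
falloff physics, scenario perturbations, inter-metric correlations beyond
those induced by the two shared components, and the published cohort's
larger NTCP standard deviations (its patients varied more in hot-region
anatomy than the surrogate family reproduces).  Green tests on synthetic
cohorts therefore demonstrate that the *pipeline* recovers the directional
pattern it was pointed at — significant stomach / small-bowel / composite
NTCP reductions with RR < 1, non-significant duodenum intermediate-dose
differences — not that any clinical cohort behaves this way.

## Problem sizes and numerical choices

Default grids run 0–70 Gy(RBE) at 0.05 Gy (1401 points); a nine-patient
paired cohort generates, analyses and reports in well under a second, and
the 50-seed directional stability check in the test suite takes a few
seconds.  Cumulative↔differential round trips are exact to 1e-9 cc.  Tiny
negative volumes from float noise are clipped on construction.  The exact
signed-rank DP uses int64 counts (exact up to n = 25, where the
distribution has 2²⁵ ≈ 3.4·10⁷ assignments).  Degenerate inputs are
first-class: zero-volume structures raise undefined-value errors at the
metric level but only annotate constraint-audit records; all-zero paired
differences surface as p = NA rows with a note rather than aborting a
cohort run.

## Known limitations

* Fixed RBE 1.1 by assumption; no variable proton RBE modelling.
* No TCP models, no parameter fitting, no confidence intervals on NTCP,
  and no multiple-testing correction across the ~40 reported comparisons.
* The stomach-wall vs whole-stomach contour distinction is whatever the
  DVH file labels; no wall-extraction geometry.
* NTCP values from the shipped parameter sets are for relative plan
  comparison, not absolute risk prediction.
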