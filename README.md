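# ntcpkit

Comparative radiobiological evaluation of rival radiotherapy treatment
plans from their dose-volume histograms (DVHs).

When two planning techniques — say an intensity-modulated photon plan and a
robustly optimized proton plan — are produced for the same patient, the
question that matters clinically is not which plan has prettier isodose
lines but which one carries a lower modeled risk of toxicity for the organs
at risk. `ntcpkit` provides the full chain used for that comparison in
dose-escalated upper-abdominal radiotherapy (e.g. unresectable pancreatic
head cancer, where stomach, duodenum and small bowel wrap around the
target):

* **DVH core** — cumulative/differential conversion, V\_x and D\_xcc metric
  extraction with linear interpolation, mean dose, clinical constraint
  auditing, worst-case envelopes over perturbation-scenario DVHs, and a
  plain-text DVH table format with cohort manifests.
* **Radiobiology** — the linear-quadratic EQD2 conversion
  `EQD2(D) = D·(d + α/β)/(2 + α/β)` with per-fraction dose `d = D/n`,
  the generalized equivalent uniform dose
  `gEUD = (Σᵢ (vᵢ/V)·Dᵢ^(1/n))^n`, and the Lyman–Kutcher–Burman
  normal-tissue-complication-probability model
  `NTCP = Φ((gEUD − TD₅₀)/(m·TD₅₀))`, with a registry of six published
  (TD₅₀, m, n) parameter sets for upper-GI endpoints (gastric bleed,
  ulceration/perforation, bowel obstruction, grade ≥3 GI toxicity).
* **Plan quality** — RTOG homogeneity index `HI = (D2% − D98%)/D50%`,
  conformation number `CN = CTV95²/(CTV·V95)`, prescription coverage flags.
* **Cohort statistics** — exact Wilcoxon signed-rank test (dynamic
  programming over all 2ⁿ sign assignments, midranks for ties), per-arm
  mean ± SD, per-patient ΔNTCP with ≤5 / 5–10 / >10 percentage-point bins,
  and per-patient relative risk NTCP_rival/NTCP_reference.
* **Synthetic cohort** — a seedable generator of paired photon-like /
  proton-like patients whose cohort summary statistics emulate a published
  nine-patient dose-escalation comparison (59.4 Gy(RBE) in 33 fractions),
  so the whole pipeline is testable without any clinical data.
* **Pipeline + CLI** — one call (or `ntcpkit compare`) from cohort manifest
  to a JSON/CSV report of all metric, quality and NTCP comparisons.

## Worked example

```python
import numpy as np
import ntcpkit as nk

# a cumulative stomach DVH: 300 cc organ, dose in Gy(RBE)
dvh = nk.DVH("stomach", "cumulative",
             np.array([0., 10., 20., 30., 40., 50., 55., 60.]),
             np.array([300., 135., 85., 40., 22., 11., 6., 0.]))

dvh.volume_at_dose(50.0, "cc")        # 11.0  (cc at or above 50 Gy(RBE))
dvh.volume_at_dose(50.0, "percent")   # 3.7   (% of the organ)
dvh.dose_at_volume(0.1, "cc")         # 59.9  (hottest 0.1 cc, Gy(RBE))

# LKB NTCP for the gastric-bleed endpoint (Pan parameters: TD50=62, m=0.30,
# n=0.07), after EQD2 conversion for 59.4 Gy(RBE)/33 fx with alpha/beta = 4
scheme = nk.FractionationScheme(total_dose=59.4, fractions=33, alpha_beta=4.0)
params = nk.lookup_parameters("stomach", "pan")
100 * nk.ntcp_from_dvh(dvh, params, scheme)   # 11.73 (% risk)
```

The modeled bleeding risk for this stomach DVH is 11.7%: the 0.07 volume
exponent makes the gEUD track the hottest few percent of the organ
(gEUD ≈ 41 Gy EQD2), which the probit response maps to a probability.

End-to-end on a synthetic paired cohort:

```python
report = nk.run_analysis(nk.generate_cohort(nk.default_spec(seed=1)))
print(report.ntcp_frame().iloc[0])
```

```
organ                stomach
parameters       stomach/pan
metric         gastric bleed
photon_mean            13.05
photon_sd               1.39
proton_mean            11.45
proton_sd               1.03
p                      0.004
significant             True
rr_mean                 0.88
rr_sd                   0.02
delta_le5                  9
delta_5to10                0
delta_gt10                 0
```

Read: across the nine synthetic patients the photon-like arm's mean
gastric-bleed NTCP is 13.05 ± 1.39% against 11.45 ± 1.03% for the
proton-like arm; every patient's risk is lower with protons (exact
signed-rank p = 0.004, the smallest two-sided p attainable at n = 9), the
mean per-patient relative risk is 0.88, and all nine ΔNTCP values are below
5 percentage points.

There is also a CLI:

```bash
ntcpkit simulate --seed 1 --out cohort/        # DVH tables + manifest
ntcpkit compare cohort/manifest.json --out report.json
ntcpkit ntcp patient1.dvh --params stomach/pan
ntcpkit params                                 # list the LKB registry
```

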