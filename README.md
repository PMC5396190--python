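# discload

Does habitual locomotor loading — years of jogging or long-distance
running — leave a measurable signature in the lumbar intervertebral discs
(IVDs), and which *intensity* of loading tracks disc quality most closely?
`discload` is a Python package for the quantitative side of that question.
It is aimed at researchers working with multi-echo spine MRI and raw
hip-worn accelerometry who want a tested, reproducible implementation of:

* **T2 relaxometry** — per-pixel and per-ROI transverse relaxation times
  from multi-echo spin-echo stacks via the log-linear fit
  `ln S(TE) = ln S0 − TE/T2`, so `T2 = −1/slope`;
* **disc morphometry** — rotation of a traced disc to the horizontal
  (principal axis of its second central moments), area / width / mean
  column height, five anterior→posterior subregions of the T2 map (the
  central one is the nucleus measure), trapezoidal slice-area volume, and
  the disc:vertebral-body height ratio as a hypertrophy index;
* **actigraphy** — the mean amplitude deviation
  `MAD = (1/n) Σ |r_i − r̄|` of the resultant acceleration in 5 s epochs,
  6 am day segmentation, non-wear screening (clock-hour SD < 0.024 g),
  valid-day (≥ 10 h wear) and eligibility (≥ 3 valid days) rules, and
  per-subject histograms over 98 log-spaced bins from 0 to 2.5 g;
* **statistics** — Welch t-tests against a non-sport referent with percent
  differences, a group × gender type-II ANOVA, and the bin-wise Pearson
  correlation (with Fisher-z 95 % CIs) between per-bin epoch counts and
  nucleus T2, including identification of the peak intensity band;
* **synthetic data** — spine phantoms with exact monoexponential ground
  truth, gait-like accelerometer days and graded treadmill sessions under
  an explicit speed→MAD calibration, and three-group cohorts with planted
  effects, so the whole pipeline is testable without any data download.

`docs/methods.md` describes the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from discload.relaxometry import DEFAULT_ECHO_TIMES_MS, fit_t2_loglinear
from discload.synthgen import make_treadmill_session, make_histogram_cohort
from discload.actigraphy import treadmill_summary
from discload.stats import binwise_correlation, peak_band

# 1. T2 from an 8-echo decay curve
tes = np.asarray(DEFAULT_ECHO_TIMES_MS)
fit = fit_t2_loglinear(tes, 1000 * np.exp(-tes / 120.0))
print(f"T2 = {fit.t2_ms:.2f} ms, S0 = {fit.s0:.1f}, r2 = {fit.r_squared:.4f}")

# 2. MAD of a synthetic graded treadmill test (first 10 s of each stage dropped)
sess = make_treadmill_session(seed=1)
for s in treadmill_summary(sess.recording, sess.stages):
    print(f"{s['stage']:>7}: MAD {s['mean_mad_g']:.3f} g "
          f"(95% CI {s['ci_low_g']:.3f}-{s['ci_high_g']:.3f})")

# 3. Which intensity band tracks nucleus T2?  (association planted in bins 40-55)
counts, t2, edges = make_histogram_cohort(n_subjects=70, band=(40, 56), seed=1)
curve = binwise_correlation(counts, t2, edges)
lo, hi = peak_band(curve)
print(f"peak band: bins {lo}..{hi - 1} -> {edges[lo]:.2f}-{edges[hi]:.2f} g, "
      f"max r = {np.nanmax(curve.r):.2f}")
```

Output:

```
T2 = 120.00 ms, S0 = 1000.0, r2 = 1.0000
0.5 m/s: MAD 0.185 g (95% CI 0.185-0.186)
  1 m/s: MAD 0.295 g (95% CI 0.295-0.296)
1.5 m/s: MAD 0.405 g (95% CI 0.404-0.406)
  2 m/s: MAD 0.515 g (95% CI 0.515-0.516)
2.5 m/s: MAD 0.625 g (95% CI 0.624-0.626)
  3 m/s: MAD 0.718 g (95% CI 0.718-0.719)
3.5 m/s: MAD 0.796 g (95% CI 0.796-0.797)
peak band: bins 40..55 -> 0.09-0.23 g, max r = 0.55
```

The exact T2 and unit r² confirm the noiseless fit; the treadmill table
shows per-stage intensity rising monotonically with speed, with 2 m/s
ambulation inside the 0.44–0.59 g band and 1.5 / 2.5 m/s below and above
it; and the bin-wise correlation recovers exactly the bin band in which the
generator planted the association with nucleus T2.

A full run — cohort synthesis, phantom imaging, per-subject actigraphy,
statistics, figures and a reproducibility manifest — is one command:

```bash
discload run-all --outdir out/demo --small --seed 7
```

which writes `cohort.csv`, `disc_metrics.csv`, `histograms.csv`,
`group_comparisons.csv`, `anova.csv`, `correlation_curve.csv` and
`figures/`.  Re-running the same config produces byte-identical tables.
Individual stages are available as `discload synth | relax | morph |
actigraphy | stats`.

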