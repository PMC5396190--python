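# Methods

`discload` implements a quantitative pipeline linking habitual locomotor
loading to lumbar intervertebral-disc (IVD) tissue quality: multi-echo T2
relaxometry and disc morphometry on sagittal MR images, a raw-accelerometry
intensity-profiling pipeline based on the mean amplitude deviation (MAD),
and the statistical layer that joins the two.  Because no suitable public
dataset pairs multi-echo spine MRI with week-long raw accelerometry, every
stage is exercised on synthetic inputs with known ground truth; the
generators are first-class, tested code.

## T2 relaxometry

The signal model is monoexponential transverse decay,
`S(TE) = S0 * exp(-TE / T2)`.  T2 is estimated by ordinary least squares of
`ln S` on the echo time TE; the slope is `-1/T2` and the intercept
back-transforms to S0.  The default protocol uses 8 echoes at
15.75–162.75 ms in 21 ms steps.  Choices:

* **Unweighted OLS in log space.**  The simplest faithful reading of a
  "linear fit to the log intensity"; a weighted variant (which would
  down-weight noisy late echoes) is out of scope.
* **Nonpositive intensities** cannot enter the logarithm and are excluded
  pointwise.  A fit needs ≥ 3 surviving echoes — two points give r² ≡ 1,
  which carries no goodness-of-fit information.
* **Nonnegative slopes** mark the fit invalid rather than producing a
  negative or infinite T2; invalid fits stay visible downstream (maps carry
  a `valid` channel and a `fraction_invalid` summary).
* **No Rician bias correction.**  Magnitude MR noise is Rician, which biases
  log-linear fits upward where the signal approaches the noise floor; the
  pipeline deliberately applies no correction, and the phantom generator
  offers a `rician` noise model so the size of that bias can be measured.
* ROI aggregation order is ambiguous in general; both orders are provided.
  `fit-of-means` (default) fits the ROI-mean signal per echo;
  `mean-of-fits` averages valid per-pixel T2s.  They agree exactly on
  uniform ROIs and differ on mixed ROIs because a mean of exponentials is
  not exponential.

## Disc morphometry

Masks are binary, single-component, with row 0 superior and column 0
anterior.  A traced disc is rotated to the horizontal about the principal
axis of its second central moments — moments are deterministic and easy to
validate, whereas interactive tracing tools rarely document their rotation
rule; this is a known divergence surface against any particular legacy
implementation.  The rotation itself is bilinear with a 0.5 threshold,
which preserves area to rasterization tolerance (≈ 2 %).

Measures on the horizontal mask:

* **area** = pixel count × pixel area (default 0.366 mm/px);
* **width** = occupied-column count × pixel size (antero-posterior extent);
* **height** = mean per-column vertical extent.  For rectangles this equals
  the bounding-box height; for lens-shaped discs it is robust to single
  protruding pixels.
* **five subregions**: occupied columns split into 5 contiguous
  anterior→posterior blocks.  When the width is not divisible by 5 the
  remainder columns go to the interior blocks (one each to blocks 2 and 4
  first, the rest to the central block), keeping the anterior/posterior
  annulus blocks unpolluted.  Pixels with invalid fits are excluded from
  block means; a block over 50 % invalid is reported missing.  The
  pixel-count-weighted mean of the five blocks equals the whole-disc mean
  exactly (partition property).  The **nucleus T2** reported downstream is
  the central (3rd) subregion mean.
* **dense profile**: per-column mean T2 linearly interpolated onto a fixed
  100-point grid across the width (for 3-D surface plots).
* **volume** = trapezoidal integration of per-slice areas over slice
  centres, in cm³.  Slice position is cumulative centre-to-centre spacing;
  with 3 mm slices and a 1.5 mm gap that is 4.5 mm.
* **height ratio** = disc height / adjacent vertebral-body height, a
  size-normalised hypertrophy index.  Per-level values are averaged over
  the three slices around the spinous process; a spinous slice at the stack
  boundary is an error rather than a silent 2-slice mean.

## Actigraphy

The resultant acceleration `r = sqrt(x² + y² + z²)` (no smoothing) is
summarised in non-overlapping 5 s epochs by the mean amplitude deviation
`MAD = mean(|r_i - mean(r)|)`, an intensity metric that is invariant to the
constant gravity offset.  Days run 06:00→06:00 (half-open).  Any clock hour
with resultant SD below 0.024 g is non-wear (population SD, so the
strict-inequality boundary is exactly constructible); hours with under half
their samples are unevaluable and count as non-wear.  Days with under 10 h
of wear are dropped; subjects need ≥ 3 valid days to be eligible
(ineligibility is a flag — the histogram is still computed).  Trailing
partial epochs are discarded.

Per valid day, wear-epoch MADs are binned into 98 logarithmically
equidistant bins spanning 0–2.5 g and averaged across days, so bin contents
are *mean wear epochs per day* and sum exactly to the mean daily wear-epoch
count.  Strict log spacing cannot start at 0: the first bin runs 0–0.01 g
and the remaining 97 edges are geometric up to 2.5 g.  The 0.01 g floor is
a named config constant and is the largest single reconstruction
uncertainty in the binning; MADs above 2.5 g fold into the top bin to keep
the conservation property exact.

Graded treadmill sessions (0.5–3.5 m/s in 0.5 m/s stages, 70 s per stage,
optionally followed by jumps) discard the first 10 s of each stage (getting
up to speed), leaving 12 epochs per stage, summarised as mean MAD with a
t-based 95 % CI.

## Statistics

* Runner groups are compared to the non-sport referent with **Welch
  t-tests** (a named switch selects the pooled test) and percent
  differences `100·(group − ref)/ref`.
* The gender dependence of the training effect is tested with a **two-way
  type-II ANOVA** (group × gender interaction); empty cells and saturated
  designs raise informative errors.
* The **bin-wise correlation curve** computes, per MAD bin, the Pearson
  correlation across subjects between bin counts and nucleus T2, with
  Fisher-z 95 % CIs (`tanh(atanh r ± 1.96/sqrt(n−3))`).  Bins with no
  variance across subjects are flagged undefined, not reported as r = 0.
  Spearman is available by flag.  No multiple-testing correction is applied
  across the 98 bins by default — per-bin CIs are reported as-is — with
  Benjamini–Hochberg available as an option.
* The **peak band** is the maximal contiguous run of CI-excluding-zero bins
  containing the strongest |r|; ties break toward lower acceleration so the
  output is deterministic.  All subjects are pooled (no group/gender
  adjustment) by default.

## Synthetic data: what it emulates and what it does not

**Phantoms.**  Regions are geometric primitives (rectangle, ellipse, and an
elliptical annulus so a nucleus can sit inside an annulus without the
regions overlapping) with exact label masks and per-region S0/T2.
Noiseless pixels decay exactly monoexponentially; Gaussian (default) or
Rician noise is added on top.  The default phantom is a mid-sagittal lumbar
column — seven vertebral rectangles and six two-compartment discs tilted by
up to ±6° to mimic lordosis — with nucleus 120 ms > annulus 70 ms >
vertebra 50 ms.  These T2s are plausible generator defaults chosen so
subregion profiles have testable structure, not measured claims.  No motion,
bias field, partial volume or susceptibility artifacts are simulated, so
passing phantom tests validates the estimator chain, not robustness to real
scanner physics.

**Accelerometry.**  Locomotion is a 1 g baseline plus a sinusoid at the
step frequency `f(v) = 1.4 + 0.4·v` Hz with 0.02 g white noise — the
simplest periodic model whose MAD has a closed form (2A/π over whole
periods).  The speed→amplitude calibration is an explicit config object,
fitted once so 2 m/s lands mid-way in the 0.44–0.59 g MAD band with
1.5 m/s below and 2.5 m/s above it; the linear map (0.515 g at 2 m/s,
0.22 g per m/s) is the smallest-complexity curve through those anchors.
Jumps are a half-sine impulse train (4 g peak at 2 Hz) whose MAD sits above
the fastest running stage.  Non-wear is 1 g plus 0.005 g noise (≥ 2× below
the detector threshold); sitting/rest noise (0.06–0.09 g) sits ≥ 2× above
it, so the wear classifier has constructed margins in both directions.
Real accelerometry — impacts, posture changes, device calibration error,
broadband gait harmonics — is far richer; the generator validates the
epoching/binning/screening logic, not human-activity realism.

**Cohorts.**  Three groups (default 24/30/25 subjects) with a gender split;
nucleus T2 drawn per subject around `referent mean × (1 + planted effect)`
with between-subject SD 8 % of the referent mean (120 ms) — this yields
realistic overlap while keeping ≈ +10 % effects detectable at this sample
size.  Default planted effects (+9.2 % jogging, +11.4 % long-distance on
T2; +3 %/+6 % on height ratio) are the magnitudes the pipeline is designed
to detect.  Daily schedules allocate 16 h of wear from 06:00 (night-time
non-wear), with group-specific running bouts (joggers 30 min at 2.5 m/s,
long-distance 60 min at 3.2 m/s, on average).  Per-subject day traces are
rendered lazily, one day at a time, because a week of 100 Hz data per
subject is large and most analyses need only epoch series or histograms.

For correlation studies a histogram-level generator draws per-subject bin
counts log-normally around a smooth decreasing baseline, with a
subject-level total-activity factor on all bins and a latent band factor on
a chosen contiguous band that the outcome shares (association strength
0.8 → in-band r ≈ 0.55 at n = 70).  Setting the association to 0 gives an
exact null for calibration studies.

## Problem sizes and numerical choices

Simulation-backed checks use: 100 cohort replicates for power, 200 for the
null rejection rate, 50 for band recovery, 100 for null calibration of the
correlation curve, 20 seeds for treadmill monotonicity, and 20 synthetic
subject-weeks (at 10 Hz — the epoching logic is rate-agnostic and the MAD
of the gait sinusoid is unchanged well above the Nyquist rate of the
2–3 Hz step frequency) for the conservation property.  Stochastic tests
are derandomised with fixed seeds.  Degenerate inputs fail loudly:
overlapping phantom regions, empty masks, single-slice volumes,
boundary spinous slices, saturated ANOVA designs, speeds outside the
calibration range, and timestamp gaps in CSV traces all raise with
specific messages.

## Known limitations

* The log-bin floor (0.01 g) and the epoch-count (vs time-in-bin) reading
  of histogram contents are reconstruction choices; both are surfaced as
  config options and the raw totals are emitted alongside the per-day means.
* Principal-moment rotation and mean-column height are one defensible
  definition of disc orientation/height among several; rectangle fixtures
  (where all definitions coincide) pin the implementation.
* The gait model puts the entire resultant on the vertical axis; per-axis
  statistics beyond the resultant should not be read off the synthetic
  traces.
* No multi-exponential relaxometry, no B0/B1 correction, no automatic disc
  segmentation (masks are inputs), no activity classification or
  energy-expenditure estimation.
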