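# Methods

## Scope and data model

The package analyzes per-frame landmark tables of a single zebrafish-embryo
ventricle labeled with eight boundary points (`1`–`8`).  Tables follow the
common pose-estimation output dialect: three header rows (scorer /
bodyparts / coords), one leading frame-index column, and `x, y, likelihood`
per body part, as CSV or an equivalent HDF5 table.  The table carries no
timebase, so frames-per-second is user metadata (default 30 fps, matching
the 1-minute recordings the pipeline targets).  Coordinates are pixel
centers with y increasing downward; every derived quantity is a distance or
volume, so only consistency of the convention matters.  An optional
µm-per-px scale converts lengths to µm and volumes to µm³.

## Likelihood filtering

Samples with likelihood below `p_cutoff` (default 0.6, the conventional
tracking threshold) are treated as gaps.  The default policy rebuilds each
gap by linear interpolation between the nearest confident frames of the
same landmark; leading/trailing gaps take the nearest confident value
rather than extrapolating.  A `drop_frame` policy removes whole frames
instead, preserving original frame numbering.  Confident samples are never
altered, which makes filtering idempotent, and per-landmark replacement
counts are recorded on the track.  A landmark confident in zero frames is
unrecoverable and raises rather than fabricating a trajectory.

## Geometry

Axis endpoints are exactly the named landmark pairs: `Ds = |p1 − p5|`,
`Dl = |p3 − p7|`.  No ellipse is fitted to the ring — the remaining four
landmarks contribute only to the centroid, which serves as the drift/jump
diagnostic (slide drift appears as a linear centroid trend, a startled
fish as a single large step).  The ventricle is modeled as a prolate
spheroid with polar diameter `Dl` and both equatorial diameters `Ds`,
giving `V = (π/6)·Dl·Ds²`; for `Dl = Ds` this is the sphere volume, and it
matches Monte-Carlo integration of the ellipsoid indicator to well under
0.5 %.  Rigid motions of the landmark ring leave `Ds`, `Dl`, `V` unchanged;
uniform scaling by `s` scales lengths by `s` and volumes by `s³`.

## Beat segmentation

Diastolic peaks anchor the cycles because end-diastole defines the beat in
the volume formulation.  Detection runs on a lightly smoothed volume trace
(centered moving average, default 5 frames ≈ 167 ms, short against a
≥ 200 ms cycle) using prominence-based local maxima: threshold
`min_prominence_frac` (default 0.3) times the trace's 5th–95th percentile
spread, so detection is invariant to affine rescaling of the volume, with
minimum separation `fps·60/hr_max`.  Defaults bound the physiological band
at 40–400 bpm, a generous envelope around the 120–180 bpm typical of 2–3
dpf embryos.  Two guards handle boundary conditions: the smoothed trace is
padded with one trough-level (5th-percentile) sample per end so edge
peaks keep their full prominence, and if the initial pass shows the
smoothing window exceeds half the median beat spacing (fast hearts), the
trace is re-smoothed with a window matched to the observed rhythm.

End-systole is the raw-volume minimum strictly between consecutive peaks.
EDV, ESV and the short-axis diameters `Dsd`, `Dss` are read from the
*unsmoothed* series at the located frames, so smoothing cannot bias the
measured extremes.  Cycles implying a rate outside the band, or an
inverted EDV/ESV pair, are flagged with a reason and kept — sudden-movement
artifacts stay visible instead of silently vanishing.

### Sub-frame beat timing

Integer-frame peak times quantize inter-beat intervals to 33 ms at 30 fps,
which would swamp the few-millisecond beat-to-beat variability the
Poincaré indices measure.  The refinement must also respect that a heart's
volume waveform *stretches* with each cycle length rather than rigidly
shifting, so fitting the peak samples alone systematically under-responds
to real timing variation.  Each peak's neighborhood (±0.45 cycle) is
therefore resampled onto a phase axis — left of the peak normalized by the
preceding inter-peak period, right by the following one — where the
waveform shape is cycle-length invariant.  The mean phase-space segment is
the template; each beat is matched against it over ±2 frames of candidate
shift with parabolic interpolation of the correlation maximum, and a
second pass repeats the procedure with refined periods and template.
Inter-beat intervals are differences of these refined times; the integer
frames are kept for reading EDV/ESV.

On simulated control recordings this recovers sd1/sd2 within ~10 % at the
preset's tracking-noise level.  At substantially higher noise (landmark
jitter near 2 % of the short axis) the per-peak timing error inherent in a
30 fps, ~6 %-volume-noise trace is several milliseconds, which inflates
measured sd1 regardless of estimator — a measurement-noise floor users
should keep in mind when interpreting small HRV effects; the volumetric
panel (HR, EDV, ESV, EF) remains accurate there.

## Cardiac panel

Per-cycle values are computed first (`SV_i`, `EF_i`, `SF_i`), then averaged
— robust against a single odd beat, while the per-beat table is retained
so a single-beat readout stays recoverable.  `CO = mean(SV)·HR` holds as
an exact panel-level identity.  Heart rate defaults to the
instantaneous-rate average `mean(60/IBI_i)`; a count-based estimator
(`60·N/ΣIBI`) is available since the two differ for irregular rhythms.
The shortening fraction divides by the *systolic* diameter by default,
`SF = (Dsd − Dss)/Dss × 100`, with the conventional diastolic-denominator
form behind `sf_denominator="diastolic"`; the convention used is recorded
in the output because the two differ materially (25 % vs 20 % for
Dsd = 10, Dss = 8).  An optional user-supplied reference volume yields a
normalized stroke volume; it is off by default.  Inverted cycles
(ESV ≥ EDV) raise a named error rather than averaging silently.

## Poincaré HRV

With `d_n = IBI_n − IBI_{n+1}` and `s_n = IBI_n + IBI_{n+1}`:
`sd1 = √(Var(d)/2)`, `sd2 = √(Var(s)/2)`, both with the n−1 variance
denominator for unbiasedness at 1-minute beat counts.  The 0.95-confidence
ellipse is a descriptive overlay centered at (mean, mean), rotated 45°,
with semi-axes `sd2·c` along the identity line and `sd1·c` across it,
`c = √χ²₀.₉₅(2)`; the indices are never fitted to the ellipse.  For i.i.d.
intervals sd1 = sd2 = σ; positive lag-1 autocorrelation makes sd2 > sd1.

## Synthetic beating heart

The generator emulates what the tracker sees, with full ground truth:

- **Rhythm**: inter-beat intervals are an AR(1) Gaussian process around
  `60/hr_bpm` (stationary SD `rr_sd_s`, coefficient `rr_ar1`), floored at
  a resolvable 6 frames/beat.  AR(1) is the minimal process separating
  sd1 from sd2.  The record starts mid-cycle so no peak sits exactly on
  frame 0.
- **Volume waveform**: an asymmetric raised-cosine pulse from `EDV0` down
  to `ESV0` over `systolic_fraction` (default 0.35) of the cycle and back
  — smooth with flat extremes, like a filling curve.
- **Geometry**: `Ds = (6V/(π·ar))^{1/3}`, `Dl = ar·Ds` with aspect ratio
  1.2 (slightly ovoid), landmarks at 45° parametric increments on that
  ellipse, so recomputing `(π/6)·Dl·Ds²` from the noiseless ring returns
  the generator's V exactly.
- **Artifacts**: constant slide-drift velocity; persistent jump
  displacements at chosen frames; i.i.d. Gaussian landmark jitter; and a
  `dropout_rate` fraction of samples given sub-cutoff likelihood plus a
  25 px positional excursion (a momentary mislabel).

Defaults describe a healthy 2–3 dpf embryo: 60 s at 30 fps, 150 bpm,
EDV₀ = 4×10⁵ px³, ESV₀ = 2×10⁵ px³ (EF 50 %), rr SD 10 ms, jitter 0.5 px.
Presets encode treatment phenotypes by direction, not by any published
magnitude: `ethanol_like` (110 bpm, EDV₀ 2.6×10⁵, ESV₀ 1.3×10⁵ — smaller,
slower heart with EF preserved) and `ponatinib_like` (100 bpm, EDV₀
2.4×10⁵, ESV₀ 1.56×10⁵ — additionally depressed EF ≈ 35 % and an
arrhythmic rhythm, rr SD 40 ms, AR(1) 0.5).  Only the signs of the
treatment effects are asserted anywhere.

What the generator does *not* emulate: optical blur and illumination,
correlated (non-Gaussian) tracking error, beat-shape morphology changes,
atrium contamination, or tracking failure modes beyond likelihood
dropouts.  Passing tests therefore demonstrate the correctness of the
analysis given landmark tracks with these statistics, not the accuracy of
any upstream tracker.

## Numerical and design notes

- Filtering uses `np.interp`, which clamps at the record edges (the
  nearest-confident-value rule falls out naturally).
- CSV round-trips write floats as `%.17g` and read with round-trip float
  parsing so tracks survive a write/read cycle bit-for-bit.
- Peak ties on flat maxima resolve to the earliest frame (scipy plateau
  handling with the padded trace).
- Group summaries report SD as blank (NaN) for n = 1 groups, never 0.
- Inferential statistics are deliberately excluded; summaries are
  descriptive n / mean / SD, and panels serialize to JSON/CSV so any
  external stats tool can consume them.
- Problem sizes used in validation: 1-minute records (≈ 150 control
  beats), 10 seeds per recovery/direction check, and 2×10⁶ Monte-Carlo
  samples for the volume oracle — comfortably beyond where the checked
  estimates stabilize.

## Known limitations

- The spheroid model is exact only for a truly spheroidal ventricle; real
  chambers deviate, and the atrium is out of scope entirely.
- sd1 at 30 fps carries the measurement-noise floor discussed above.
- Multi-animal tables and video decoding are out of scope; the pipeline
  starts at the landmark table.
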