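# Methods

## Problem and data model

Optical mapping of an isolated right-atrial (RA) preparation yields a
movie `F(t, r, c)` of dye fluorescence proportional (up to polarity) to
transmembrane potential, typically 100 × 100 px at 0.5–2 kHz. The
quantity of interest per beat is the **leading pacemaker site**: the
pixel where the depolarization wave originates. Plotting each beat's
site on a normalized anatomical axis from the inferior vena cava
(y = 0 AU) to the superior vena cava (y = 1 AU) reveals two discrete
clusters of automaticity — the superior and inferior sinoatrial node
(sSAN/iSAN) — rather than a continuously migrating pacemaker.

A `MovieStack` carries the frames plus `frame_rate_hz`,
`pixel_pitch_mm` and `polarity` (`positive` = depolarization increases
fluorescence; `inverted` = styryl-dye convention, negative-going).
Coordinates are (row, col), 0-based from the top-left; times are ms;
rates are beats/min (HR = 60000 / CL with CL in ms).

## Signal conditioning

1. **Spatial filter** — unweighted k × k box mean per frame, restricted
   to in-mask pixels; windows truncated at edges average only existing
   neighbors. k = 3 for rat-scale fields, 5 for human-scale. A box
   mean (not Gaussian) is used because the operation is defined on a
   pixel neighborhood; it is linear, which tests exploit.
2. **Temporal filter** — Butterworth low-pass (default cutoff 150 Hz,
   within the 150–200 Hz range appropriate for optical action
   potentials), order 3, applied forward–backward (`sosfiltfilt`).
   Zero phase is essential: a causal filter would delay every upstroke
   and bias activation times; the effective magnitude response is the
   squared Butterworth response and DC gain is exactly 1. The order is
   a package default (the operative parameters are the cutoff and the
   zero-phase application); it is configurable.
3. **Normalization** — per pixel, per beat window: `(v − min) / (max −
   min)` after polarity correction, so 0.5 is a well-defined fraction
   of the local amplitude. Pixels whose within-window amplitude falls
   below a floor are flagged invalid instead of being divided by a
   vanishing range. The default floor is 2× a robust per-pixel noise
   estimate (1.4826 × the median absolute deviation of the diastolic
   samples, taken as the frames in the lowest quartile of the pixel's
   range); `amplitude_floor` overrides it.

Order of operations: space → time → segmentation → normalization.
Beat segmentation operates on the filtered, spatially averaged in-mask
trace.

## Beats, activation, leading site

* **Segmentation** — depolarization peaks of the global trace
  (`scipy.signal.find_peaks`, minimum separation `min_cl_ms`, default
  100 ms for rat, 400 ms for human; prominence 0.3 × trace range); each
  beat window runs from the preceding diastolic minimum to the
  following one. Windows whose trace already exceeds the 50% level at
  the window start (truncated upstroke at a recording edge) are
  dropped.
* **AP50 timing** — per pixel, the first upward 0.5-crossing before the
  window's peak, linearly interpolated between the bracketing frames.
  Sub-frame interpolation matters: at 1 kHz a one-frame quantization is
  1 ms, the same order as inter-pixel conduction delays. Taking the
  *first* crossing before the peak resolves noise-induced re-crossings
  deterministically. No crossing → missing value.
* **Leading site** — the earliest valid pixel, subject to neighbor
  validation: at least half of its valid neighbors within
  `neighbor_radius_px` (default 2) must activate within
  `neighbor_tolerance_ms` (default 5 ms) of the candidate, otherwise
  the next-earliest pixel is tested. This is a concrete form of
  "identified from its spatial neighbors" that rejects salt-and-pepper
  outliers. Co-minimal accepted pixels are merged by rounding their
  centroid to the nearest pixel (halves away from zero); if the rounded
  centroid is itself invalid, the nearest accepted pixel is used.
* **Heart rate** — CL from successive peak-to-peak intervals; the first
  beat carries the interval that follows it, every later beat the
  interval that precedes it.
* **SNRT** — sinus node recovery time = first spontaneous activation −
  last pacing stimulus, after a drive train (default 12 pulses at a
  pacing cycle length of 100 ms); no spontaneous beat within the
  timeout → censored, never silently zero.

## Axis projection

`y_au` is the scalar projection of (pixel − IVC) onto the IVC→SVC unit
vector divided by the axis length; `x_mm` is the signed perpendicular
component times the pixel pitch (positive side: axis vector rotated
+90°, i.e. normal `(-u_col, u_row)`). `y_au` is **not clamped** to
[0, 1]: a site projecting beyond the venae cavae is a real signal of
annotation error and must stay visible. A straight segment approximates
the crista terminalis; for curved preparations a `PolylineAxis` through
ordered waypoints is provided (arc-length normalized, nearest-point
projection — which clamps beyond the endpoints by construction).

## Cluster statistics

* **Exact 1-D k-means** — optimal 1-D clusters are contiguous in sorted
  order, so the globally WCSS-optimal partition is found by dynamic
  programming over the sorted values (O(k n²) with prefix sums). This
  replaces Lloyd's algorithm deliberately: no random initialization, no
  local optima, bitwise reproducibility. The cluster with the larger
  center is labeled superior. Clustering is pooled across hearts by
  default (per-heart clustering is a caller choice on subset tables).
* **Normal fits** — sample mean and sd (n − 1 denominator) per cluster;
  singleton clusters report σ = 0 with a warning.
* **Logistic membership vs HR** — P(superior | HR) by maximum
  likelihood (`statsmodels` Logit). When the two labels are perfectly
  separated in HR — the usual case for well-separated clusters — the
  unpenalized MLE diverges, so the fit switches to a ridge-penalized
  likelihood (penalty `0.5·λ·β₁²` on the slope in standardized-HR
  units, λ = 10⁻³ by default, minimized with BFGS) and sets
  `separation_flag`. The penalty bounds the slope while leaving the
  0.5-crossing inside the separating gap.
* **Dominance calls** — per heart, `fraction_superior` = share of beats
  in the superior cluster across all conditions; ≥ 0.95 → sSAN_only,
  ≤ 0.05 → iSAN_only, else dual. The 0.95 threshold operationalizes
  "activity from one region alone under every condition" and is
  configurable.
* **Percent HR change** — 100 × (treated − baseline)/baseline, one
  decimal.

Significance testing (ANOVA and post-hoc comparisons) is out of scope;
the tables written by `summarize_experiment` feed directly into
standard packages.

## Synthetic movie generator

The generator emulates the experiment end to end with exact ground
truth:

* **Propagation** — isotropic constant-velocity (eikonal) wavefront:
  `t(p) = min_f [onset_f + dist_mm(p, f) / cv]`, Euclidean distances
  via the pixel pitch. Published recordings show but do not
  parameterize conduction, so the simplest model with exact
  closed-form isochrones is used. Default conduction velocities:
  0.5 mm/ms (rat), 0.8 mm/ms (human) — typical atrial values.
* **Competition** — foci free-run at condition-dependent intrinsic
  cycle lengths without phase resetting; a firing event within the
  refractory window (default: the template's APD) of an accepted beat
  does not open a new beat, but its wavefront joins the earliest-wins
  minimum for that beat. The winning focus of a beat is the focus whose
  own onset is achieved at its position.
* **Waveform** — stylized optical action potential: linear upstroke
  (rat 5 ms, human 8 ms), exponential repolarization with time constant
  (APD − upstroke)/3 (rat APD 60 ms, human 150 ms), unit amplitude over
  a configurable resting level; inverted polarity flips the deflection.
  The AP50 instant of this template lags the wavefront arrival by half
  the upstroke everywhere, so measured maps equal true fields plus a
  constant — leading sites and isochrone shapes are unaffected.
* **Noise** — i.i.d. Gaussian per pixel per frame, sd = `noise_sd` ×
  amplitude; 0.05 ("low noise") in the benchmark studies. Shot noise,
  photobleaching and motion are deliberately not modeled.

What passing the recovery tests shows — and does not show: the pipeline
is exact on the generator's assumptions (isotropic propagation,
stationary baseline, stereotyped waveform). Real recordings add drift,
motion, heterogeneous conduction and fractionated signals; performance
there is bounded by how far those effects break the AP50 and
neighbor-validation assumptions, not by this test suite.

## Benchmark studies (`pacemap.studies`)

Generator settings are the published rat and human RA values: rat site
clusters 0.80 ± 0.09 AU (superior) and 0.24 ± 0.14 AU (inferior) with
condition HRs 280.90 ± 43.00 (baseline), 192.30 ± 50.15 (ACh-like) and
426.00 ± 57.12 bpm (ISO-like), truncated to the observed 102.47–502.09
range; human clusters 0.90 ± 0.05 and 0.36 ± 0.09 AU over 52.50–118.40
bpm, with inferior sites below ~66 bpm and superior above ~81 bpm.

Problem sizes and grids were chosen for desk-scale runtimes and stated
here as the package's own defaults: 60 × 60 px fields (0.1 mm/px rat →
6 mm; 0.5 mm/px human → 30 mm), axis landmarks at rows 50 → 10 (axis
quantization 0.025 AU/px, zero-mean), 1 kHz rat / 500 Hz human
sampling, ten beats per rendered recording. The rat cluster-recovery
dataset uses 480 beats (240 per cluster), keeping the Monte-Carlo
standard error of a fitted cluster mean near 0.01 AU; the human dataset
uses 120 beats. In the cluster-recovery studies each beat is produced
by its own single-shot focus at a site drawn from the cluster normal
(the beat-to-beat site wander seen experimentally); in the failing-heart
cohort each heart exposes a single free-running focus whose position is
drawn from its region's normal truncated at ±1.5σ — the region's
anatomical extent — so that the ground-truth dominance label is itself
unambiguous. Note one inherent property of the method, visible in the
recovery studies: because k-means reassigns the overlapping tails of
the two site distributions before the normal fits, fitted cluster means
are slightly shrunk toward the boundary (≈0.01 AU for the wider
inferior cluster at these parameters).

## Numerical choices and degenerate inputs

* Movies are float32 on disk (TIFF or raw little-endian + JSON header);
  filtering promotes to float64.
* Determinism: every stochastic step takes a seed
  (`numpy.random.default_rng`); exact k-means and fixed tie-breaks
  (stable sorts, half-away-from-zero rounding, lowest focus index on
  ties) make reruns bit-identical, which the run manifest's SHA-256
  checksums verify.
* Degenerate cases raise rather than guess: empty focus lists, IVC =
  SVC axes, out-of-bounds landmarks, even spatial kernels, cutoffs at
  or above Nyquist, flat traces (invalid pixel, not 0/0), all-invalid
  activation maps, identical values handed to k-means, single-label
  logistic fits, nonpositive baseline HR.
* Beats straddling recording edges are dropped (no complete upstroke in
  the window); the first/last diastolic boundary is the recording edge.

## Known limitations

* No anisotropic or heterogeneous conduction, ionic-current dynamics,
  phase resetting between competing foci, motion artifacts, or
  photobleaching drift in the generator.
* Per-beat min–max normalization is the only detrending; recordings
  with strong baseline drift within a beat need upstream correction.
* The straight (or polyline) axis approximates the crista terminalis;
  no 3-D surface registration.
* Dominance threshold (0.95) and neighbor-validation defaults (2 px,
  5 ms) are operational choices; both are exposed as parameters.
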