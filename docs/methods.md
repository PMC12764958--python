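# Methods

This note documents the models behind `frsom`, the parameters that matter,
the choices made where the design was genuinely open, and what the
synthetic data do and do not establish about real measurements.

## PORH protocols and the hemodynamic model

Two cuff protocols are built in: the long test (2 min baseline, 5 min
arterial occlusion, 3 min rest; marks at 2/7/10 min) and the short test
(1/3/2 min; marks at 1/4/6 min), both sampled at one frame per second by
default (0.5 s supported).

The normalized intensity of a dermal layer over a PORH test is modeled
piecewise (`HemodynamicParams`, `hemodynamic_modulation`):

* **Baseline** `[0, t_b)` — constant 1.
* **Occlusion** `[t_b, t_r)` — exponential decay toward the floor
  `1 − mvc_true` with time constant `occlusion_decay_tau`
  (default **0.25 min**). The default is chosen so the curve settles to
  within 1% of the floor before cuff release under *both* protocols
  (3 min of occlusion demands `tau ≤ 0.65 min`) and so the occlusion-window
  mean — which defines MVIC — stays close to the floor the biomarker
  definitions assume. The residual transient makes the ideal recovered MVC
  `≈ (1 − tau/T_occ) · mvc_true`, i.e. a known ~5% (long) to ~8% (short)
  under-recovery at the default; tests and tolerances account for it.
* **Recovery** `[t_r, T]` — a gamma-variate-weighted blend
  `f(τ) = (1 − g(τ))·b(τ) + g(τ)·piv` between an exponential relaxation
  backbone `b(τ) = 1 + (v_r − 1)·e^{−τ/recovery_tau}` (default
  `recovery_tau` = 1 min) and the peak value `piv = 1/(1 − hr_true)`,
  where `g(τ) = (τ/tp)^α e^{α(1−τ/tp)}` is the unit-peak gamma variate
  (shape `α` = 3). Because `g` peaks at exactly `τ = tp` with `g' = 0`, and
  `b < 1 < piv`, the global maximum of `f` is *exactly* `piv` at
  `t_r + tp` — the three biomarker truths (MVC, HR, TP) are closed-form.

`depth_tp_offset_s` shifts a layer's peak time; deep reticular vessels are
given a negative offset to emulate their earlier peak (≈15 s before the
superficial plexus).

The CVD-group time-to-peak statistics (2.05–2.36 min) exceed the short
protocol's 2 min post-release window; the generator deliberately allows
`tp_true` beyond the recording edge (the observed peak is then clipped at
the final frame). Time-to-peak recovery is therefore only asserted for
long-protocol cohorts.

## Phantoms and the acoustic forward model

Phantoms are voxelized volumes holding a melanin slab (default 0–60 µm,
absorption 2 — melanin is the strongest absorber at 532 nm and serves as
the constant intensity reference) and cylindrical vessels along the slow
axis with per-vessel radius (10–100 µm scale), absorption and layer label.

The forward model (`simulate_raw_scan`) treats every absorbing voxel as a
small uniform sphere of the voxel-equivalent radius. Its ideal pressure
signature is the canonical bipolar **N-shaped pulse** (`p(τ) ∝ −τ` for
`|τ| ≤ a/c`, amplitude ∝ radius), band-limited by a Gaussian transducer
response centered at 50 MHz (σ = 30 MHz over the 10–120 MHz detection
band). Each voxel contributes at its exact time of flight
(distance / speed of sound, deposited with linear sub-sample
interpolation), scaled by absorption, 1/r spherical spreading and the
transducer sensitivity, and is exactly zero outside the 60° acceptance
cone. Superposition makes the model linear in absorption, so large vessels
— rasterized into many voxels — naturally emit the longer, low-frequency
pulses that dominate the 10–40 MHz band, while capillary-scale absorbers
fall into the 40–120 MHz band.

Fixed physical constants (configurable in `AcquisitionGeometry`): speed of
sound 1540 m/s (standard soft tissue), sampling 500 MS/s (≥4× the 120 MHz
band edge; one sample ≈ 3.1 µm of depth), 3 mm element, 30° half-angle,
15 µm fast-axis step, 500 Hz repetition rate. The detector scans in a
plane `focal_depth_mm` (default 2 mm) above the membrane with its focus at
the skin surface.

The **sensitivity field** used both in the forward model and as the
beamforming weight is a Gaussian focal beam (waist 40 µm at the surface
focus, spreading at the acceptance half-angle) inside a hard 30° cone with
cosine apodization toward the cone edge, normalized to unit maximum. The
published description names simulated sensitivity weighting without a
formula; this parametric field reproduces its qualitative structure and is
fully configurable.

Additive measurement noise is white Gaussian on the sinogram. Image-level
experiments default to `noise_sd = 0.002`, ≈30 dB peak signal-to-noise on
the simulated A-lines — the regime of visibly clean raw vessel echoes that
clinical mesoscopy operates in. Profile-level cohorts use `noise_sd = 0.02`
on the normalized intensity profiles.

## Reconstruction

* **Motion correction** substitutes a self-contained surface tracker for
  the published (separately cited, unpublished here) algorithm: per A-line
  first arrival on the signal envelope (relative threshold 0.3 of line
  max), median filter across lines to reject outliers, then a global
  *linear* fit as the reference surface. A local smoother would track the
  low-frequency wander of the motion itself; the two-parameter fit cannot,
  so all per-line jitter is attributed to motion (bounded by `max_shift`).
  Surface curvature beyond a tilt ends up in the shifts, which downstream
  flattening would remove anyway. Correction is refused when >20% of lines
  have no detectable surface.
* **Band filtering** is a zero-phase 4th-order Butterworth (forward-
  backward `sosfiltfilt`): ripple-free pass band, ≥40 dB one octave out.
* **Beamforming** is sensitivity-weighted delay-and-sum on the fixed voxel
  lattice (default 12 × 12 × 3 µm): each voxel sums A-line samples at its
  time of flight (linear sub-sample interpolation) over all positions
  whose angle lies in the acceptance cone, weighted by the sensitivity
  field. Per-position delay/weight tables are precomputed once and reused
  across fRSOM frame series. The image is the magnitude of the analytic
  signal along depth (Hilbert envelope) — nonnegative, consistent with
  intensity MIPs; the pre-envelope sum is exposed for linearity checks and
  oracle comparisons.
* **Dual-band compositing** reconstructs 10–40 MHz and 40–120 MHz
  channels independently (rendered red/green with per-channel percentile
  normalization); 2D fRSOM frames are thin volumes MIP'd over the slow
  axis.

Exact reproduction of the hardware system's printed resolution figures is
out of scope; the beamformer is validated against a brute-force
delay-and-sum oracle and point-source localization instead.

## Segmentation

The skin surface is the first depth where each column exceeds an adaptive
threshold (0.3 of the column maximum — relative, hence invariant to global
intensity scaling), median-smoothed laterally (window 7). Columns are
shifted so the surface maps to depth 0; shifts are kept for inversion.

The published epidermis/dermis separation is an unpublished in-house
algorithm, so the boundary here is defined reproducibly: `d_ep` is the
depth where the laterally-averaged intensity falls below 0.5 of its
superficial (melanin-band) peak, constrained to a plausible 60–200 µm
range with a 100 µm fallback (warning). The SD/RD split is a fixed,
configurable 200 µm below the EP boundary — consistent with the anatomy
the instrument resolves over ~1.5 mm depth, but *not* a claim about the
original authors' split; depth-stratified tests therefore validate against
the generator's own layer labels, not anatomical truth.

## Biomarker extraction

Window means (MVB, MVIC) use the raw profile; MVIC spans the full
occlusion window exactly as defined, even though the early occlusion phase
is transient (users can restrict the window). The peak search is
restricted to strictly after cuff release with earliest-time tie-breaking,
and runs on a centered 15 s moving average: the raw maximum of hundreds of
noisy frames is an extreme-value statistic that systematically inflates
PIV (and hence HR), while the moving average leaves the physically broad
hyperemic peak essentially unchanged. The peak is then refined by a local
quadratic fit within ±20 s of the argmax: its vertex gives a sub-frame
peak time and a noise-averaged peak height. Both windows are parameters;
0 disables either step and reverts to the literal max/argmax. With the
defaults the residual estimator bias is < 0.2 percentage points in HR and
≈ +2 s in TP at the default noise levels (measured on degenerate-sd
cohorts), far inside the recovery tolerances.

Vessel diameters are FWHM of 1D intensity cross-sections through a
refined local maximum, with edge-median background and linear sub-voxel
interpolation of the half-maximum crossings; a missing crossing yields NaN
(flagged, not raised). A printed worked example in the source material
reports one vessel's dilation as an 18% increment where the quoted
diameters (58 → 69 µm) give 18.97%, rounding to 19; the package reports
unrounded values and nearest-integer rounding only as explicit formatting.

Total blood volume is the count of dermal voxels above `k = 3` robust
background scales (median + 3 × 1.4826·MAD of the deepest 10% of rows —
scale-invariant) times the voxel volume; an intensity-weighted variant is
provided since the published definition does not specify which was used.

Depth-resolved time-to-peak bins the dermis into fixed-size depth bins
(final bin absorbs the remainder) and runs each bin's mean-intensity
profile through the standard extraction.

## Statistics

Normality is assessed per group with Shapiro–Wilk at α = 0.05 (the source
names no specific normality test); both groups normal → classic unpaired
two-sided t-test, otherwise an unpaired test. The nonparametric branch
uses the **Mann–Whitney rank-sum** test: the signed-rank procedure named
in the source text is a paired test and is not applicable to independent
groups; the substitution is recorded in each result's notes. No
multiple-testing correction is applied (matching the original analysis).
Repeatability between aligned repeated profiles is summarized by all
pairwise Pearson correlations and RMSDs.

## What the synthetic data do and do not show

The generator emulates: layer-resolved PORH dynamics with closed-form
biomarker truths; subject-to-subject variation at the published group
means/SDs via truncated (not clipped) normal sampling; melanin/vessel
anatomy at realistic scales; broadband N-shaped acoustics with directivity
and additive noise. It does **not** model acoustic attenuation or
dispersion, optical fluence decay with depth, flow or oxygenation,
heartbeat/breathing motion beyond per-line jitter, or vessel tortuosity.
Passing recovery tests therefore establishes that the *analysis chain* is
unbiased and correctly calibrated under the stated physics — not that the
instrument itself achieves these numbers on human skin.

Cohort recovery tolerances are evaluated on single n = 10 cohorts at
fixed seeds, where the sample mean of the drawn truths itself carries a
standard error of ≈1.4 HR percentage points (0.026 a.u. MVC, 0.12 min
TP); occasional excursions of a single cohort's recovered mean beyond a
±2-point band around the *configured* mean are expected behavior of the
draw, not extraction error — the per-subject truths are recovered to
< 0.5 percentage points.

## Problem sizes

Unit and property tests run on deliberately small instances (≤ 64-voxel
lateral grids, ≤ 21 scan positions, single-vessel phantoms); the
image-level depth-lag experiment uses a 1.5 × 1.5 mm cross-section at
24 × 12 µm voxels, 62 scan positions and a 601-frame series at 1 s
spacing, chosen to resolve a 15 s depth lag comfortably while keeping a
full run in seconds on one core.
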