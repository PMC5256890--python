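# Methods

This note documents the models behind `spinetrack`: what the virtual
microscope simulates, the parameters that matter and their defaults, the
numerical choices, and what the passing tests do and do not establish
about behavior on real data.

## Focus measures

All 27 operators compute in float64 and return a scalar with the uniform
contract *higher = sharper*, so `best_focus` is a plain argmax with ties
broken toward the stack center (index `n//2`; the center is the previous
best-focus estimate in a tracking loop), then toward the lower index.
The registry stores a `higher_is_sharper` flag per operator; in the
implemented set no operator needed the sign flip, but the mechanism is
kept so an added lower-is-sharper measure composes with the same argmax.

Implementation conventions worth knowing (each documented in its
docstring): Brenner (`BREN`) takes the mean of the larger of the two
squared 2-step differences; `LAPE`/`LAPV` use the 4-neighbor Laplacian
kernel; the DCT measures use non-overlapping blockwise orthonormal
DCT-II (block 8, adaptive for smaller frames) with `DCTE` = mean AC
energy and `DCTR` = mean total/DC energy ratio; window sizes (`GLLV`,
`HELM`: 7), Gaussian scales (`GDER`, `SFIL`: σ=1) and the `GRAT`
threshold (0) are registry defaults overridable per call. Filters use
replicate borders. `MGRD` is the maximum central-difference gradient
magnitude; `BRGT` the maximum intensity.

## Relative-accuracy metric

`acc = 100·(1 − |z_sel − z_tgt|/d_max)` with
`d_max = max(z_tgt, n−1−z_tgt)`, the distance from the target to the
farther stack end. The formula is fixed by its three calibration
anchors: 100 at the target, 0 at the maximally distant slice, and a 50%
average for a continuous uniform selection when the target is centered
(for a centered target, `E|u − c| = (n−1)/4 = d_max/2`). Positions may
be fractional, which is how the random-selector anchor is evaluated
directly; per-stack scores are standardized first and then averaged
arithmetically across stacks. Benchmark timings come from a monotonic
clock and are reported per slice; they are informational only.

## Drift estimation

The estimator is raw circular cross-correlation computed in the Fourier
domain, corner-to-center reordering, argmax minus the center index
`(H//2, W//2)` — integer-pixel output by construction, ties broken
toward the smallest row then column. No spectral whitening and no mean
subtraction by default (a `subtract_mean` flag exists for bright,
slowly-varying backgrounds). The returned pair is the displacement of
the new frame relative to the reference; `corrective_shift` negates it.

Noise behavior, measured on the phantom's dendrite frame with additive
Gaussian noise and no offset: exact recovery of all shifts ≤ 5 px in
≥ 99% of 1,000 trials at peak SNR 8, and recovery within 1 px in ≥ 99%
at peak SNR 5. At peak SNR 5 the *exact*-pixel rate is only ~80%: with
the in-focus blur at σ ≈ 1.5 px, the correlation drop between adjacent
lags is small, and the frame-wide noise×noise correlation floor
(standard deviation ∝ σ²√N) can exceed it, producing single-pixel
errors. These are harmless to the closed loop (the next cycle absorbs
them) but they bound what "exact recovery under noise" can promise.

## Uncaging targeting

Perimeter membership uses 4-connectivity (a foreground pixel with a
4-neighbor that is background or off-frame), which yields a closed
8-connected boundary curve. Relocation minimizes Euclidean distance,
ties toward the smaller row then column, over the perimeters of *all*
objects in frame. Thresholding is absolute by default with a
fraction-of-max mode; in relative mode a frame with zero maximum gives
an empty mask (a lost spine) instead of selecting everything. Depth
modulation interpolates pulse duration 4→8 ms and power 3.5→4.0 mW
linearly over the configured depth range (clamped outside), 30 pulses at
1 Hz; the linear form is the simplest monotone choice between the two
documented endpoints.

## Scheduler

All semantics run on a virtual clock (times rounded to 1 ns) so logs are
bit-identical across repeats; a wall-clock driver with the same queue
logic exists for live use. Imaging timers fire at
`start, start+period, …` while `t ≤ start+duration` (inclusive end);
uncaging timers fire once. Same-tick firings enqueue in position
definition order. The activation timer ticks every 0.1 s, executes the
queue head, and pauses until completion — long actions delay but never
drop later firings. Rotation admits the first `capacity` positions at
t = 0 and each waiting position one tick after the earliest-finishing
active position's final firing; deleted waiting positions are never
admitted.

## ETL calibration

Calibration points are (drive current mA ∈ [0, 300], focal Z µm)
collected by stepping a Z motor and autofocusing with the ETL alone.
Z(control) is fit by least squares, linear or polynomial (default
degree 3); the fit must be strictly monotonic over the spanned control
range (checked on a 512-point grid) or it is rejected as uninvertible.
Inversion uses the exact linear formula or Brent root-finding at machine
tolerance, giving round-trips below 1e-6 µm. Tilted-plane imaging is
parameterized as ΔZ per scanline rather than an angle (the angle form
has a tangent singularity near 90°; ΔZ/line maps directly to the
per-line control update) and every line's Z must stay inside the
calibrated range. A single abstract "control value" axis in mA is used
throughout.

## Quantification

"Volume" is integrated fluorescence: stacks are sum-projected and ROI
integrals taken by pixel-center containment (deterministic and
resolution-independent). Background subtraction — mean of a
structure-free background ROI times the target ROI's pixel count — is
off by default in `integrate_roi` but used by the packaged pipelines,
because a uniform detector/autofluorescence offset otherwise dilutes
the normalized change. Each object is normalized to its own
pre-uncaging mean (all samples at t < 0 by default). Phase statistics
are the mean normalized change (V/V0 − 1; the tidy output also carries
V/V0) over the closed windows [1, 3] and [26, 30] minutes, compared
between groups with two-tailed pooled-variance (Student) unpaired
t-tests — the plain reading of "unpaired t-test"; Welch is a one-line
change if group variances are expected to differ.

## The virtual microscope

The phantom is quasi-planar: a dendrite (cylinder along the image x
axis, radius 0.5 µm) with spines (spherical heads, radius 0.3 µm, on
0.04 µm-radius necks, 1.5 µm long) all in one focal plane. Rendering
integrates fluorophore path length through each structure at every
pixel on a 5×5 subpixel grid, so a sphere's total rendered mass tracks
(4/3)πR³ to well under 1% regardless of where its rim lands on the
pixel grid. The dendrite's brightness is modulated along its axis by a
seeded sinusoid mixture (relative std 0.5, ~0.3 µm scale, normalized so
the texture dims below the nominal intensity rather than creating hot
spots): real GFP fills are strongly textured by varicosities and uneven
expression, and a perfectly uniform cylinder would make registration
along its own axis ill-posed. The texture is a function of the specimen
coordinate, so it drifts rigidly with the structure.

Defocus applies a normalized Gaussian blur of width
σ(d) = σ0·√(1 + (d/z_half)²) with σ0 = 0.15 µm (≈ 0.35 µm FWHM lateral
PSF at 0.1 µm/px) and z_half = 0.5 µm (blur roughly doubling within a
micron of defocus, as for a high-NA objective). Blurring uses periodic
boundaries, which conserves total intensity exactly and matches the
circular-shift model of the drift estimator. Default frames are
128×128 px at 0.1 µm/px; default stacks 7 slices at 0.5 µm.

Noise: `shot_noise_for_snr` is the default acquisition model —
two-photon detection is photon-limited, so "peak SNR s" means
photon_scale = s²/peak (s² photons at the brightest pixel) plus a 5%
autofluorescence offset; dark pixels are then nearly noise-free, as in
a real PMT image. `read_noise_for_snr` provides the additive-Gaussian
alternative with a 3σ detector offset; the offset matters because
intensities are clipped at zero, and clipping an offset-free Gaussian
creates a signal-dependent bias that contaminated both quantification
and Laplacian-based focus values in early versions of the simulator.

Plasticity: the stimulated spine's volume factor is 1 before uncaging
and 1 + A_sust + A_trans·e^(−(t−t0)/τ) after (defaults A_trans = 2.0,
τ = 1.5 min, A_sust = 0.6 — a ~3.6× transient peak relaxing onto a
~1.6× sustained enlargement). The factor scales the whole spine's
fluorescence: head radius ∝ v^(1/3) about a fixed center and neck
radius ∝ v^(1/2). Scaling only the head (with its center pushed outward
by the growing radius) makes the measured ROI change systematically
under-read the generative factor by ~10% — the constant neck mass and
the moving center dilute the ROI ratio — so the whole-spine convention
is what keeps "volume factor" identical to "factor on the measured
integral", which is the quantity the quantification pipeline estimates.

Drift is a per-axis random walk (σ per frame) plus optional linear
creep, advanced once per imaging event; all randomness flows from one
session generator, so a seed reproduces a dataset bit-for-bit.

## Closed-loop sessions

Per imaging event: acquire a stack around the current Z estimate →
argmax focus (update Z) → estimate lateral shift of the in-focus slice
against the position's reference → apply the integer corrective scan
shift → sum-project and integrate ROIs. References are captured at
position definition and never updated (re-baselining would let the
reference itself drift; a flag enables it). If the estimate reaches the
half-frame aliasing bound of circular correlation, the runner re-aligns
once against a zoomed-out reference (same frame size, 2× coarser
pixels, hence 2× the reach). Per uncaging event: relocate the target on
the current frame and log depth-modulated parameters; three consecutive
relocation failures mark the spine lost and drop the position. Default
session noise is shot-noise at peak SNR 20; imaging actions take 1 s,
uncaging 30 s (the 30-pulse train at 1 Hz).

Under the default conditions (random-walk drift σ = 0.15 µm/frame ≈
1.5 px/frame, one frame per simulated minute for 50 minutes), ≥ 90% of
100 seeded runs end within 2 px lateral and one focal step (0.5 µm) of
ground truth; typical residuals are well under a pixel because each
cycle re-zeros the integer part of the error.

## Problem sizes used by the test suite

Simulated experiments are sized to what the guarantees need: 30–50
annotated 7-slice stacks for the autofocus checks, 1,000 trials per
noise level for drift robustness, 100 seeded 50-minute runs for
closed-loop tracking, a 24-spine cohort (26 time points each: every
minute through +10 min, every 2 min thereafter to +30 min) for
quantification recovery, and 1,000 randomized plans for the scheduler
invariants. The whole suite completes in a few minutes on one CPU.

## Known limitations

- The specimen is quasi-planar: axial structure enters only through
  defocus blur, so axial drift moves the best-focus slice but never
  changes the in-focus image content. There is no photobleaching,
  no aberration model, and no excitation-physics model.
- The Gaussian defocus blur is not a physical two-photon PSF; it is
  chosen to give every focus operator a smooth monotonic response.
  Operator *rankings* on synthetic stacks (e.g. LAPE's collapse under
  noise at this sampling, where the Laplacian signal of σ≈1.5 px-smooth
  images sits far below the noise-induced energy floor) should be read
  as properties of this regime, not as universal orderings — which is
  precisely why the operator-selection benchmark is part of the tool.
- Quantification recovery carries a small systematic (−3 to −5%)
  from ROI capture losses and residual dendrite leakage into the spine
  ROI; passing the ±10% recovery check on synthetic cohorts does not
  certify unbiasedness on real morphologies, where ROI placement
  dominates.
- Drift correction is integer-pixel and lateral-only by design (axial
  correction is the autofocus loop); true drifts beyond half a frame
  alias and are handled only by the zoomed-out fallback.
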