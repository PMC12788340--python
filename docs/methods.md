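# Methods

## The synthetic sprint model

A trial emulates a maximal 10 m fly: a 10 m approach, a 10 m measurement
zone instrumented with force plates, and an overrun. The centre of mass
(COM) moves forward with

v_x(t) = v_peak · u(t) + A_s · u(t) · sin(2π·g·t),   u(t) = 1 − e^(−t/τ),

where g = 2·f_stride is the step frequency (two steps per stride cycle).
The COM oscillates vertically with amplitude A_z at the same step
frequency. Positions are the closed-form integrals, so velocity,
acceleration and position are mutually consistent to machine precision and
the generator can report exact ground truth at any instant.

Each foot alternates stance and swing: stance lasts duty_factor × stride
period, feet are offset by half a stride period, the stance foot is planted
at the COM position of mid-stance, and swing is a cosine-eased forward
translation with a sinusoidal vertical arc. During each stance the foot's
force plate records a vertical GRF bump

F(s) = F_peak · sin(π·s)^q,  s ∈ (0, 1),

exactly zero outside stance. The exponent q = 0.5 gives the steep loading
rate of sprint ground contact; with the default F_peak = 2.2 body weights
the 50 N detection threshold is crossed within ~0.1 ms of true stance
onset, so threshold-based event detection is limited only by the 1000 Hz
force-plate sampling (≤ 1 ms). A smoother bump (e.g. sin², peak force
unchanged) would cross 50 N only ~7 ms after onset — a property of the
bump shape, not of the detector — and was rejected for that reason.

Markers (COM, per-foot device and toe markers) are sampled at 100 Hz with
isotropic Gaussian noise (default 1 mm, typical of a calibrated capture
volume); GRF at 1000 Hz, noise-free.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| v_peak | 7.8 m/s | plateau speed of a trained field-sport athlete |
| τ | 1.2 s | reaches ~85 % of v_peak at zone entry after a 10 m approach |
| f_stride | 2.11 Hz | stride period 0.474 s, cadence ≈ 127 strides/min |
| duty_factor | 0.25 | ~0.12 s ground contact, sprint-like |
| A_s | 0.25 m/s | intra-step braking/propulsion speed fluctuation |
| A_z | 0.02 m | COM vertical oscillation, small at sprint speeds |
| body weight | 700 N | ~71 kg athlete |
| marker noise | 1 mm | optical mocap residual |

Cohorts draw per-participant ability (v_peak sd 0.6 m/s, f_stride sd
0.06 Hz, τ sd 0.08 s, duty sd 0.01, body weight sd 90 N) once per
participant plus ~1 % within-participant trial-to-trial jitter. These are
simulator choices representative of a mixed elite/sub-elite field-sport
cohort, not estimates of any particular study population.

### The device error model

The device under test is emulated at its export interface only (10 Hz
velocity/acceleration streams, event-based stride records); its internal
sensor fusion is out of scope. Defaults describe a heavily smoothed
(Kalman-filtered) stream: velocity bias −0.50 m/s with scale 1.0 and white
noise sd 0.05 m/s, acceleration noise sd 0.30 m/s², a 0.30 s stream lag,
5 ms event-timing jitter, and stride length bias −0.07 m with noise sd
0.12 m. The small default velocity noise reflects that a drift-corrected
inertial pipeline outputs a smooth trace whose error is dominated by the
systematic component; experiments that need a specific noise level (e.g.
the 0.30 m/s white-noise recovery experiment) set it explicitly. Criterion
and device randomness come from independent streams, so changing the error
model never changes the underlying gait.

## Event detection and stride metrics

Foot strike = first sample at/above 50 N after ≥ 20 ms below; toe-off =
first subsequent sample below 50 N sustained ≥ 20 ms. The 20 ms debounce
suppresses threshold chatter and is far below any sprint contact time.
Strides pair consecutive ipsilateral foot strikes. Stride length is the
straight-line horizontal displacement of the foot-mounted marker between
the two strike frames (nearest 100 Hz frame to each 1000 Hz event time);
for straight-line sprinting this equals the cumulative per-step
displacement. Zone entry is the first frame the leading toe reaches 0 m;
exit the first frame the trailing toe reaches 10 m. Note the COM travels
slightly more than 10 m between those events (by the toe lead/lag at each
boundary, ~0.7–1.3 m in this geometry); transit time × mean velocity
equals the COM displacement between the event frames, not the nominal
zone length.

## Criterion signal processing

COM velocity components come from central differences of the COM marker
(interior: (x_{i+1} − x_{i−1})/2Δt; endpoints: first-order one-sided, so
the series keeps its length and time base for synchronization), combined
into the resultant magnitude. Filtering is zero-phase (forward–backward)
Butterworth; the design cutoff is raised by (√2 − 1)^(−1/(2m)) per pass of
order m so the cascade's −3 dB point lands on the nominal cutoff and the
effective order is the nominal 4. Phase distortion would shift event
timing, hence zero-phase.

The cutoff is selected by Winter's residual analysis: RMS(raw − filtered)
over 33 candidates in [4, 20] Hz, a straight line fitted to the
noise-dominated upper region (default 0.75–1.0 × fc_max, config-exposed)
and extrapolated to 0 Hz as the noise estimate; the chosen cutoff is the
smallest candidate whose residual does not exceed that estimate, clamped
to the range. Two caveats are documented rather than hidden: (i) for a
noiseless band-limited signal the extrapolated floor is ~0 and the rule
selects the cutoff at which passband distortion vanishes rather than the
range minimum; (ii) velocity obtained by differentiation has an ω-shaped
noise spectrum, which makes the residual curve convex and biases the
linear extrapolation upward, so selected cutoffs sit near the lower clamp
on such signals. By default one global cutoff per quantity is selected
from the trial-averaged residual curve (per-trial selection is a config
switch). Acceleration is the central difference of the filtered velocity,
then filtered at its own selected cutoff.

Marker gaps of ≤ 5 frames are filled by a quintic spline through the six
nearest valid frames on each side (exactly reproducing polynomials up to
degree 5); longer and boundary gaps stay missing and flagged, and strides
whose strike frame is missing are excluded.

## Synchronization

Device series are upsampled 10 → 100 Hz by linear interpolation (original
samples preserved exactly; cubic is a config option). The lag is found by
exhaustive search over integer 100 Hz samples in ±2 s, minimising the RMSE
of the overlap; ties break to the smallest |lag|, then negative. The
pipeline applies two refinements, both config-visible:

- **mean removal per overlap** — with a systematic device offset present,
  raw RMSE trades the offset against the velocity trend and can mis-place
  the lag by over a second on near-plateau data; demeaned (shape-based)
  alignment is immune;
- **full-trace overlap** — the lag objective uses the whole shared trace,
  not just the 10 m zone. The step-frequency ripple is periodic, so
  zone-only alignment leaves one-step-period ambiguities under noise
  (lag sd ~0.5 s at 0.30 m/s noise); the steep approach-phase slope
  resolves them (lag sd ~0.02 s under the same noise). Statistics still
  use in-zone data only.

Stride records are matched greedily by nearest event time (the completing
foot strike), same foot required, within a 100 ms tolerance (≈ a quarter
stride; config-exposed, since the original workflow matched manually).

## Pairing and the agreement battery

Instantaneous velocity/acceleration pairs are taken at the device's native
10 Hz instants inside the zone (criterion read at the nearest 100 Hz
frame): interpolated samples are not independent measurements, and pairing
on the upsampled grid would understate the device's noise and shrink the
limits of agreement. Peak velocity is each system's maximum inside the
zone. Differences are device − criterion throughout (negative bias =
device underestimates).

LoA use the plain 1.96 multiplier (no small-sample t correction). The
first-trial mode keeps each participant's earliest trial and collapses it
to one row per participant (within-trial means of each system) so the
repeated-measures correction is exact. The log-ratio Bland–Altman excludes
pairs with either value ≤ 10⁻⁶ in the variable's units (counted and
reported); it is disabled for instantaneous acceleration, whose negative
and near-zero values violate the log-ratio assumptions. The normality
screen is Lilliefors-corrected KS by default (moments are
sample-estimated; the uncorrected variant is a switch). The
heteroscedasticity verdict uses a two-sided α = 0.05 on the Spearman
correlation of |d| with pair means. No multiple-testing correction is
applied anywhere. Degenerate inputs (zero-variance margins, constant
differences, constant samples) return flagged/undefined results instead of
raising.

## Problem sizes

The test suite and the acceptance script run the full chain on a
23-participant × 4-trial synthetic cohort (92 trials, ~1400 velocity pairs,
~420 matched strides), calibration checks at n = 10⁵ (LoA coverage) and
2000 × n = 100 (normality screen), chosen so the whole suite completes in
well under a minute per experiment on one core.

## What passing tests do and do not show

The generator produces straight-line, strictly periodic gait with
stationary stance feet, noise-free per-foot GRF, and a device whose errors
are Gaussian and stationary. Passing tests therefore demonstrate that the
analysis chain is correct and recovers known error structure; they do not
certify any real device. Known mismatches with real data: the synthetic
device's acceleration shares the true step ripple with the criterion, so
its rank correlation is far higher than a real IMU's impact-contaminated
accelerometry; the criterion system has no soft-tissue artifact or
labelling error; no trials are lost to hardware dropouts; and left/right
GRF assignment comes from per-foot plates, not from a single mixed trace.
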