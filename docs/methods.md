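# Methods

## Model overview and assumptions

The package implements a single-sensor account of mantis stereoscopic
striking. One binocular neuron, tuned jointly to target size and to
stereoscopic distance, is assumed to gate predatory strikes: its
instantaneous activity `R(t)` is read as a strike probability per unit
time, so the expected number of strikes in a trial is the time integral
of `R`. Everything upstream of the sensor is deliberately minimal:

- **Inputs are kinetic, not contrast-matched.** Each eye's image is
  blurred (ommatidial acceptance), temporally highpassed (lamina cells
  signal change) and squared. Squaring makes the pathway fully
  rectifying: bright-on-dark and dark-on-bright targets produce the same
  neural input `J`, consistent with the observation that mantis
  stereopsis tolerates contrast inversion between the eyes. It also
  permits "false matches" between a leading edge in one eye and a
  trailing edge in the other — the mechanism behind several of the
  model's signature predictions (disparity-dependent size tuning, weak
  responses to uncrossed stimuli under horizontal motion).
- **One sensor, one location.** The receptive fields sit at ±α_pref/2
  about the midline at elevation 0; no population over positions or
  disparities is modelled. Predictions therefore concern targets whose
  trajectory passes over (or near) this single receptive-field pair.
- **Poisson strikes.** Per-trial strike counts are treated as Poisson
  with mean `M_model`, which both defines the fitting objective (a
  pseudo-log-likelihood with constant terms dropped) and drives the
  synthetic-trial generator.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| σ | spatial lowpass SD | 4 px = 0.616° | fixed |
| τ | temporal highpass time-constant | 20 ms | fixed |
| α_pref | receptive-field screen disparity | 15.4° | fitted, bounds [9°, 23°] |
| s_e1 | central excitatory square side | 8.14° | fitted, [3°, 11°] |
| s_e2 | outer excitatory square side | 16.3° | fitted, [11°, 17°] |
| s_i | inhibitory square side | 104.5° | fixed |
| w_e1, w_e2 | excitatory weights per full-res pixel | 6.77e-4, 3.18e-4 | fitted, ≥ 0 |
| w_i | inhibitory weight per full-res pixel | −7.46e-5 | fitted, ≤ 0 |
| b | bias (threshold when negative) | −0.0542 | fitted, ≤ 0 |
| γ | output exponent | 5.05 | fitted, ≥ 0 |

Defaults are the published fitted values; `SensorParams()` reproduces
them. Weights are defined per pixel of the reference raster
(0.154°/px); on coarser rasters the weight map carries the pixel-area
ratio so drives are raster-invariant.

**Time unit of `R`.** The sensor's weights implicitly fix the unit in
which `R` counts strikes. The published worked numbers (peak monocular
drive ≈ 0.35, peak response ≈ 0.11, yet ~0.7 expected strikes over a
0.73 s traverse) are only mutually consistent if `R` is a probability
per simulation timestep, not per second. The package therefore fixes
`STRIKE_TIME_UNIT = 1/300 s` as a model constant: `M_model = ∫R dt /
(1/300)`. Being a constant, it does not change with the simulation
profile in use.

## Stimuli

Stimuli are hard-edged binary disks (a pixel is lit iff its centre lies
inside the disk — no anti-aliasing, matching the binary pixel values of
the experimental displays) on a square canvas whose centre pixel
(index N//2) maps to visual direction (0°, 0°). The binocular pattern
centre moves linearly at 82°/s across a 60° span, advancing V/frame-rate
degrees per monitor frame (1.37° at 60 Hz; the final partial frame is
included, 44 frames in all). Each eye's disk centres are fixed offsets
from the pattern centre: the horizontal disparity split ±α/2, a vertical
disparity split ±Δy/2, and, for the ghost-match geometries, the per-disk
offsets derived from the 2.1 cm baseline parallax (≈ ±6° on screen).
Uncrossed controls are the same stimuli with the eyes' streams swapped
(equivalently, negated parallax). Monocular stimuli are rendered to the
left eye by default; the right-eye choice differs only through half-pixel
raster asymmetry (a test bounds the difference).

Ghost condition C (the configuration with no consistent two-object
interpretation) is under-determined by its qualitative description: the
package places the extra disk of each eye mirrored to the opposite side
at three times the baseline half-separation (left eye {+6°, −18°}, right
eye {−6°, +18°}), which gives the required diverging lines of sight and
a larger within-eye separation than condition B. With the fitted
parameters this reproduces the qualitative suppression of C relative to
A (≈ 0.27 of A, averaged over motion directions) but not the printed
vertical-motion value of exactly zero; with mirror-symmetric layouts
that retain the A pair at ±6°, a near-zero vertical response is
unreachable, because the surround weight is two orders of magnitude
smaller than the drive the A pair delivers (see Limitations).

## Numerical choices

- **Temporal filter.** Bilinear-transform discretisation of
  H(s) = τs/(1+τs): `y[n] = g(x[n] − x[n−1]) + r·y[n−1]` with
  K = 2τ/dt, g = K/(1+K), r = (K−1)/(K+1). At dt = 1/300 s the step
  response tracks the continuous-time exponential (evaluated at the
  bilinear transform's characteristic half-sample offset) to < 2%, and
  converges as dt shrinks (< 0.5% at 1/1200 s).
- **Initial conditions.** The first frame is treated as having been on
  screen since before the traverse (the filter starts in steady state).
  This removes a spurious "appearance" transient that would otherwise
  make polarity invariance fail (a dark-on-bright stimulus steps the
  whole field at t = 0) and would inject artificial responses in
  multi-disk geometries whose disks start near a receptive field.
- **Gaussian kernel support.** The blur kernel is truncated at 2σ per
  side and renormalised. With γ ≈ 5 downstream, predicted strike numbers
  are sensitive to this tail choice; 2σ support reproduces the published
  full-pipeline values markedly better than wider kernels (which leave
  edge profiles slightly shallower and predictions 15–25% lower).
- **Frame advance.** The controlled quantity is target speed: the
  pattern centre advances exactly V/frame-rate degrees per frame and is
  re-rasterised each frame (the nominal "9 px per frame" of the
  reference display is internally inconsistent with its own pixel pitch
  by ~1.5%, which the output exponent would amplify to ~15%).
- **Receptive-field rasterisation.** Square half-sides and centres are
  rounded to whole pixels (≤ 0.08° quantisation at full resolution). The
  same rounding helper feeds the weight-map builder and the fitting
  objective's box sums, so the two routes agree exactly.
- **Simulation profiles.** `FULL_PROFILE` is the reference grid (680 px,
  0.154°/px, 60 Hz frames held 5× at 300 Hz). `REDUCED_PROFILE` (340 px,
  0.308°/px, 50 Hz held 2× at 100 Hz) is used for fitting: it tracks
  full-profile predictions within ~12% with near-uniform scaling at
  ~10× the speed. `COARSE_PROFILE` (170 px, 0.616°/px) is rank-faithful
  but biased ~1.4× high, and is reserved for qualitative sweeps and fast
  tests. Profile sizes were chosen so the default test suite and the
  reproduction script complete at desk scale.
- **Likelihood floor.** Model predictions are floored at 1e-12 before
  the log so the objective stays finite when the model predicts zero
  strikes for a condition with observed strikes.
- **Fitting.** Because pixel rounding makes the objective piecewise
  constant in α_pref, s_e1 and s_e2, numerical gradients vanish and
  quasi-Newton methods stall; the optimiser is bounded Powell search
  (derivative-free), multistart from uniform draws, with a
  tighter-tolerance polish pass from the best start. Half-infinite
  published bounds are realised as generous finite boxes (~1e3× the
  fitted scale); multistart draws come from a narrower documented start
  box around physically plausible drive scales, since uniform draws from
  the full box almost never produce a responsive sensor. Parameters are
  internally rescaled to O(1)–O(10) coordinates.
- **Fit validation.** Refitting at the reduced profile and comparing
  likelihoods is only meaningful if both candidates are scored on the
  same grid: a reduced-profile refit can "improve" on the published
  parameters by exploiting the profile's uniform prediction bias, an
  advantage that disappears (and reverses) when its best candidate is
  re-scored at full resolution. The validation test therefore re-scores
  both parameter sets at full resolution.
- **Synthetic trials.** One integer seed governs a whole dataset;
  per-condition generators are sub-seeded from a CRC of the condition
  descriptor, so draws are independent of design-row order.

## What the synthetic generator does and does not emulate

`generate_synthetic_dataset` reproduces the statistical structure of the
behavioural fitting table: per-condition i.i.d. Poisson strike counts
around model-predicted means at the experimental trial count (68),
aggregated to per-condition means. It does not emulate the spiralling
trajectories of the real experiments (the model is probed with constant-
velocity cardinal trajectories), inter-animal variability, defensive
strikes to large uncrossed stimuli (removed from the real data by the
crossed-minus-uncrossed correction before it reaches this package), or
any overdispersion. Parameter-recovery results therefore show that the
fitting machinery can identify the sensor from data *generated by the
model itself* at behavioural sample sizes — not that the published
parameters are the unique account of the real behaviour.

## Limitations

- The preferred-disparity sensor is single and midline-fixed; behaviour
  driven by eccentric targets or by populations of sensors is out of
  scope.
- Speed tuning is only implicit (through τ); the model is not expected
  to extrapolate across target speeds.
- The vertical-motion prediction for ghost condition C is qualitatively
  (suppressed) but not quantitatively reproduced; its exact stimulus
  layout is not recoverable from the available description.
- The monocular response is small but not arbitrarily so: with the
  fitted threshold and exponent, halving the binocular drive leaves
  ~2% of the optimal response (0.002 vs 0.11 at peak), and integrated
  strike counts behave accordingly.
- Reduced-profile predictions are systematically biased (documented
  above); absolute numbers should be quoted from the full profile.
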