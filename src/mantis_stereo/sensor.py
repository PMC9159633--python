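"""The disparity sensor: binocular receptive fields, drives and strikes.

A single binocular neuron receives from each eye the inner product of the
neural input ``J(x, y, t)`` with a receptive-field weight map built from
three nested concentric squares: a strongly excitatory centre (side
``s_e1``, weight ``w_e1``), a weaker excitatory belt (``s_e2``, ``w_e2``)
and a large inhibitory surround (``s_i``, ``w_i`` < 0).  The two eyes'
fields are mirror-placed at ``x = +/- alpha_pref / 2``, giving the neuron
its preferred screen disparity.  Monocular drives combine as

    R(t) = max(0, v_L + v_R + b) ** gamma

with a negative bias ``b`` acting as a threshold and a steep exponent
``gamma`` sharpening selectivity.  ``R`` is the instantaneous strike
probability per simulation timestep; its trapezoidal time integral (in
units of the reference 3.33 ms timestep, see :data:`STRIKE_TIME_UNIT`) is
the expected number of strikes per trial, ``M_model``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DEFAULT_GEOMETRY, ViewingGeometry, distance_from_screen_disparity
from .early_vision import EarlyVisionParams, highpass_coefficients, spatial_lowpass
from .stimuli import (
    FULL_PROFILE,
    FrameSequence,
    ResolutionProfile,
    StimulusSpec,
    render_disk_frames,
)

__all__ = [
    "SensorParams",
    "ReceptiveField",
    "SensorResponse",
    "STRIKE_TIME_UNIT",
    "build_receptive_field",
    "monocular_drive",
    "binocular_response",
    "expected_strikes",
    "simulate_stimulus",
    "box_bounds",
]

#: Time unit (s) in which the instantaneous response R(t) counts strikes.
#: R is a probability per reference timestep (3.33 ms), so M_model is the
#: time integral of R divided by this constant.  It is a fixed property of
#: the fitted weights, independent of the simulation profile in use.
STRIKE_TIME_UNIT = 1.0 / 300.0

#: Pixel pitch (deg) at which the receptive-field weights are defined.
#: Weights act as a surface density: on coarser rasters each pixel's
#: weight is scaled by the pixel-area ratio so drives are raster-invariant.
REFERENCE_PIXEL_PITCH = 0.154


@dataclass(frozen=True)
class SensorParams:
    """The eight fitted sensor parameters plus the fixed surround size.

    Defaults are the published maximum-likelihood values.  Sizes are side
    lengths in degrees, weights are per pixel of the full-resolution
    raster, ``b`` and ``gamma`` are dimensionless.
    """

    alpha_pref: float = 15.4  # preferred screen disparity, deg
    s_e1: float = 8.14
    s_e2: float = 16.3
    s_i: float = 104.5  # fixed, not fitted
    w_e1: float = 6.77e-4
    w_e2: float = 3.18e-4
    w_i: float = -7.46e-5
    b: float = -0.0542
    gamma: float = 5.05

    def __post_init__(self) -> None:
        if not 0 < self.s_e1 < self.s_e2 < self.s_i:
            raise ValueError("receptive-field sizes must satisfy 0 < s_e1 < s_e2 < s_i")
        if not (self.w_e1 >= self.w_e2 > 0 > self.w_i):
            raise ValueError("weights must satisfy w_e1 >= w_e2 > 0 > w_i")
        if self.b > 0:
            raise ValueError("bias must be non-positive (threshold)")
        if self.gamma <= 0:
            raise ValueError("exponent must be positive")

    def preferred_distance(self, geom: ViewingGeometry = DEFAULT_GEOMETRY) -> float:
        """Simulated distance (cm) matching the preferred screen disparity."""
        return distance_from_screen_disparity(self.alpha_pref, geom)

    def with_(self, **kwargs) -> "SensorParams":
        return replace(self, **kwargs)


@dataclass
class ReceptiveField:
    """Pixel weight map of one eye's receptive field."""

    weight_map: np.ndarray  # (N, N)
    centre: tuple[float, float]  # (x, y) deg, before pixel rounding

    def total_weight(self) -> float:
        return float(self.weight_map.sum())


def box_bounds(centre_px: int, side_deg: float, pitch: float, n: int) -> tuple[int, int]:
    """Inclusive-exclusive pixel bounds of a square region.

    The half-side is rounded to whole pixels; the same rounding is used by
    the weight-map builder and by the box-sum fast path of the fitting
    objective, so the two routes agree exactly.
    """
    half = round(0.5 * side_deg / pitch)
    return max(0, centre_px - half), min(n, centre_px + half + 1)


def build_receptive_field(
    params: SensorParams,
    eye: str,
    pitch: float = FULL_PROFILE.pixel_pitch,
    canvas_size: int = FULL_PROFILE.canvas_size,
) -> ReceptiveField:
    """Weight map for ``eye`` ("left" or "right") on the given raster.

    The left-eye centre sits at ``+alpha_pref/2`` deg, the right at
    ``-alpha_pref/2`` (both at elevation 0), rounded to the nearest pixel.
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    cx = params.alpha_pref / 2.0 if eye == "left" else -params.alpha_pref / 2.0
    c = canvas_size // 2
    ci = c + round(cx / pitch)
    area_scale = (pitch / REFERENCE_PIXEL_PITCH) ** 2
    w = np.zeros((canvas_size, canvas_size))
    for side, value in ((params.s_i, params.w_i), (params.s_e2, params.w_e2), (params.s_e1, params.w_e1)):
        x0, x1 = box_bounds(ci, side, pitch, canvas_size)
        y0, y1 = box_bounds(c, side, pitch, canvas_size)
        w[y0:y1, x0:x1] = value * area_scale
    return ReceptiveField(weight_map=w, centre=(cx, 0.0))


def monocular_drive(J_frame: np.ndarray, rf: ReceptiveField) -> float:
    """Eq-1 drive: inner product of the neural input with the weight map."""
    J_frame = np.asarray(J_frame)
    if J_frame.shape != rf.weight_map.shape:
        raise ValueError(
            f"shape mismatch: J {J_frame.shape} vs receptive field {rf.weight_map.shape}"
        )
    return float(np.vdot(J_frame, rf.weight_map))


def binocular_response(
    v_left: np.ndarray | float,
    v_right: np.ndarray | float,
    b: float = SensorParams().b,
    gamma: float = SensorParams().gamma,
) -> np.ndarray | float:
    """Threshold-exponent combination ``max(0, vL + vR + b) ** gamma``.

    The half-bracket of the energy-model literature is the positive-part
    rectifier, not an integer floor.
    """
    if gamma <= 0:
        raise ValueError("exponent must be positive")
    total = np.asarray(v_left, dtype=float) + np.asarray(v_right, dtype=float) + b
    out = np.power(np.maximum(total, 0.0), gamma)
    return float(out) if out.ndim == 0 else out


def expected_strikes(
    R_series: np.ndarray,
    sample_times: np.ndarray,
    time_unit: float = STRIKE_TIME_UNIT,
) -> float:
    """Expected strikes per trial: trapezoidal integral of R(t) over the
    traverse, expressed in units of ``time_unit``."""
    R_series = np.asarray(R_series, dtype=float)
    sample_times = np.asarray(sample_times, dtype=float)
    if R_series.shape != sample_times.shape or R_series.size < 2:
        raise ValueError("need at least two aligned samples")
    steps = np.diff(sample_times)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError("sample times must be uniformly spaced")
    return float(np.trapezoid(R_series, dx=steps[0]) / time_unit)


@dataclass
class SensorResponse:
    """Time-resolved sensor output for one stimulus presentation."""

    v_left: np.ndarray
    v_right: np.ndarray
    R: np.ndarray
    sample_times: np.ndarray
    M_model: float


def simulate_stimulus(
    spec: StimulusSpec,
    params: SensorParams | None = None,
    ev_params: EarlyVisionParams | None = None,
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    profile: ResolutionProfile = FULL_PROFILE,
    frames: FrameSequence | None = None,
) -> SensorResponse:
    """Full deterministic pipeline: render, filter, drive, combine, integrate.

    Streams the temporal filter state frame by frame instead of
    materialising the filtered stacks, so full-resolution runs stay within
    a few hundred MB.  Numerically identical to composing
    :func:`mantis_stereo.early_vision.compute_neural_input` with
    :func:`monocular_drive`.

    ``frames`` may be supplied to reuse a rendered (or eye-swapped)
    sequence; it must match ``profile``'s raster and frame period.
    """
    if params is None:
        params = SensorParams()
    if ev_params is None:
        ev_params = EarlyVisionParams.for_profile(profile)
    if frames is None:
        frames = render_disk_frames(spec, geom, profile)
    ev_params.check_frame_period(frames.frame_period)

    n = frames.canvas_size
    w_left = build_receptive_field(params, "left", frames.pixel_pitch, n).weight_map.ravel()
    w_right = build_receptive_field(params, "right", frames.pixel_pitch, n).weight_map.ravel()
    (g, _), (_, a1) = highpass_coefficients(ev_params.tau, ev_params.sim_timestep)
    decay = -a1
    hold = ev_params.frame_hold_count

    n_samples = frames.n_frames * hold
    vL = np.empty(n_samples)
    vR = np.empty(n_samples)
    y = np.zeros((2, n * n))
    prev = None  # first frame counts as steady state: no onset transient
    i = 0
    for k in range(frames.n_frames):
        blurred = np.stack(
            [
                spatial_lowpass(frames.left_frames[k], ev_params.spatial_sigma_px).ravel(),
                spatial_lowpass(frames.right_frames[k], ev_params.spatial_sigma_px).ravel(),
            ]
        )
        for j in range(hold):
            if j == 0:
                y = decay * y + (0.0 if prev is None else g * (blurred - prev))
                prev = blurred
            else:
                y = decay * y
            vL[i] = np.dot(y[0] * y[0], w_left)
            vR[i] = np.dot(y[1] * y[1], w_right)
            i += 1
    sample_times = np.arange(n_samples) * ev_params.sim_timestep
    R = binocular_response(vL, vR, params.b, params.gamma)
    M = expected_strikes(R, sample_times)
    return SensorResponse(v_left=vL, v_right=vR, R=R, sample_times=sample_times, M_model=M)
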