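"""Binocular stimulus generation: moving hard-edged disks on a pixel raster.

Every stimulus is a pair of per-eye frame stacks on a square canvas of
binary pixel values, updated at the monitor frame rate.  The *pattern
centre* moves linearly along the motion axis, spanning ``traverse_span``
degrees of visual angle; each eye's disk centres are fixed offsets from it
(the horizontal disparity split of +/- alpha/2, any vertical-disparity
split, and the per-disk offsets of the ghost-match geometries).

Coordinates: pixel ``(i, j)`` (row j = vertical, column i = horizontal) has
visual direction ``x = (i - N//2) * pitch``, ``y = (j - N//2) * pitch``, so
for the standard 680-pixel canvas pixel (340, 340) is (0 deg, 0 deg); the
grid extends half a pixel further to the left/bottom than to the
right/top.  Positive x is rightward on the screen, positive y upward.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    DEFAULT_GEOMETRY,
    DisparitySpec,
    ViewingGeometry,
    screen_disparity_from_parallax,
)

__all__ = [
    "Condition",
    "ResolutionProfile",
    "FULL_PROFILE",
    "REDUCED_PROFILE",
    "COARSE_PROFILE",
    "StimulusSpec",
    "FrameSequence",
    "make_condition",
    "trajectory",
    "render_disk_frames",
    "apply_uncrossed",
    "GHOST_PARALLAX_CM",
]

#: On-screen parallax (cm) of the ghost-match baseline object at 2.5 cm.
GHOST_PARALLAX_CM = 2.1


class Condition(str, enum.Enum):
    """Stimulus presentation mode."""

    SINGLE_CROSSED = "single_crossed"
    UNCROSSED = "uncrossed"
    MONOCULAR_LEFT = "monocular_left"
    MONOCULAR_RIGHT = "monocular_right"
    GHOST_A = "ghost_A"  # one disk per eye, crossed 2.1 cm parallax
    GHOST_B = "ghost_B"  # two disks per eye, zero disparity
    GHOST_C = "ghost_C"  # ghost_A pair plus a diverging second pair
    GHOST_D = "ghost_D"  # one disk per eye on the screen plane


@dataclass(frozen=True)
class ResolutionProfile:
    """Raster and timing grid used for rendering and simulation.

    The full profile reproduces the reference simulation conditions
    (680 px canvas at 0.154 deg/px, 60 Hz frames each held for five 300 Hz
    timesteps).  The reduced profile coarsens both grids for desk-scale
    fitting and prediction sweeps.
    """

    canvas_size: int = 680
    pixel_pitch: float = 0.154  # deg / pixel
    frame_rate: float = 60.0  # Hz
    frame_hold_count: int = 5  # simulation timesteps per frame

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def dt(self) -> float:
        """Simulation timestep (s)."""
        return self.frame_period / self.frame_hold_count


FULL_PROFILE = ResolutionProfile()
#: Fitting profile: half-resolution raster, 100 Hz timestep.  Predictions
#: track the full profile within ~15% with near-uniform scaling.
REDUCED_PROFILE = ResolutionProfile(
    canvas_size=340, pixel_pitch=0.308, frame_rate=50.0, frame_hold_count=2
)
#: Quarter-resolution profile for fast qualitative sweeps; biased high in
#: absolute terms but rank-faithful.
COARSE_PROFILE = ResolutionProfile(
    canvas_size=170, pixel_pitch=0.616, frame_rate=50.0, frame_hold_count=2
)


@dataclass(frozen=True)
class StimulusSpec:
    """Complete description of one binocular presentation."""

    disk_diameter: float  # deg
    disparity: DisparitySpec | None = None
    condition: Condition = Condition.SINGLE_CROSSED
    direction: str = "horizontal"  # or "vertical"
    speed: float = 82.0  # deg / s
    vertical_disparity: float = 0.0  # deg, y_L - y_R
    perpendicular_offset: float = 0.0  # deg, trajectory offset from the midline
    traverse_span: float = 60.0  # deg
    polarity: str = "bright_on_dark"  # or "dark_on_bright"

    def __post_init__(self) -> None:
        if self.disk_diameter < 0:
            raise ValueError("disk diameter must be non-negative")
        if self.speed <= 0 or self.traverse_span <= 0:
            raise ValueError("speed and traverse span must be positive")
        if self.direction not in ("horizontal", "vertical"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.polarity not in ("bright_on_dark", "dark_on_bright"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @classmethod
    def for_condition(
        cls,
        condition: Condition | str,
        disk_diameter: float,
        geom: ViewingGeometry = DEFAULT_GEOMETRY,
        **kwargs,
    ) -> "StimulusSpec":
        """Build a spec for a named condition, filling in its disparity.

        Ghost conditions A and C carry the 2.1 cm crossed parallax; B and D
        are on the screen plane; monocular conditions get zero disparity.
        A ``disparity`` keyword is honoured for single/uncrossed specs.
        """
        condition = Condition(condition)
        disparity = kwargs.pop("disparity", None)
        if disparity is None:
            if condition in (Condition.GHOST_A, Condition.GHOST_C):
                disparity = DisparitySpec.from_parallax(GHOST_PARALLAX_CM, geom)
            else:
                disparity = DisparitySpec.zero(geom)
        return cls(disk_diameter=disk_diameter, disparity=disparity, condition=condition, **kwargs)

    @property
    def duration(self) -> float:
        """Traverse duration (s)."""
        return self.traverse_span / self.speed

    def screen_disparity(self) -> float:
        """Effective screen disparity alpha (deg) of the pattern, after the
        uncrossed sign flip when applicable; 0 for monocular stimuli."""
        if self.disparity is None:
            return 0.0
        alpha = self.disparity.screen_disparity
        if self.condition is Condition.UNCROSSED:
            alpha = -alpha
        return alpha


def make_condition(
    condition: Condition | str,
    disk_diameter: float,
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    disparity: DisparitySpec | None = None,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-eye horizontal disk-centre offsets (deg) relative to the moving
    pattern centre.

    Returns ``(left_offsets, right_offsets)``.  For the ghost geometries the
    offsets are fixed by the 2.1 cm baseline parallax (screen disparity
    ~12 deg, so +/-6 deg about the pattern centre):

    * ``A`` - one disk per eye with crossed parallax: left +6, right -6;
    * ``B`` - both A images shown to both eyes: disks at +/-6 in each eye;
    * ``C`` - the A pair plus a second pair mirrored with diverging lines of
      sight: left {+6, -18}, right {-6, +18};
    * ``D`` - one disk per eye at 0 (screen plane).

    For single/uncrossed/monocular conditions the offsets are the usual
    +/- alpha/2 disparity split of ``disparity`` (zero disparity if omitted).
    """
    condition = Condition(condition)
    if disk_diameter < 0:
        raise ValueError("disk diameter must be non-negative")
    half_ghost = screen_disparity_from_parallax(GHOST_PARALLAX_CM, geom) / 2.0
    if condition is Condition.GHOST_A:
        return (half_ghost,), (-half_ghost,)
    if condition is Condition.GHOST_B:
        return (half_ghost, -half_ghost), (half_ghost, -half_ghost)
    if condition is Condition.GHOST_C:
        return (half_ghost, -3 * half_ghost), (-half_ghost, 3 * half_ghost)
    if condition is Condition.GHOST_D:
        return (0.0,), (0.0,)
    half = 0.0 if disparity is None else disparity.screen_disparity / 2.0
    if condition is Condition.UNCROSSED:
        half = -half
    if condition is Condition.MONOCULAR_LEFT:
        return (half,), ()
    if condition is Condition.MONOCULAR_RIGHT:
        return (), (-half,)
    if condition is Condition.SINGLE_CROSSED or condition is Condition.UNCROSSED:
        return (half,), (-half,)
    raise ValueError(f"unknown condition {condition!r}")


def trajectory(
    spec: StimulusSpec, t: float | np.ndarray, geom: ViewingGeometry = DEFAULT_GEOMETRY
) -> np.ndarray:
    """Per-eye pattern centres ``(x_L, y_L, x_R, y_R)`` in degrees at time(s)
    ``t`` (s) from traverse onset.

    The binocular pattern centre moves linearly from ``-span/2`` to
    ``+span/2`` along the motion axis; the other coordinate is held at
    ``perpendicular_offset``.  Each eye adds the horizontal disparity split
    (+alpha/2 left, -alpha/2 right) and the vertical disparity split
    (+dy/2 left, -dy/2 right).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > spec.duration + 1e-12):
        raise ValueError("time outside the traverse")
    c = -spec.traverse_span / 2.0 + spec.speed * t
    half_alpha = spec.screen_disparity() / 2.0
    half_dy = spec.vertical_disparity / 2.0
    if spec.direction == "horizontal":
        x_c, y_c = c, np.full_like(c, spec.perpendicular_offset)
    else:
        x_c, y_c = np.full_like(c, spec.perpendicular_offset), c
    out = np.stack(
        [x_c + half_alpha, y_c + half_dy, x_c - half_alpha, y_c - half_dy], axis=-1
    )
    return out


@dataclass
class FrameSequence:
    """Per-eye stacks of binary intensity frames plus raster/timing metadata.

    ``target_centre_track`` records the per-frame pattern centre in each eye
    as ``(x_L, y_L, x_R, y_R)`` degrees (disk offsets of multi-disk
    conditions are not included).
    """

    left_frames: np.ndarray  # (T, N, N) in [0, 1]
    right_frames: np.ndarray
    pixel_pitch: float  # deg / pixel
    frame_period: float  # s
    frame_times: np.ndarray  # (T,) s
    target_centre_track: np.ndarray  # (T, 4) deg

    def __post_init__(self) -> None:
        if self.left_frames.shape != self.right_frames.shape:
            raise ValueError("left and right stacks must have identical shape")
        if len(self.frame_times) != len(self.left_frames):
            raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.left_frames)

    @property
    def canvas_size(self) -> int:
        return self.left_frames.shape[-1]

    def axis_degrees(self) -> np.ndarray:
        """Visual direction (deg) of each pixel centre along either axis."""
        n = self.canvas_size
        return (np.arange(n) - n // 2) * self.pixel_pitch

    def swap_eyes(self) -> "FrameSequence":
        track = self.target_centre_track[:, [2, 3, 0, 1]].copy()
        return FrameSequence(
            left_frames=self.right_frames,
            right_frames=self.left_frames,
            pixel_pitch=self.pixel_pitch,
            frame_period=self.frame_period,
            frame_times=self.frame_times,
            target_centre_track=track,
        )

    def export(self, directory: str | Path, stem: str = "stimulus") -> dict:
        """Write per-eye multi-page TIFFs and a JSON metadata sidecar.

        Returns the metadata dictionary.
        """
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for eye, stack in (("left", self.left_frames), ("right", self.right_frames)):
            tifffile.imwrite(
                directory / f"{stem}_{eye}.tif",
                (np.clip(stack, 0, 1) * 255).astype(np.uint8),
            )
        meta = {
            "pixel_pitch_deg": self.pixel_pitch,
            "frame_period_s": self.frame_period,
            "frame_times_s": self.frame_times.tolist(),
            "target_centre_track_deg": self.target_centre_track.tolist(),
        }
        (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))
        return meta


def _rasterise_disks(
    centres: Sequence[tuple[float, float]],
    radius: float,
    axis: np.ndarray,
) -> np.ndarray:
    """Binary frame with 1 wherever a pixel centre lies inside any disk."""
    n = len(axis)
    frame = np.zeros((n, n))
    if radius <= 0:
        return frame
    r2 = radius * radius
    for cx, cy in centres:
        dx2 = (axis - cx) ** 2
        dy2 = (axis - cy) ** 2
        frame = np.maximum(frame, (dy2[:, None] + dx2[None, :] <= r2).astype(float))
    return frame


def render_disk_frames(
    spec: StimulusSpec,
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    profile: ResolutionProfile = FULL_PROFILE,
) -> FrameSequence:
    """Render the full frame sequence for ``spec``.

    One frame per monitor refresh over the traverse (the final partial
    advance is included), hard-edged rasterisation at pixel centres, and a
    blank stack for the unstimulated eye of monocular conditions.
    """
    advance = spec.speed * profile.frame_period
    n_frames = int(np.ceil(spec.traverse_span / advance))
    frame_times = np.arange(n_frames) * profile.frame_period
    track = trajectory(spec, frame_times, geom)
    offsets_l, offsets_r = make_condition(
        spec.condition, spec.disk_diameter, geom, spec.disparity
    )
    # make_condition offsets already include the disparity split, so disk
    # centres are built from the binocular pattern centre (x_c, y_L/y_R)
    # plus the per-disk offsets.
    axis = (np.arange(profile.canvas_size) - profile.canvas_size // 2) * profile.pixel_pitch
    radius = spec.disk_diameter / 2.0
    left = np.empty((n_frames, profile.canvas_size, profile.canvas_size))
    right = np.empty_like(left)
    for k in range(n_frames):
        x_l, y_l, x_r, y_r = track[k]
        x_c = 0.5 * (x_l + x_r)
        left[k] = _rasterise_disks([(x_c + off, y_l) for off in offsets_l], radius, axis)
        right[k] = _rasterise_disks([(x_c + off, y_r) for off in offsets_r], radius, axis)
    binocular = spec.condition not in (Condition.MONOCULAR_LEFT, Condition.MONOCULAR_RIGHT)
    if (left.sum() == 0 and (binocular or spec.condition is Condition.MONOCULAR_LEFT)) or (
        right.sum() == 0 and (binocular or spec.condition is Condition.MONOCULAR_RIGHT)
    ):
        if spec.disk_diameter > 0:
            warnings.warn("disk never intersects the canvas", stacklevel=2)
    if spec.polarity == "dark_on_bright":
        left, right = 1.0 - left, 1.0 - right
    return FrameSequence(
        left_frames=left,
        right_frames=right,
        pixel_pitch=profile.pixel_pitch,
        frame_period=profile.frame_period,
        frame_times=frame_times,
        target_centre_track=track,
    )


def apply_uncrossed(seq: FrameSequence) -> FrameSequence:
    """Swap the left and right frame stacks (the uncrossed control)."""
    return seq.swap_eyes()
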