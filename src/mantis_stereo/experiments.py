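"""Prediction suites: strike-rate grids, response maps, vertical disparity
and ghost-match tables for a fixed parameter set.

Every function here is a pure function of its parameters and the chosen
resolution profile: re-running it reproduces the same numbers exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, DisparitySpec, ViewingGeometry
from .sensor import SensorParams, simulate_stimulus
from .stimuli import (
    FULL_PROFILE,
    Condition,
    ResolutionProfile,
    StimulusSpec,
    render_disk_frames,
)

__all__ = [
    "ResponseMap",
    "size_distance_grid",
    "response_map",
    "vertical_disparity_map",
    "ghost_match_table",
    "BEHAVIOURAL_SIZES",
    "GRID_DISTANCES",
]

BEHAVIOURAL_SIZES = (7.5, 11.25, 16.88, 25.31, 38.0)
#: Distances swept in the size-by-distance grid: the behavioural distances
#: plus nearer probes bracketing the sensor's preferred distance.
GRID_DISTANCES = (1.0, 1.5, 2.0, 2.5, 3.75, 5.63, 10.0)


def _with_average(df: pd.DataFrame, value: str = "M_model") -> pd.DataFrame:
    """Append rows with direction='average' (mean over the two motions)."""
    group_cols = [c for c in df.columns if c not in ("direction", value)]
    avg = df.groupby(group_cols, sort=False, as_index=False)[value].mean()
    avg["direction"] = "average"
    return pd.concat([df, avg[df.columns]], ignore_index=True)


def size_distance_grid(
    params: SensorParams | None = None,
    sizes=BEHAVIOURAL_SIZES,
    distances=GRID_DISTANCES,
    directions=("horizontal", "vertical"),
    crossings=("crossed", "uncrossed"),
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    profile: ResolutionProfile = FULL_PROFILE,
) -> pd.DataFrame:
    """Expected strikes per trial over size x distance x direction x
    crossed/uncrossed, for targets passing over the receptive-field centre.
    Includes direction='average' rows."""
    params = params or SensorParams()
    rows = []
    for crossing in crossings:
        cond = Condition.SINGLE_CROSSED if crossing == "crossed" else Condition.UNCROSSED
        for distance in distances:
            disparity = DisparitySpec.from_distance(distance, geom)
            for size in sizes:
                for direction in directions:
                    spec = StimulusSpec(
                        disk_diameter=size,
                        disparity=disparity,
                        condition=cond,
                        direction=direction,
                    )
                    m = simulate_stimulus(spec, params, geom=geom, profile=profile).M_model
                    rows.append(
                        {
                            "crossing": crossing,
                            "distance_cm": distance,
                            "diameter_deg": size,
                            "direction": direction,
                            "M_model": m,
                        }
                    )
    return _with_average(pd.DataFrame(rows))


@dataclass
class ResponseMap:
    """Instantaneous sensor response on a grid of target directions.

    ``R[j, i]`` is the response as the binocular pattern centre first
    reaches ``(x_c[i], y_c[j])``; for horizontal motion each row is one
    trajectory (time running left to right), for vertical motion each
    column is one trajectory.
    """

    R: np.ndarray
    x_c: np.ndarray
    y_c: np.ndarray
    diameter_deg: float
    distance_cm: float
    direction: str


def response_map(
    params: SensorParams | None = None,
    size: float = 11.25,
    distance: float = 2.5,
    direction: str = "horizontal",
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    profile: ResolutionProfile = FULL_PROFILE,
    half_extent: float = 30.0,
) -> ResponseMap:
    """Sweep trajectories across the visual field and collect per-frame R.

    Grid spacing equals the per-frame advance of the target.
    """
    params = params or SensorParams()
    disparity = DisparitySpec.from_distance(distance, geom)
    advance = 82.0 * profile.frame_period
    offsets = np.arange(-half_extent, half_extent + 1e-9, advance)
    rows = []
    along = None
    for off in offsets:
        spec = StimulusSpec(
            disk_diameter=size,
            disparity=disparity,
            direction=direction,
            perpendicular_offset=float(off),
            traverse_span=2 * half_extent,
        )
        resp = simulate_stimulus(spec, params, geom=geom, profile=profile)
        # response when the pattern centre first reaches each frame position
        per_frame = resp.R[:: profile.frame_hold_count]
        rows.append(per_frame)
        if along is None:
            along = -half_extent + np.arange(len(per_frame)) * advance
    grid = np.asarray(rows)
    if direction == "horizontal":
        return ResponseMap(
            R=grid, x_c=along, y_c=offsets, diameter_deg=size, distance_cm=distance, direction=direction
        )
    return ResponseMap(
        R=grid.T, x_c=offsets, y_c=along, diameter_deg=size, distance_cm=distance, direction=direction
    )


def vertical_disparity_map(
    params: SensorParams | None = None,
    sizes=(11.25,),
    distances=(2.1,),
    dy_values=np.arange(-30.0, 30.0 + 1e-9, 5.0),
    offsets=np.arange(-20.0, 20.0 + 1e-9, 5.0),
    directions=("horizontal", "vertical"),
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    profile: ResolutionProfile = FULL_PROFILE,
) -> pd.DataFrame:
    """Expected strikes as a function of vertical disparity and of the
    trajectory's offset perpendicular to the motion; includes
    direction='average' rows (the zero-offset average rows are the
    vertical-disparity tuning curves)."""
    params = params or SensorParams()
    rows = []
    for size in sizes:
        for distance in distances:
            disparity = DisparitySpec.from_distance(distance, geom)
            for direction in directions:
                for dy in dy_values:
                    for off in offsets:
                        spec = StimulusSpec(
                            disk_diameter=size,
                            disparity=disparity,
                            direction=direction,
                            vertical_disparity=float(dy),
                            perpendicular_offset=float(off),
                        )
                        m = simulate_stimulus(
                            spec, params, geom=geom, profile=profile
                        ).M_model
                        rows.append(
                            {
                                "diameter_deg": size,
                                "distance_cm": distance,
                                "direction": direction,
                                "dy_deg": float(dy),
                                "offset_deg": float(off),
                                "M_model": m,
                            }
                        )
    return _with_average(pd.DataFrame(rows))


def ghost_match_table(
    params: SensorParams | None = None,
    sizes=(11.4, 22.8),
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
    profile: ResolutionProfile = FULL_PROFILE,
) -> pd.DataFrame:
    """Model strike predictions for the four ghost-match geometries.

    A: one disk per eye simulating a single object at 2.5 cm; B: both of
    A's images shown to both eyes (two objects on the screen plane); C: A
    plus a mirrored pair with diverging lines of sight; D: a single disk on
    the screen plane.  Rows for horizontal, vertical and average motion.
    """
    params = params or SensorParams()
    rows = []
    for size in sizes:
        for cond in (Condition.GHOST_A, Condition.GHOST_B, Condition.GHOST_C, Condition.GHOST_D):
            for direction in ("horizontal", "vertical"):
                spec = StimulusSpec.for_condition(cond, size, geom, direction=direction)
                m = simulate_stimulus(spec, params, geom=geom, profile=profile).M_model
                rows.append(
                    {
                        "diameter_deg": size,
                        "condition": cond.value,
                        "direction": direction,
                        "M_model": m,
                    }
                )
    return _with_average(pd.DataFrame(rows))
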