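"""Synthetic behavioural trials: Poisson strike counts from model means.

Observed per-trial strike counts are well described by a Poisson
distribution (variance tracking the mean up to about one strike per
trial), so synthetic datasets for likelihood and parameter-recovery
studies are generated by drawing i.i.d. Poisson counts around the model's
predicted mean for each condition and aggregating back to per-condition
means.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ViewingGeometry
from .fitting import MONOCULAR, BehaviouralDataset, spec_for_row
from .sensor import SensorParams, simulate_stimulus
from .stimuli import REDUCED_PROFILE, ResolutionProfile

__all__ = [
    "TrialTable",
    "sample_strike_counts",
    "generate_synthetic_dataset",
    "table3_design",
]


@dataclass
class TrialTable:
    """Per-trial strike counts with their generating descriptors."""

    table: pd.DataFrame  # columns: condition descriptors, trial, strike_count, seed

    def condition_means(self) -> pd.DataFrame:
        return (
            self.table.groupby(["diameter_deg", "distance", "direction"], sort=False)[
                "strike_count"
            ]
            .mean()
            .reset_index()
        )


def sample_strike_counts(mean: float, n_trials: int, seed) -> np.ndarray:
    """``n_trials`` i.i.d. Poisson(mean) strike counts.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.
    """
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(mean, size=n_trials)


def _condition_seed(seed: int, diameter: float, distance, direction: str) -> np.random.Generator:
    # Sub-seed derived from the condition's content, not its position in the
    # design, so reordering the design leaves every condition's draw intact.
    key = zlib.crc32(f"{diameter:.6f}|{distance}|{direction}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def table3_design(
    sizes=(7.5, 11.25, 16.88, 25.31, 38.0),
    distances=(2.5, 3.75, 5.63, 10.0, MONOCULAR),
    directions=("horizontal", "vertical"),
) -> pd.DataFrame:
    """Condition design shaped like the published fitting grid."""
    rows = [
        {"diameter_deg": s, "distance": d, "direction": motion}
        for d in distances
        for s in sizes
        for motion in directions
    ]
    return pd.DataFrame(rows)


def generate_synthetic_dataset(
    true_params: SensorParams,
    design: pd.DataFrame,
    n_trials: int = 68,
    seed: int = 0,
    profile: ResolutionProfile = REDUCED_PROFILE,
    geom: ViewingGeometry = DEFAULT_GEOMETRY,
) -> tuple[BehaviouralDataset, TrialTable]:
    """Simulate every design condition and draw Poisson trial counts.

    ``design`` needs columns ``diameter_deg``, ``distance``, ``direction``.
    Returns the aggregated dataset (per-condition mean strike counts with
    ``N_trials``) and the underlying trial table.  A single integer seed
    governs the whole dataset through per-condition sub-seeds.
    """
    trial_rows = []
    data_rows = []
    cache: dict[tuple, float] = {}
    for _, row in design.iterrows():
        key = (float(row["diameter_deg"]), row["distance"], row["direction"])
        if key not in cache:
            spec = spec_for_row(row, geom)
            cache[key] = simulate_stimulus(
                spec, true_params, geom=geom, profile=profile
            ).M_model
        mean = cache[key]
        rng = _condition_seed(seed, *key)
        counts = sample_strike_counts(mean, n_trials, rng)
        for t, c in enumerate(counts):
            trial_rows.append(
                {
                    "diameter_deg": key[0],
                    "distance": key[1],
                    "direction": key[2],
                    "trial": t,
                    "strike_count": int(c),
                    "seed": seed,
                }
            )
        data_rows.append(
            {
                "diameter_deg": key[0],
                "distance": key[1],
                "direction": key[2],
                "M_data": float(counts.mean()),
                "N_trials": n_trials,
                "M_true": mean,
            }
        )
    return BehaviouralDataset(pd.DataFrame(data_rows)), TrialTable(pd.DataFrame(trial_rows))
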