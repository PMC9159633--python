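import numpy as np
import pytest

import mantis_stereo as ms


@pytest.fixture(scope="session")
def geom():
    return ms.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def table2_params():
    """Published fitted sensor parameters (the package defaults)."""
    return ms.SensorParams()


def simulate(diameter, distance, direction="horizontal", profile=ms.COARSE_PROFILE,
             condition=ms.Condition.SINGLE_CROSSED, **kwargs):
    """Convenience wrapper: single-disk simulation at a simulated distance."""
    spec = ms.StimulusSpec(
        disk_diameter=diameter,
        disparity=ms.DisparitySpec.from_distance(distance),
        condition=condition,
        direction=direction,
        **kwargs,
    )
    return ms.simulate_stimulus(spec, profile=profile)


@pytest.fixture(scope="session")
def full_res_strikes(table2_params):
    """Expected-strike values at the full simulation profile for the
    published parameters, shared across the acceptance tests."""
    cache = {}

    def get(key):
        if key in cache:
            return cache[key]
        kind = key[0]
        if kind == "single":
            _, diameter, distance, direction = key
            m = simulate(diameter, distance, direction, profile=ms.FULL_PROFILE).M_model
        else:
            _, condition, diameter, direction = key
            spec = ms.StimulusSpec.for_condition(condition, diameter, direction=direction)
            m = ms.simulate_stimulus(spec, profile=ms.FULL_PROFILE).M_model
        cache[key] = m
        return m

    return get
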