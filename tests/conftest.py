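import numpy as np
import pytest

from silentstar.paradigm import ParadigmConfig, generate_schedule
from silentstar.phantom import PhantomSpec, build_phantom, simulate_bold_series

TINY_TR = 2.648
TINY_N_VOLS = 60


@pytest.fixture(scope="session")
def tiny_phantom():
    return build_phantom(PhantomSpec(grid_shape=(16, 16, 16), roi_radius_fraction=0.14))


@pytest.fixture(scope="session")
def phantom32():
    return build_phantom()


@pytest.fixture(scope="session")
def tiny_paradigm_config():
    return ParadigmConfig(
        initial_silence=4 * TINY_TR,
        total_duration=TINY_TR * TINY_N_VOLS + 5.0,
        n_rest_blocks=4,
    )


@pytest.fixture(scope="session")
def tiny_schedule(tiny_paradigm_config):
    return generate_schedule(tiny_paradigm_config, seed=7)


@pytest.fixture(scope="session")
def tiny_ideal(tiny_phantom, tiny_schedule):
    return simulate_bold_series(
        tiny_phantom,
        tiny_schedule,
        TR=TINY_TR,
        TEs=[0.0, 0.0161, 0.0322],
        n_volumes=TINY_N_VOLS,
    )


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(ParadigmConfig(), seed=11)


def cover_schedule(duration, events=()):
    """A schedule covering ``duration`` seconds (zero-length rest marker)."""
    from silentstar.paradigm import Schedule, ToneEvent

    return Schedule(
        events=list(events) + [ToneEvent(duration, 0.0, "rest")], config=None
    )


def point_ideal(shape=(16, 16, 16), value=3.0, n_volumes=2, tes=(0.0, 0.02)):
    """An ideal series whose object is a delta at the grid centre."""
    ph = build_phantom(PhantomSpec(grid_shape=shape, roi_radius_fraction=0.14))
    ph.pd_map[:] = 0.0
    c = tuple(s // 2 for s in shape)
    ph.pd_map[c] = value
    ph.r2star_map[:] = 0.0
    return simulate_bold_series(
        ph, cover_schedule(n_volumes * 1.0), TR=1.0, TEs=list(tes),
        n_volumes=n_volumes, activation_table={},
    )
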