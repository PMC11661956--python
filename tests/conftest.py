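import numpy as np
import pytest

from dynconn.dynamic_fnc import GlassoParams, WindowParams, window_fnc
from dynconn.synthetic import (
    ArtifactSpec,
    BlockSpec,
    CohortSpec,
    ScoreCoupling,
    TransitionModel,
    make_planted_states,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def planted_states():
    """Three well-separated 10-component block states."""
    spec = BlockSpec(
        block_sizes=[3, 3, 4],
        within=[[0.7, 0.7, 0.7], [-0.3, 0.7, -0.3], [0.7, -0.3, 0.0]],
        between=0.05,
    )
    return make_planted_states(3, 10, spec)


@pytest.fixture(scope="session")
def small_cohort(planted_states):
    """6+6 subjects, 200 TRs, mild artifacts, dwell contrast and score coupling."""
    spec = CohortSpec(
        states=planted_states,
        transition_models={
            "EP": TransitionModel.sticky(3, 0.97),
            "HC": TransitionModel.sticky(3, 0.92),
        },
        n_per_group={"EP": 6, "HC": 6},
        n_timepoints=200,
        artifact=ArtifactSpec(noise_sd=0.2),
        coupling=ScoreCoupling(slope=-0.8, intercept=20.0, noise_sd=1.5, name="score"),
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_wfnc(small_cohort):
    """Windowed FNC of the small cohort (penalty 0 for speed)."""
    tcs, _ = small_cohort
    return window_fnc(
        tcs,
        WindowParams(width=30, gauss_alpha=3.0, step=1),
        GlassoParams(penalty_grid=(0.0,)),
        seed=3,
    )


def pytest_configure(config):
    # derandomize property tests so runs are reproducible
    from hypothesis import settings

    settings.register_profile("repro", derandomize=True, deadline=None)
    settings.load_profile("repro")
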