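"""Meta-state decomposition and the four dynamism metrics.

Decomposes pooled windowed FNC into 5 maximally independent connectivity
patterns, discretizes each window's weights into signed quartiles, and
summarizes each subject's trajectory by fluidity (number of meta-states,
number of changes) and range (span, total city-block distance).
"""

from dynconn.dynamic_fnc import GlassoParams, window_fnc
from dynconn.meta_states import MetaParams, discretize_weights, fit_meta_states, metrics_table
from dynconn.synthetic import (
    BlockSpec,
    CohortSpec,
    TransitionModel,
    make_planted_states,
    simulate_cohort,
)

base = [0.7, -0.2, 0.0, 0.4, -0.15]
states = make_planted_states(
    5, 25,
    BlockSpec([5] * 5, [[base[(b + s) % 5] for b in range(5)] for s in range(5)], 0.05),
)
spec = CohortSpec(
    states=states,
    transition_models={
        "EP": TransitionModel.sticky(5, 0.97),  # reduced dynamism
        "HC": TransitionModel.sticky(5, 0.92),
    },
    n_per_group={"EP": 12, "HC": 12},
    n_timepoints=250,
    seed=5,
)
tcs, _ = simulate_cohort(spec)

wfnc = window_fnc(tcs, gparams=GlassoParams(penalty_grid=(0.0,)), seed=1)
model = fit_meta_states(wfnc, MetaParams(model_order=5, seed=2))
print(f"{model.model_order} patterns over {model.patterns.shape[1]} pairs "
      "(unit norm, dominant entry positive)")

trajectories = discretize_weights(model)
table = metrics_table(trajectories, tcs.groups())
print("\nper-group mean dynamism metrics:")
print(table.groupby("group").mean().round(1))
print("\nFluidity (n_meta_states, n_changes) and range (span, total_distance)"
      " are all lower for the stickier EP group - the reduced-dynamism signature.")
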