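"""Discrimination is insensitive to the time-interval layout.

Fits the flexible model to a binary-covariate Weibull cohort (pooled
median 182 days) under four different grids — uniform 1-year, 1-month and
1-week widths, and geometrically widening intervals with a 1-year
half-life — ranking patients by predicted 1-year survival each time.
"""

import numpy as np

import nnsurv as ns

cohort = ns.simulate_weibull_binary(n=5000, seed=9)
max_t = cohort.times.max()
grids = {
    "uniform 1-year": ns.make_uniform_grid(365.0, max_t),
    "uniform 1-month": ns.make_uniform_grid(365.0 / 12, max_t),
    "uniform 1-week": ns.make_uniform_grid(7.0, max_t),
    "half-life 1-year": ns.make_halflife_grid(365.0, np.arange(20) / 20),
}

for name, grid in grids.items():
    surv_s, surv_f = ns.encode_dataset(cohort.times, cohort.events, grid)
    model = ns.SurvivalNetwork(grid, input_dim=1, head="flexible")
    model.fit(cohort.covariates, surv_s, surv_f, ns.TrainingConfig(seed=2, epochs=300))
    S = model.predict_survival(cohort.covariates)
    scores = [ns.survival_at(365.0, ns.StepSurvivalCurve(grid, row)) for row in S]
    c = ns.c_index(scores, cohort.times, cohort.events)
    print(f"{name:18s} ({grid.n:3d} intervals): C-index {c:.4f}")
# All four C-indices agree to the third decimal: the grid layout changes
# the resolution of the predicted curves, not the ranking of patients.
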