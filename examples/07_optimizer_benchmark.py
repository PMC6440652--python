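"""Benchmark harmony search against the GA and PSO baselines.

All three minimize the same weighted-residual objective for k_on/k_off on
one noisy measurement set, with matched evaluation budgets (HS spends one
evaluation per iteration; GA and PSO spend one per population member per
generation).  Lower final fitness at the same budget is better.
"""

import time

import numpy as np

from hsoed import (
    HSConfig,
    generate_measurements,
    ga_minimize,
    hs_minimize,
    make_circuit,
    make_input,
    pso_minimize,
    simulate_trajectory,
    wrsse,
)

model = make_circuit("unbuffered")
inp = make_input("step", 20.0)
meas = generate_measurements(model, inp, 50, seed=0)
idx = [model.kinetic_names.index(n) for n in ("k_on", "k_off")]
ref = np.asarray(model.kinetic_params, dtype=float)
lb, ub = np.array([0.004, 0.002]), np.array([0.1, 0.05])


def objective(theta):
    p = ref.copy()
    p[idx] = theta
    traj = simulate_trajectory(model, inp, meas.times, params=p,
                               rtol=1e-6, atol=1e-9)
    return wrsse(meas.values, traj.states[:, model.observable], meas.stds)


BUDGET = 1500  # objective evaluations per optimizer
runs = {}
t0 = time.time()
runs["HS"] = hs_minimize(objective, HSConfig(
    lb=lb, ub=ub, max_iter=BUDGET, seed=1, hmcr=0.8, par=0.9, hms=10,
    bandwidth_frac=0.2, bandwidth_final_frac=5e-5))
runs["GA"] = ga_minimize(objective, lb, ub, pop_size=50,
                         max_iter=BUDGET // 50, seed=1)
runs["PSO"] = pso_minimize(objective, lb, ub, swarm_size=30,
                           max_iter=BUDGET // 30, seed=1)

for name, res in runs.items():
    print(f"{name:>3s}: best wRSSE {res.best_fitness:10.4g}  "
          f"best (k_on, k_off) = ({res.best_vector[0]:.4g}, "
          f"{res.best_vector[1]:.4g})  [{res.n_evaluations} evals]")
print(f"({time.time() - t0:.0f} s; generating values k_on=0.02, k_off=0.01)")
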