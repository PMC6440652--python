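"""Seedable bounded-box minimizers: harmony search, plus GA and PSO baselines.

Harmony search (HS) keeps a memory of HMS candidate vectors and, each
iteration, improvises one new vector dimension by dimension: with probability
HMCR the value is drawn from the memory (and then pitch-adjusted with
probability PAR by a random amount within the bandwidth); otherwise it is
drawn uniformly from the box.  The new vector replaces the worst memory row
only on strict improvement, so the incumbent-best fitness trace is monotone
non-increasing.

The GA and PSO baselines use the comparison settings of the nested-OED study:
GA with population 50 and rates 0.8/0.2 as printed (note: conventional usage
usually labels these the other way around), PSO with inertia weight 1 and
c1 = c2 = 1.  All three optimizers are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HSConfig", "OptResult", "hs_minimize", "ga_minimize", "pso_minimize"]

#: Preset HMCR values used in the two study contexts: coarse input screening
#: (0.2) and the nested OED loops (0.8).
HMCR_SCREENING = 0.2
HMCR_OED = 0.8


@dataclass
class HSConfig:
    """Harmony-search settings.

    ``grid`` optionally restricts dimensions to discrete candidate values:
    random draws pick a grid point and pitch adjustment moves one grid step,
    which makes HS comparable with exhaustive screening on the same grid.

    ``bandwidth_final_frac``, when set, decays the pitch bandwidth
    geometrically from ``bandwidth_frac`` down to it over the run (the usual
    improved-HS refinement schedule); the default is a static bandwidth.
    """

    lb: np.ndarray
    ub: np.ndarray
    hms: int = 15
    hmcr: float = HMCR_OED
    par: float = 0.2
    bandwidth_frac: float = 0.05
    bandwidth_final_frac: float | None = None
    max_iter: int = 2000
    seed: int | None = None
    grid: list | None = None  # per-dimension array of candidates, or None

    def __post_init__(self):
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape or np.any(self.lb >= self.ub):
            raise ValueError("need lb < ub elementwise")
        if not (0 <= self.hmcr <= 1 and 0 <= self.par <= 1):
            raise ValueError("HMCR and PAR must lie in [0, 1]")
        if self.hms < 2:
            raise ValueError("HMS must be at least 2")
        if self.grid is not None:
            if len(self.grid) != self.lb.size:
                raise ValueError("grid must give one candidate set per dimension")
            self.grid = [
                None if g is None else np.sort(np.asarray(g, dtype=float))
                for g in self.grid
            ]

    @property
    def n_dim(self) -> int:
        return self.lb.size


@dataclass
class OptResult:
    """Outcome of one optimizer run with its incumbent-best fitness trace."""

    best_vector: np.ndarray
    best_fitness: float
    trace: np.ndarray
    n_evaluations: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(len(self.trace)), "best_fitness": self.trace}
        )


def _safe_eval(objective, x, counter):
    counter[0] += 1
    v = float(objective(np.asarray(x, dtype=float)))
    if not np.isfinite(v):
        warnings.warn("non-finite objective value; candidate discarded",
                      RuntimeWarning, stacklevel=3)
        return None
    return v


def hs_minimize(objective, config: HSConfig, incumbent=None) -> OptResult:
    """Minimize ``objective`` over the box [lb, ub] by harmony search.

    ``incumbent``, when given, seeds row 1 of the harmony memory so a
    previously found solution is never lost across restarts.
    """
    rng = np.random.default_rng(config.seed)
    d = config.n_dim
    lb, ub = config.lb, config.ub
    box = ub - lb
    counter = [0]

    def random_value(j):
        if config.grid is not None and config.grid[j] is not None:
            return rng.choice(config.grid[j])
        return lb[j] + (ub[j] - lb[j]) * rng.random()

    memory = np.array([[random_value(j) for j in range(d)]
                       for _ in range(config.hms)])
    if incumbent is not None:
        memory[0] = np.clip(np.asarray(incumbent, dtype=float), lb, ub)
    fitness = np.empty(config.hms)
    for i in range(config.hms):
        v = _safe_eval(objective, memory[i], counter)
        fitness[i] = np.inf if v is None else v

    trace = np.empty(config.max_iter)
    for it in range(config.max_iter):
        if config.bandwidth_final_frac is not None:
            frac = config.bandwidth_frac * (
                config.bandwidth_final_frac / config.bandwidth_frac
            ) ** (it / config.max_iter)
        else:
            frac = config.bandwidth_frac
        bw = frac * box
        x = np.empty(d)
        for j in range(d):
            if rng.random() < config.hmcr:
                x[j] = memory[rng.integers(config.hms), j]
                if rng.random() < config.par:
                    if config.grid is not None and config.grid[j] is not None:
                        g = config.grid[j]
                        idx = int(np.argmin(np.abs(g - x[j])))
                        idx = np.clip(idx + (1 if rng.random() < 0.5 else -1),
                                      0, len(g) - 1)
                        x[j] = g[idx]
                    else:
                        x[j] += bw[j] * (2.0 * rng.random() - 1.0)
            else:
                x[j] = random_value(j)
        x = np.clip(x, lb, ub)
        v = _safe_eval(objective, x, counter)
        if v is not None:
            worst = int(np.argmax(fitness))
            if v < fitness[worst]:  # strict improvement only
                memory[worst] = x
                fitness[worst] = v
        trace[it] = fitness.min()

    best = int(np.argmin(fitness))
    return OptResult(
        best_vector=memory[best].copy(),
        best_fitness=float(fitness[best]),
        trace=np.minimum.accumulate(trace),
        n_evaluations=counter[0],
        seed=config.seed,
    )


def ga_minimize(
    objective,
    lb,
    ub,
    pop_size: int = 50,
    mutation_rate: float = 0.8,
    crossover_rate: float = 0.2,
    max_iter: int = 2000,
    mutation_scale: float = 0.1,
    seed: int | None = None,
) -> OptResult:
    """Real-coded genetic algorithm: tournament selection (size 2),
    arithmetic crossover, Gaussian mutation, elitism of 1."""
    rng = np.random.default_rng(seed)
    lb = np.atleast_1d(np.asarray(lb, dtype=float))
    ub = np.atleast_1d(np.asarray(ub, dtype=float))
    d = lb.size
    sigma = mutation_scale * (ub - lb)
    counter = [0]

    pop = lb + (ub - lb) * rng.random((pop_size, d))
    fit = np.array([np.inf if (v := _safe_eval(objective, x, counter)) is None
                    else v for x in pop])
    trace = np.empty(max_iter)
    for it in range(max_iter):
        elite = int(np.argmin(fit))
        new_pop = [pop[elite].copy()]
        while len(new_pop) < pop_size:
            i1, i2 = rng.integers(pop_size, size=2)
            a = pop[i1] if fit[i1] <= fit[i2] else pop[i2]
            i1, i2 = rng.integers(pop_size, size=2)
            b = pop[i1] if fit[i1] <= fit[i2] else pop[i2]
            if rng.random() < crossover_rate:
                alpha = rng.random(d)
                child = alpha * a + (1.0 - alpha) * b
            else:
                child = a.copy()
            mask = rng.random(d) < mutation_rate
            child = child + mask * rng.normal(0.0, 1.0, d) * sigma
            new_pop.append(np.clip(child, lb, ub))
        pop = np.array(new_pop)
        fit = np.array([np.inf if (v := _safe_eval(objective, x, counter)) is None
                        else v for x in pop])
        trace[it] = fit.min()

    best = int(np.argmin(fit))
    return OptResult(
        best_vector=pop[best].copy(),
        best_fitness=float(fit[best]),
        trace=np.minimum.accumulate(trace),
        n_evaluations=counter[0],
        seed=seed,
    )


def pso_minimize(
    objective,
    lb,
    ub,
    swarm_size: int = 30,
    weight: float = 1.0,
    c1: float = 1.0,
    c2: float = 1.0,
    max_iter: int = 2000,
    velocity_clamp_frac: float = 0.5,
    seed: int | None = None,
) -> OptResult:
    """Global-best particle swarm with velocity clamping and box clipping."""
    rng = np.random.default_rng(seed)
    lb = np.atleast_1d(np.asarray(lb, dtype=float))
    ub = np.atleast_1d(np.asarray(ub, dtype=float))
    d = lb.size
    vmax = velocity_clamp_frac * (ub - lb)
    counter = [0]

    x = lb + (ub - lb) * rng.random((swarm_size, d))
    v = vmax * (2.0 * rng.random((swarm_size, d)) - 1.0)
    fit = np.array([np.inf if (val := _safe_eval(objective, xi, counter)) is None
                    else val for xi in x])
    pbest, pbest_fit = x.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = x[g].copy(), float(fit[g])

    trace = np.empty(max_iter)
    for it in range(max_iter):
        r1 = rng.random((swarm_size, d))
        r2 = rng.random((swarm_size, d))
        v = weight * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lb, ub)
        fit = np.array([np.inf if (val := _safe_eval(objective, xi, counter)) is None
                        else val for xi in x])
        improved = fit < pbest_fit
        pbest[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace[it] = gbest_fit

    return OptResult(
        best_vector=gbest,
        best_fitness=gbest_fit,
        trace=trace,
        n_evaluations=counter[0],
        seed=seed,
    )
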