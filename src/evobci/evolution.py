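"""Real-valued black-box minimizers: (mu, lambda)-CMA-ES and GLGA.

Both engines minimize an arbitrary fitness over a box in R^n and return the
best solution found together with an :class:`EvolutionTrace` of
per-checkpoint fitness statistics.

CMA-ES samples lambda candidates per generation from N(m, sigma^2 C),
ranks them, and updates the mean (weighted recombination of the mu best),
two evolution paths, the covariance C and the step size sigma.  Internal
constants (recombination weights, c_c, c_sigma, c_1, c_mu, damping) follow
the standard Hansen tutorial defaults; the offspring count defaults to
5 x dimension.

GLGA is a steady-state real-coded GA balancing global and local search.
Each iteration picks a female parent by uniform fertility selection (the
least-recently-used member of the elite pool), a male parent by negative
assortative mating (fitness-proportional roulette draw of a few candidates,
keep the one farthest from the female), produces one offspring with the
parent-centric BLX-alpha (PBX-alpha) crossover and replaces the worst
population member if the offspring improves on it.  After a fixed fraction
of the evaluation budget the parent-pool sizes switch from the large global
values to small local ones, shifting from exploration to exploitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EvolutionTrace",
    "GLGAConfig",
    "cmaes_run",
    "glga_run",
    "ufs_select_female",
    "nas_select_male",
    "pbx_crossover",
]


@dataclass
class EvolutionTrace:
    """Per-checkpoint fitness statistics of one optimizer run.

    ``best_fitness`` is the best-so-far series (elitist bookkeeping, hence
    non-increasing); ``mean_fitness``/``std_fitness`` describe the
    population or offspring batch at each checkpoint; ``evaluations`` counts
    fitness calls consumed up to each checkpoint.
    """

    evaluations: list[int] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    std_fitness: list[float] = field(default_factory=list)
    best_solution_history: list[np.ndarray] = field(default_factory=list)
    #: evaluation count at which GLGA switched from global to local search
    #: (None for CMA-ES or if the budget ended inside the global phase)
    switch_evaluation: int | None = None

    def record(self, n_evals, best, mean, std, best_sol) -> None:
        self.evaluations.append(int(n_evals))
        self.best_fitness.append(float(best))
        self.mean_fitness.append(float(mean))
        self.std_fitness.append(float(std))
        self.best_solution_history.append(np.array(best_sol))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "evaluations": self.evaluations,
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "std_fitness": self.std_fitness,
            }
        )


def _as_bounds(bounds, dim: int) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.shape != (dim, 2):
        raise ValueError(f"bounds must have shape ({dim}, 2), got {b.shape}")
    if np.any(b[:, 0] >= b[:, 1]):
        raise ValueError("each bound must satisfy lo < hi")
    return b


def _init_box(bounds: np.ndarray) -> np.ndarray:
    """Finite initialization box: unbounded coordinates default to [-1, 1]."""
    box = bounds.copy()
    box[~np.isfinite(box[:, 0]), 0] = -1.0
    box[~np.isfinite(box[:, 1]), 1] = 1.0
    return box


def _reflect(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Reflect coordinates into the box; infinite bounds are left free."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    finite = np.isfinite(lo) & np.isfinite(hi)
    if not np.any(finite):
        return x
    y = x.copy()
    span = hi[finite] - lo[finite]
    z = np.mod(y[finite] - lo[finite], 2 * span)
    z = np.where(z > span, 2 * span - z, z)
    y[finite] = lo[finite] + z
    return y


def _safe_eval(fitness, x: np.ndarray) -> float:
    v = float(fitness(x))
    if not np.isfinite(v):
        logger.warning("non-finite fitness %r at %s; ranked worst", v, x)
        return np.inf
    return v


# ---------------------------------------------------------------------------
# (mu, lambda)-CMA-ES
# ---------------------------------------------------------------------------

def cmaes_run(
    fitness,
    dim: int,
    bounds,
    max_generations: int = 300,
    seed: int = 0,
    lam: int | None = None,
    sigma0: float | None = None,
    tol_fitness: float | None = None,
):
    """Minimize ``fitness`` with covariance matrix adaptation.

    Parameters
    ----------
    fitness : callable(ndarray) -> float
        Objective to minimize; non-finite returns are ranked worst.
    dim : int
        Solution dimension.
    bounds : array-like (dim, 2)
        Per-coordinate [lo, hi]; +/-inf leaves a coordinate unconstrained.
        Out-of-box samples are repaired by reflection.
    max_generations : int
        Generation budget.
    seed : int
        Seed for the candidate sampler.
    lam : int, optional
        Offspring per generation; defaults to 5 x dim.
    sigma0 : float, optional
        Initial step size; defaults to 0.3 x mean finite box width.
    tol_fitness : float, optional
        Early stop once the best-so-far fitness falls below this value.

    Returns
    -------
    (best_solution, EvolutionTrace)
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    bounds = _as_bounds(bounds, dim)
    box = _init_box(bounds)
    rng = np.random.default_rng(seed)

    lam = int(lam) if lam is not None else 5 * dim
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    c_sigma = (mu_eff + 2) / (dim + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (dim + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / dim) / (dim + 4 + 2 * mu_eff / dim)
    c_1 = 2 / ((dim + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((dim + 2) ** 2 + mu_eff))
    chi_n = np.sqrt(dim) * (1 - 1 / (4 * dim) + 1 / (21 * dim**2))

    m = (box[:, 0] + box[:, 1]) / 2
    sigma = sigma0 if sigma0 is not None else 0.3 * float(np.mean(box[:, 1] - box[:, 0]))
    C = np.eye(dim)
    p_c = np.zeros(dim)
    p_sigma = np.zeros(dim)

    trace = EvolutionTrace()
    best_sol, best_fit = m.copy(), np.inf
    n_evals = 0

    for g in range(max_generations):
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)
        z = rng.standard_normal((lam, dim))
        y = z @ (B * D).T                     # y_i ~ N(0, C)
        X = m + sigma * y
        X = np.array([_reflect(x, bounds) for x in X])
        f = np.array([_safe_eval(fitness, x) for x in X])
        n_evals += lam
        order = np.argsort(f, kind="stable")

        if f[order[0]] < best_fit:
            best_fit = float(f[order[0]])
            best_sol = X[order[0]].copy()

        # recombination on the repaired candidates
        y_sel = (X[order[:mu]] - m) / sigma
        y_w = w @ y_sel
        m = m + sigma * y_w

        C_inv_sqrt = (B / D) @ B.T
        p_sigma = (1 - c_sigma) * p_sigma + np.sqrt(
            c_sigma * (2 - c_sigma) * mu_eff
        ) * (C_inv_sqrt @ y_w)
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / np.sqrt(1 - (1 - c_sigma) ** (2 * (g + 1)))
            < (1.4 + 2 / (dim + 1)) * chi_n
        )
        p_c = (1 - c_c) * p_c + h_sigma * np.sqrt(c_c * (2 - c_c) * mu_eff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c_1 - c_mu) * C
            + c_1 * (np.outer(p_c, p_c) + (1 - h_sigma) * c_c * (2 - c_c) * C)
            + c_mu * rank_mu
        )
        C = (C + C.T) / 2
        sigma = sigma * np.exp(
            (c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_n - 1)
        )

        finite = f[np.isfinite(f)]
        trace.record(
            n_evals,
            best_fit,
            finite.mean() if finite.size else np.inf,
            finite.std() if finite.size else 0.0,
            best_sol,
        )
        logger.info("cmaes gen %d evals %d best %.6g sigma %.3g",
                    g, n_evals, best_fit, sigma)
        if tol_fitness is not None and best_fit < tol_fitness:
            break
    return best_sol, trace


# ---------------------------------------------------------------------------
# GLGA: global/local steady-state real-coded GA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLGAConfig:
    """GLGA hyperparameters.

    ``global_fraction`` of the evaluation budget is spent with the large
    (exploratory) parent pools ``nf_global``/``nm_global``; the remainder
    uses the small local pools.  ``nf_global`` and ``nm_global`` default to
    pop_size/2 and pop_size when left as None.  ``nm_local`` is used as
    printed even if it exceeds the population (then capped, with a log
    message).
    """

    pop_size: int = 100
    alpha_pbx: float = 0.5
    global_fraction: float = 0.25
    budget: int = 10_000
    nm_global: int | None = None
    nf_global: int | None = None
    nm_local: int = 100
    nf_local: int = 5
    n_male_candidates: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.global_fraction < 1:
            raise ValueError("global_fraction must lie in (0, 1)")
        if self.budget < self.pop_size:
            raise ValueError("budget must cover at least the initial population")
        if self.nf_local < 1:
            raise ValueError("nf_local must be >= 1")

    def resolved_pools(self, phase: str, pop_size: int) -> tuple[int, int]:
        """(nf, nm) for the given phase, capped to the population size."""
        if phase == "global":
            nf = self.nf_global if self.nf_global is not None else pop_size // 2
            nm = self.nm_global if self.nm_global is not None else pop_size
        else:
            nf, nm = self.nf_local, self.nm_local
        if nm > pop_size:
            logger.info("male pool %d exceeds population %d; capped", nm, pop_size)
        return min(nf, pop_size), min(nm, pop_size)


def ufs_select_female(
    population: np.ndarray,
    fitness_values: np.ndarray,
    usage_counts: np.ndarray,
    nf: int,
) -> int:
    """Uniform fertility selection: least-used member of the nf-best elite.

    Among the ``nf`` best-fitness members, the one used least often as a
    female parent is chosen (ties go to the better fitness); its usage
    counter is incremented in place.
    """
    if nf > len(population):
        raise ValueError("nf exceeds population size")
    elite = np.argsort(fitness_values, kind="stable")[:nf]
    # lexicographic: primary key usage count, secondary fitness rank
    usage = usage_counts[elite]
    pick = elite[np.lexsort((np.arange(nf), usage))[0]]
    usage_counts[pick] += 1
    return int(pick)


def nas_select_male(
    population: np.ndarray,
    fitness_values: np.ndarray,
    female: np.ndarray,
    n_candidates: int = 5,
    rng: np.random.Generator | None = None,
    pool: np.ndarray | None = None,
) -> int:
    """Negative assortative mating: distant mate from a roulette draw.

    ``n_candidates`` members are drawn by fitness-proportional roulette —
    the wheel weight is (worst_error - error) + eps since lower fitness is
    better — and the candidate with the greatest Euclidean distance to the
    female is returned (distance ties break to the lower index).
    """
    rng = rng or np.random.default_rng()
    pool = np.arange(len(population)) if pool is None else np.asarray(pool)
    if len(pool) < n_candidates:
        n_candidates = len(pool)
    errs = fitness_values[pool]
    wheel = (np.max(errs) - errs) + 1e-12
    wheel = wheel / wheel.sum()
    cand = rng.choice(pool, size=n_candidates, replace=False, p=wheel)
    d = np.linalg.norm(population[cand] - female, axis=1)
    return int(cand[np.argmax(d)])


def pbx_crossover(
    female: np.ndarray,
    male: np.ndarray,
    alpha_pbx: float,
    bounds,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Parent-centric BLX-alpha: offspring uniform around the female.

    Coordinate i is drawn uniformly from
    [female_i - alpha*d_i, female_i + alpha*d_i] with d_i = |female_i -
    male_i|, then clipped into the box.  The offspring therefore stays in
    the female's vicinity with a spread set by the male's distance and
    alpha.
    """
    if female.shape != male.shape:
        raise ValueError("parents must share a dimension")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    b = _as_bounds(bounds, len(female))
    d = np.abs(female - male)
    child = rng.uniform(female - alpha_pbx * d, female + alpha_pbx * d)
    return np.clip(child, b[:, 0], b[:, 1])


def glga_run(
    fitness,
    dim: int,
    bounds,
    config: GLGAConfig | None = None,
    seed: int = 0,
):
    """Minimize ``fitness`` with the global/local steady-state GA.

    Terminates after exactly ``config.budget`` fitness evaluations (the
    initial population evaluation included).  Returns
    (best_solution, EvolutionTrace); checkpoints are recorded every
    ``pop_size`` evaluations.
    """
    config = config or GLGAConfig()
    if dim < 1:
        raise ValueError("dim must be >= 1")
    bounds = _as_bounds(bounds, dim)
    box = _init_box(bounds)
    rng = np.random.default_rng(seed)

    N = config.pop_size
    pop = rng.uniform(box[:, 0], box[:, 1], size=(N, dim))
    fit = np.array([_safe_eval(fitness, x) for x in pop])
    n_evals = N
    usage = np.zeros(N, dtype=int)
    switch_at = int(round(config.global_fraction * config.budget))

    trace = EvolutionTrace()

    def checkpoint():
        b = int(np.argmin(fit))
        finite = fit[np.isfinite(fit)]
        trace.record(
            n_evals, fit[b],
            finite.mean() if finite.size else np.inf,
            finite.std() if finite.size else 0.0,
            pop[b],
        )

    checkpoint()
    while n_evals < config.budget:
        phase = "global" if n_evals < switch_at else "local"
        if phase == "local" and trace.switch_evaluation is None:
            trace.switch_evaluation = n_evals
        nf, nm = config.resolved_pools(phase, N)
        fi = ufs_select_female(pop, fit, usage, nf)
        # male pool: the nm best among the non-elite remainder
        order = np.argsort(fit, kind="stable")
        rest = order[nf:]
        pool = rest[:nm] if len(rest) else order[:nm]
        mi = nas_select_male(pop, fit, pop[fi], config.n_male_candidates,
                             rng=rng, pool=pool)
        child = pbx_crossover(pop[fi], pop[mi], config.alpha_pbx, bounds, rng=rng)
        cf = _safe_eval(fitness, child)
        n_evals += 1
        worst = int(np.argmax(fit))
        if cf < fit[worst]:
            pop[worst] = child
            fit[worst] = cf
            usage[worst] = 0
        if n_evals % N == 0 or n_evals == config.budget:
            checkpoint()
            logger.info("glga %s evals %d best %.6g", phase, n_evals, fit.min())
    b = int(np.argmin(fit))
    return pop[b].copy(), trace
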