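"""Hybrid genetic-algorithm / damped-least-squares global optimizer.

Multi-curve kinetic objectives are riddled with local minima (rate constants
trade off against one another across bands), so a derivative-based fit from a
single start is unreliable.  The strategy here couples a global, gradient-free
genetic search with a local least-squares polish:

1. **GA stage** — a real-coded genetic algorithm on the box-constrained
   (typically log-scaled) parameter space: tournament selection, BLX-alpha
   blend crossover, additive Gaussian mutation, and elitism, which makes the
   best-so-far objective non-increasing across generations.
2. **Polish stage** — a diverse (niched) set of top GA candidates, plus the
   same number of independent seeded random starts, seed
   ``scipy.optimize.least_squares`` (Trust Region Reflective, a damped
   least-squares method honoring the box bounds) when a residual vector is
   available, or bounded L-BFGS-B on the scalar objective otherwise.
   Because the random restarts of :func:`multistart_points` are part of the
   polish set, the hybrid can never end worse than plain multi-start NLLS
   run from those same points.

The result is the lowest-objective polished candidate; exact ties are broken
by the smallest parameter-vector norm for reproducibility.  Everything is
deterministic given ``HybridConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

__all__ = ["HybridConfig", "HybridResult", "hybrid_optimize", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Every polish start failed; the GA trace is attached for diagnosis."""

    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.trace = trace


@dataclass
class HybridConfig:
    """Tuning knobs of the hybrid optimizer.

    ``mutation_sd`` is in absolute units of the (transformed) search space —
    about a quarter of a decade when rates are optimized in log10 space.
    """

    population: int = 48
    generations: int = 60
    crossover_rate: float = 0.7
    blend_alpha: float = 0.3
    mutation_rate: float = 0.25
    mutation_sd: float = 0.25
    tournament_k: int = 3
    n_elite: int = 2
    n_polish: int = 5
    niche_distance: float = 0.5
    max_nfev: int | None = 1500
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10
    diff_step: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")
        if self.n_polish < 1:
            raise ValueError("n_polish must be >= 1")


@dataclass
class HybridResult:
    """Outcome of :func:`hybrid_optimize`."""

    x: np.ndarray
    fun: float
    trace: np.ndarray  # best objective after each GA generation
    n_evals: int
    converged: bool
    polish_funs: list[float] = field(default_factory=list)


def _tournament(rng: np.random.Generator, funs: np.ndarray, k: int) -> int:
    idx = rng.integers(0, funs.size, size=k)
    return int(idx[np.argmin(funs[idx])])


def multistart_points(
    bounds: Sequence[tuple[float, float]], n: int, seed: int | None
) -> np.ndarray:
    """The seeded random restart points the hybrid's polish stage uses.

    Exposed so that a plain multi-start NLLS baseline can be run from exactly
    the same starts as the hybrid (they share the seed-derived stream).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    ss = np.random.SeedSequence(seed).spawn(2)[1]
    return np.random.default_rng(ss).uniform(lo, hi, size=(n, lo.size))


def hybrid_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: HybridConfig | None = None,
    residual: Callable[[np.ndarray], np.ndarray] | None = None,
) -> HybridResult:
    """Minimize ``objective`` over a box, GA stage then least-squares polish.

    Parameters
    ----------
    objective:
        Scalar function of the parameter vector; must be finite on the box.
    bounds:
        Sequence of (lo, hi) per dimension, in the space the optimizer works
        in (callers log-transform rate parameters before calling).
    residual:
        Optional residual vector with ``objective == sum(residual**2)``;
        enables the damped least-squares polish.
    """
    config = config or HybridConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with lo < hi")
    d = lo.size
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    n_evals = 0

    def f(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        v = float(objective(x))
        return v if np.isfinite(v) else np.inf

    # -- GA stage ----------------------------------------------------------
    pop = rng.uniform(lo, hi, size=(config.population, d))
    funs = np.array([f(x) for x in pop])
    trace = []
    for _ in range(config.generations):
        order = np.argsort(funs, kind="stable")
        elites = pop[order[: config.n_elite]]
        children = list(elites)
        while len(children) < config.population:
            i = _tournament(rng, funs, config.tournament_k)
            j = _tournament(rng, funs, config.tournament_k)
            p1, p2 = pop[i], pop[j]
            if rng.random() < config.crossover_rate:
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                span = cmax - cmin
                child = rng.uniform(
                    cmin - config.blend_alpha * span,
                    cmax + config.blend_alpha * span,
                )
            else:
                child = p1.copy()
            mask = rng.random(d) < config.mutation_rate
            child = child + mask * rng.normal(0.0, config.mutation_sd, d)
            children.append(np.clip(child, lo, hi))
        pop = np.asarray(children)
        funs = np.array([f(x) for x in pop])
        trace.append(float(funs.min()))
    trace = np.asarray(trace)

    # -- polish stage -------------------------------------------------------
    # niched GA candidates: the best individual plus runners-up that are at
    # least niche_distance away from every already-chosen start, so the
    # polish explores distinct basins instead of clones of one
    order = np.argsort(funs, kind="stable")
    seeds: list[np.ndarray] = []
    for idx in order:
        x = pop[idx]
        if all(np.linalg.norm(x - s) > config.niche_distance for s in seeds):
            seeds.append(x)
        if len(seeds) == config.n_polish:
            break
    # plus independent seeded random restarts (see multistart_points)
    seeds.extend(multistart_points(bounds, config.n_polish, config.seed))

    candidates: list[tuple[float, np.ndarray]] = []
    polish_funs: list[float] = []
    for x0 in seeds:
        try:
            if residual is not None:
                res = least_squares(
                    residual,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=config.xtol,
                    ftol=config.ftol,
                    gtol=config.gtol,
                    diff_step=config.diff_step,
                    max_nfev=config.max_nfev,
                )
                x_opt, f_opt = res.x, float(np.sum(res.fun**2))
            else:
                res = minimize(
                    f,
                    x0,
                    method="L-BFGS-B",
                    bounds=list(zip(lo, hi)),
                    options={"maxiter": 500},
                )
                x_opt, f_opt = res.x, float(res.fun)
        except Exception:
            continue
        if np.isfinite(f_opt):
            candidates.append((f_opt, x_opt))
            polish_funs.append(f_opt)

    if not candidates:
        raise ConvergenceError("all polish starts failed", trace)

    best_fun = min(c[0] for c in candidates)
    # tie-break equal objectives by smallest parameter-vector norm
    tied = [c for c in candidates if c[0] <= best_fun * (1 + 1e-12) or c[0] == best_fun]
    tied.sort(key=lambda c: (c[0], float(np.linalg.norm(c[1]))))
    fun, x = tied[0]

    # never report worse than the raw GA best
    ga_best = int(np.argmin(funs))
    if funs[ga_best] < fun:
        fun, x = float(funs[ga_best]), pop[ga_best]

    return HybridResult(
        x=np.asarray(x, dtype=float),
        fun=float(fun),
        trace=trace,
        n_evals=n_evals,
        converged=True,
        polish_funs=polish_funs,
    )
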