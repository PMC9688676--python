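"""Global fitting surface: configuration, per-replicate fits, aggregation.

Thin functional layer over :class:`quenchfit.estimators.GlobalKineticFitter`.
One shared parameter set is fitted simultaneously to the nine extension-product
time courses (11-mer..19-mer) of a replicate; replicates are fitted
individually and summarized as mean +/- sample SD per parameter, the study's
reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .estimators import DegenerateDataError, GlobalKineticFitter
from .kinetics import ObservedTimeCourse, model_band_fractions
from .optimize import ConvergenceError, HybridConfig, hybrid_optimize
from .schemes import KineticScheme, RateParams, build_scheme

__all__ = [
    "FitConfig",
    "FitResult",
    "AggregatedFit",
    "objective",
    "fit_global",
    "fit_replicates",
    "aggregate_replicates",
    "DegenerateDataError",
    "ConvergenceError",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings for a global fit (see GlobalKineticFitter)."""

    rate_bounds: tuple[float, float] = (1e-3, 1e4)
    fitted_bands: tuple[int, ...] = tuple(range(11, 20))
    ga_population: int = 48
    ga_generations: int = 60
    crossover_rate: float = 0.7
    blend_alpha: float = 0.3
    mutation_rate: float = 0.25
    mutation_sd: float = 0.25
    tournament_k: int = 3
    n_elite: int = 2
    n_polish: int = 5
    max_nfev: int | None = 1500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate_bounds[0] <= 0:
            raise ValueError("rate lower bound must be positive (log-scaled search)")

    def estimator(self, scheme, bands: Sequence[int]) -> GlobalKineticFitter:
        return GlobalKineticFitter(
            scheme=scheme,
            bands=tuple(bands),
            fitted_bands=self.fitted_bands,
            rate_bounds=self.rate_bounds,
            ga_population=self.ga_population,
            ga_generations=self.ga_generations,
            crossover_rate=self.crossover_rate,
            blend_alpha=self.blend_alpha,
            mutation_rate=self.mutation_rate,
            mutation_sd=self.mutation_sd,
            tournament_k=self.tournament_k,
            n_elite=self.n_elite,
            n_polish=self.n_polish,
            max_nfev=self.max_nfev,
            random_state=self.seed,
        )


@dataclass
class FitResult:
    """Optimized parameters and diagnostics for one replicate fit."""

    scheme_id: str
    params: RateParams
    ssr: float
    n_obs: int
    n_params: int
    trace: np.ndarray
    converged: bool
    at_bounds: tuple[str, ...] = ()
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.ssr < 0:
            raise ValueError("ssr must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "params": self.params.as_dict(),
            "ssr": self.ssr,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "at_bounds": list(self.at_bounds),
            "replicate_id": self.replicate_id,
        }


@dataclass
class AggregatedFit:
    """Per-replicate fits with per-parameter mean and sample SD (ddof=1).

    With a single replicate the SD is undefined and reported as NaN.
    """

    fits: list[FitResult]
    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def n_replicates(self) -> int:
        return len(self.fits)

    @property
    def scheme_id(self) -> str:
        return self.fits[0].scheme_id

    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "n_replicates": self.n_replicates,
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "replicate_fits": [f.to_dict() for f in self.fits],
        }


def objective(
    data: ObservedTimeCourse,
    scheme: KineticScheme | str,
    params: RateParams,
    fitted_bands: Sequence[int] = tuple(range(11, 20)),
) -> float:
    """Sum of squared (observed - model) band fractions over the fitted bands.

    Unweighted least squares; the model comes from the exact linear-system
    solver projected onto gel bands.
    """
    if data.times.size == 0:
        raise ValueError("empty time grid")
    if isinstance(scheme, str):
        scheme = build_scheme(scheme)
    model = model_band_fractions(scheme, params, data.times, fitted_bands)
    obs = np.column_stack([data.band(b) for b in fitted_bands])
    return float(np.sum((obs - model) ** 2))


def fit_global(
    data: ObservedTimeCourse,
    scheme: KineticScheme | str,
    config: FitConfig | None = None,
) -> FitResult:
    """Globally fit one replicate's nine product bands with shared parameters."""
    config = config or FitConfig()
    est = config.estimator(scheme, data.bands).fit(data.times, data.fractions)
    return FitResult(
        scheme_id=est.scheme_.scheme_id,
        params=est.rate_params_,
        ssr=est.ssr_,
        n_obs=est.n_obs_,
        n_params=est.n_params_,
        trace=est.trace_,
        converged=est.converged_,
        at_bounds=est.at_bounds_,
        replicate_id=data.replicate_id,
    )


def fit_replicates(
    replicates: Sequence[ObservedTimeCourse],
    scheme: KineticScheme | str,
    config: FitConfig | None = None,
) -> AggregatedFit:
    """Fit each replicate individually and aggregate (the study's convention).

    Each replicate gets an independent optimizer seed derived from
    ``config.seed`` so fits are reproducible yet not identical.
    """
    config = config or FitConfig()
    fits = []
    for i, rep in enumerate(replicates):
        seed = None if config.seed is None else int(config.seed) * 1000 + i
        fits.append(fit_global(rep, scheme, replace(config, seed=seed % (2**31) if seed is not None else None)))
    return aggregate_replicates(fits)


def aggregate_replicates(fits: Sequence[FitResult]) -> AggregatedFit:
    """Per-parameter arithmetic mean and sample SD (n-1 denominator)."""
    if not fits:
        raise ValueError("need at least one fit to aggregate")
    names = tuple(sorted(fits[0].params.as_dict()))
    for f in fits:
        if tuple(sorted(f.params.as_dict())) != names or f.scheme_id != fits[0].scheme_id:
            raise ValueError("fits must share scheme and parameter names")
    mean, sd = {}, {}
    for name in names:
        vals = np.array([f.params[name] for f in fits])
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return AggregatedFit(fits=list(fits), mean=mean, sd=sd)
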