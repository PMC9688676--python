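"""Formal comparison of competing kinetic schemes and derived summaries.

The study adjudicated schemes qualitatively (the unbranched chain "failed to
describe" inhibitor-treated time courses).  This module adds a formal
criterion: the small-sample-corrected Akaike information criterion,

    AICc = n ln(SSR / n) + 2 p + 2 p (p + 1) / (n - p - 1),

with n the number of fitted observations and p the number of free parameters.
AICc is used instead of a nested F-test because the pause-scheme null
hypothesis places rate constants on the boundary of the parameter space
(pause rates = 0), which violates the regularity conditions of the F
distribution.  The qualitative failure mode is also reported: systematic
late-time positive residuals on the 11-/12-mer bands (data persisting above a
chain model that decays to baseline), plus a Wald–Wolfowitz runs test per
band for residual structure.

:func:`summarize_kinetics` computes the derived quantities the study reports:
the arithmetic mean of the nine nucleotide-addition rate constants (the
nuclease and activation rates are excluded), per-step fold changes versus a
reference condition, and forward/reverse rate ratios for the reversible
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.sandbox.stats.runs import runstest_1samp

from .fitting import AggregatedFit, FitConfig, FitResult, fit_global
from .kinetics import ObservedTimeCourse, model_band_fractions
from .schemes import KineticScheme, build_scheme

__all__ = [
    "ModelComparison",
    "KineticSummary",
    "aicc",
    "compare_schemes",
    "summarize_kinetics",
]

K_OBS_NAMES = tuple(f"k{i}" for i in range(1, 10))


def aicc(ssr: float, n_obs: int, n_params: int) -> float:
    """Small-sample-corrected Akaike information criterion for LS fits."""
    if n_obs <= n_params + 1:
        raise ValueError(
            f"AICc undefined: n_obs={n_obs} must exceed n_params+1={n_params + 1}"
        )
    if ssr <= 0:
        # perfect fit: -inf on the log scale; propagate as such
        return float("-inf")
    n, p = n_obs, n_params
    return n * np.log(ssr / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


@dataclass
class ModelComparison:
    """Per-scheme fits, AICc ranking, and residual-structure diagnostics."""

    fits: dict[str, FitResult]
    aicc: dict[str, float]
    delta_aicc: dict[str, float]
    preferred: str
    tie: bool
    late_positive_residuals: dict[str, float]
    runs_test_pvalues: dict[str, dict[int, float]]

    def to_dict(self) -> dict:
        return {
            "preferred": self.preferred,
            "tie": self.tie,
            "aicc": dict(self.aicc),
            "delta_aicc": dict(self.delta_aicc),
            "late_positive_residuals": dict(self.late_positive_residuals),
            "runs_test_pvalues": {
                s: {int(b): p for b, p in d.items()}
                for s, d in self.runs_test_pvalues.items()
            },
            "fits": {s: f.to_dict() for s, f in self.fits.items()},
        }

    def text_table(self) -> str:
        lines = [f"{'scheme':<8}{'SSR':>12}{'p':>5}{'AICc':>12}{'dAICc':>10}"]
        for s, f in self.fits.items():
            lines.append(
                f"{s:<8}{f.ssr:>12.5g}{f.n_params:>5d}"
                f"{self.aicc[s]:>12.2f}{self.delta_aicc[s]:>10.2f}"
            )
        lines.append(f"preferred: {self.preferred}" + (" (tie)" if self.tie else ""))
        return "\n".join(lines)


def _residual_diagnostics(
    data: ObservedTimeCourse,
    scheme: KineticScheme,
    fit: FitResult,
    fitted_bands: Sequence[int],
) -> tuple[float, dict[int, float]]:
    model = model_band_fractions(scheme, fit.params, data.times, fitted_bands)
    obs = np.column_stack([data.band(b) for b in fitted_bands])
    resid = obs - model

    # fraction of positive residuals over the last third of the time course on
    # the 11-/12-mer bands: the signature of unmodeled pausing
    late = slice(2 * data.times.size // 3, None)
    pause_bands = [i for i, b in enumerate(fitted_bands) if b in (11, 12)]
    late_pos = float(np.mean(resid[late][:, pause_bands] > 0)) if pause_bands else float("nan")

    pvalues: dict[int, float] = {}
    for i, b in enumerate(fitted_bands):
        r = resid[:, i]
        if np.allclose(r, r[0]):
            pvalues[b] = 1.0
            continue
        _, p = runstest_1samp(r, cutoff=0, correction=False)
        pvalues[b] = float(p)
    return late_pos, pvalues


def compare_schemes(
    data: ObservedTimeCourse,
    candidates: Sequence[KineticScheme | str],
    config: FitConfig | None = None,
) -> ModelComparison:
    """Fit every candidate scheme to one dataset and rank by AICc.

    Candidates are typically nested (chain vs chain-plus-pausing for the same
    polymerase); cross-polymerase comparisons are not meaningful and are the
    caller's responsibility to avoid.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate schemes")
    config = config or FitConfig()
    schemes = [build_scheme(c) if isinstance(c, str) else c for c in candidates]

    fits: dict[str, FitResult] = {}
    scores: dict[str, float] = {}
    late: dict[str, float] = {}
    runs: dict[str, dict[int, float]] = {}
    for scheme in schemes:
        fit = fit_global(data, scheme, config)
        fits[scheme.scheme_id] = fit
        scores[scheme.scheme_id] = aicc(fit.ssr, fit.n_obs, fit.n_params)
        late[scheme.scheme_id], runs[scheme.scheme_id] = _residual_diagnostics(
            data, scheme, fit, config.fitted_bands
        )

    best = min(scores.values())
    delta = {s: v - best for s, v in scores.items()}
    winners = sorted(s for s, d in delta.items() if d <= 1e-9)
    return ModelComparison(
        fits=fits,
        aicc=scores,
        delta_aicc=delta,
        preferred=winners[0],
        tie=len(winners) > 1,
        late_positive_residuals=late,
        runs_test_pvalues=runs,
    )


@dataclass
class KineticSummary:
    """Derived summary statistics of a fitted parameter set."""

    mean_kobs: float | None
    fold_change: dict[str, float] | None
    forward_reverse_ratio: dict[int, float] | None
    relative_reduction: float | None = None

    def to_dict(self) -> dict:
        return {
            "mean_kobs": self.mean_kobs,
            "fold_change": self.fold_change,
            "forward_reverse_ratio": self.forward_reverse_ratio,
            "relative_reduction": self.relative_reduction,
        }


def _param_means(fit: AggregatedFit | FitResult) -> dict[str, float]:
    if isinstance(fit, AggregatedFit):
        return dict(fit.mean)
    return fit.params.as_dict()


def summarize_kinetics(
    fit: AggregatedFit | FitResult,
    reference: AggregatedFit | FitResult | None = None,
) -> KineticSummary:
    """Mean nucleotide-addition rate, fold changes, and F/R ratios.

    ``mean_kobs`` averages k1..k9 only: the nuclease rate (k10), the pause
    rates, and the activation rate describe off-pathway processes, not
    nucleotide addition.  Fold change per step is reference / fit (> 1 means
    the fitted condition is slower).  For the reversible scheme the per-step
    forward/reverse ratio kF_i / kR_i is reported instead of ``mean_kobs``.
    """
    values = _param_means(fit)

    mean_kobs = None
    if all(n in values for n in K_OBS_NAMES):
        mean_kobs = float(np.mean([values[n] for n in K_OBS_NAMES]))

    ratios = None
    if "kF1" in values:
        ratios = {}
        for i in range(1, 10):
            kf, kr = values.get(f"kF{i}"), values.get(f"kR{i}")
            if kf is not None and kr is not None and kr > 0:
                ratios[i] = float(kf / kr)

    if mean_kobs is None and ratios is None:
        raise ValueError("fit contains neither k1..k9 nor kF/kR parameter pairs")

    fold = None
    reduction = None
    if reference is not None:
        ref_values = _param_means(reference)
        fold = {}
        for name, v in values.items():
            if name in ref_values and v > 0 and not name.startswith("f_"):
                fold[name] = float(ref_values[name] / v)
        if mean_kobs is not None:
            ref_mean = float(np.mean([ref_values[n] for n in K_OBS_NAMES]))
            reduction = float((ref_mean - mean_kobs) / ref_mean)

    return KineticSummary(
        mean_kobs=mean_kobs,
        fold_change=fold,
        forward_reverse_ratio=ratios,
        relative_reduction=reduction,
    )
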