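"""Elongation-complex (EC) stability analysis from RNase-protection gels.

In the stability assay, radiolabeled 10-mer ECs are challenged at t = 0 with
RNase A, 1 M KCl, and compound or vehicle.  An intact EC protects its RNA and
the gel shows a 10-mer; a collapsed EC exposes the RNA and RNase A trims it
to a 7-mer.  The per-lane collapse fraction,

    collapse = signal(7-mer) / (signal(7-mer) + signal(10-mer)),

is therefore scale-invariant in the raw phosphorimager units and measures EC
disassembly directly.  :func:`analyze_stability` averages collapse curves
over replicates per condition, optionally fits a single-exponential
rise-to-plateau (a convenience; the assay itself prescribes no model), and
contrasts two conditions: the verdict is "unaffected" when the mean
difference stays within ``sd_threshold`` replicate standard deviations at
every time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .estimators import StabilityDecayFitter

__all__ = [
    "StabilityLane",
    "StabilityTimeCourse",
    "StabilityContrast",
    "collapse_fraction",
    "analyze_stability",
]


@dataclass(frozen=True)
class StabilityLane:
    """One gel lane: 7-mer and 10-mer band signals at one challenge time."""

    time: float  # seconds since RNase/KCl/compound addition
    signal_7mer: float
    signal_10mer: float
    condition_label: str = ""
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.signal_7mer < 0 or self.signal_10mer < 0:
            raise ValueError("band signals must be nonnegative")


@dataclass
class StabilityTimeCourse:
    """Replicate-averaged collapse fraction versus time for one condition."""

    times: np.ndarray
    collapse: np.ndarray  # mean over replicates, in [0, 1]
    sd: np.ndarray  # sample SD over replicates (NaN for n=1)
    condition_label: str = ""
    n_replicates: int = 1
    decay_rate: float | None = None  # s^-1, set when fit_decay=True
    plateau: float | None = None
    half_life: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.collapse = np.asarray(self.collapse, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.collapse.min() < 0 or self.collapse.max() > 1:
            raise ValueError("collapse fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_label,
            "n_replicates": self.n_replicates,
            "times": self.times.tolist(),
            "collapse": self.collapse.tolist(),
            "sd": self.sd.tolist(),
            "decay_rate": self.decay_rate,
            "plateau": self.plateau,
            "half_life": self.half_life,
        }


@dataclass
class StabilityContrast:
    """Condition comparison: max |mean difference| against replicate spread."""

    conditions: tuple[str, str]
    max_abs_difference: float
    max_sd_units: float  # max over time of |difference| / pooled SD
    unaffected: bool
    sd_threshold: float

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "max_abs_difference": self.max_abs_difference,
            "max_sd_units": self.max_sd_units,
            "unaffected": self.unaffected,
            "sd_threshold": self.sd_threshold,
        }


def collapse_fraction(lane: StabilityLane) -> float:
    """Fraction of cleaved (7-mer) RNA over total lane signal."""
    total = lane.signal_7mer + lane.signal_10mer
    if total <= 0:
        raise ValueError(
            f"lane at t={lane.time}s has zero total signal and cannot be analyzed"
        )
    return lane.signal_7mer / total


def _per_condition(
    lanes: Sequence[StabilityLane], fit_decay: bool, random_state: int | None
) -> dict[str, StabilityTimeCourse]:
    by_condition: dict[str, list[StabilityLane]] = {}
    for lane in lanes:
        by_condition.setdefault(lane.condition_label, []).append(lane)

    curves: dict[str, StabilityTimeCourse] = {}
    for label, group in by_condition.items():
        times = np.array(sorted({l.time for l in group}))
        if times.size < 2:
            raise ValueError(f"condition {label!r} has fewer than 2 time points")
        reps = sorted({l.replicate_id for l in group})
        grid = np.full((len(reps), times.size), np.nan)
        for lane in group:
            i = reps.index(lane.replicate_id)
            j = int(np.searchsorted(times, lane.time))
            grid[i, j] = collapse_fraction(lane)
        if np.any(np.isnan(grid)):
            raise ValueError(
                f"condition {label!r}: replicates do not cover a common time grid"
            )
        mean = grid.mean(axis=0)
        sd = grid.std(axis=0, ddof=1) if len(reps) > 1 else np.full(times.size, np.nan)
        curve = StabilityTimeCourse(
            times=times,
            collapse=mean,
            sd=sd,
            condition_label=label,
            n_replicates=len(reps),
        )
        if fit_decay:
            est = StabilityDecayFitter(random_state=random_state).fit(times, mean)
            curve.decay_rate = est.rate_
            curve.plateau = est.plateau_
            curve.half_life = est.half_life_
        curves[label] = curve
    return curves


def analyze_stability(
    lanes: Sequence[StabilityLane],
    fit_decay: bool = False,
    sd_threshold: float = 2.0,
    random_state: int | None = 0,
) -> tuple[dict[str, StabilityTimeCourse], StabilityContrast | None]:
    """Collapse curves per condition plus a two-condition contrast.

    Returns ``(curves, contrast)``; ``contrast`` is None unless exactly two
    conditions are present.  Conditions must share their time grid exactly
    (lanes are collected from split aliquots of the same master mix);
    disjoint grids raise a ValueError.
    """
    if not lanes:
        raise ValueError("no lanes supplied")
    curves = _per_condition(lanes, fit_decay, random_state)

    contrast = None
    if len(curves) == 2:
        (la, a), (lb, b) = sorted(curves.items())
        if a.times.size != b.times.size or not np.allclose(a.times, b.times):
            raise ValueError(
                f"conditions {la!r} and {lb!r} were sampled on different time "
                "grids and cannot be contrasted point-by-point"
            )
        diff = np.abs(a.collapse - b.collapse)
        pooled = np.sqrt((np.nan_to_num(a.sd) ** 2 + np.nan_to_num(b.sd) ** 2) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            units = np.where(diff == 0, 0.0, diff / np.where(pooled > 0, pooled, np.inf))
        contrast = StabilityContrast(
            conditions=(la, lb),
            max_abs_difference=float(diff.max()),
            max_sd_units=float(np.max(units)),
            unaffected=bool(np.all(units < sd_threshold)),
            sd_threshold=sd_threshold,
        )
    return curves, contrast
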