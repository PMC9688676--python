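"""Synthetic quench-flow datasets with the statistical structure of the assay.

The in-vitro experiment extends a radiolabeled 10-mer RNA to a 19-mer in a
chemical quenched-flow, sampling ~20 time points over 0.005–10 s, with three
independent reactions per condition and gel band fractions quantified by
phosphorimager.  No raw dataset is publicly deposited, so this module
generates stand-in data: exact band fractions from the forward model plus
additive Gaussian quantification noise, clipped to the physical range [0, 1].

Six default scenarios mirror the study's condition structure:

========== ====== ======================================================
name        scheme anchors
========== ====== ======================================================
pol1_vehicle  S1   fast Pol I elongation, intrinsic nuclease k10
pol1_bmh21    S2   elongation slowed (13-/14-mer steps > 2-fold below
                   vehicle), strong pausing at the 11-/12-mer
pol2_vehicle  S3   slow reversible Pol II chain (pyrophosphorolysis)
pol2_bmh21    S3   identical truth to pol2_vehicle (Pol II unaffected)
pol3_vehicle  S4   mean(k1..k9) = 49 s^-1 exactly; inactive subpopulation
pol3_bmh21    S4   mean(k1..k9) = 39 s^-1 exactly (~20% reduction)
========== ====== ======================================================

Only the tabulated anchors are taken from the study; every other rate value
is an invented but realistic regime, not a reproduction of the study's fitted
constants.  Noise model: per-band, per-time independent additive Gaussian
(sd ``noise_sd``, default 0.02 fraction units), no per-lane renormalization.
Clipping to [0, 1] makes the noise slightly biased where the true fraction is
within ~2 sd of 0 or 1; :func:`clipped_mean` gives the exact expectation.

A small stability-assay generator (see :class:`StabilityScenario`) produces
the RNase-protection collapse curves analyzed by :mod:`quenchfit.stability`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .kinetics import ObservedTimeCourse, project_observables, solve_timecourse
from .schemes import RateParams, build_scheme
from .stability import StabilityLane

__all__ = [
    "Scenario",
    "ReplicateSet",
    "StabilityScenario",
    "default_scenarios",
    "default_stability_scenarios",
    "get_scenario",
    "generate_dataset",
    "generate_stability_lanes",
    "clipped_mean",
]

TIME_WINDOW = (0.005, 10.0)


@dataclass(frozen=True)
class Scenario:
    """Ground-truth description of one simulated condition."""

    name: str
    scheme_id: str
    true_params: RateParams
    time_grid: np.ndarray
    n_replicates: int = 3
    noise_sd: float = 0.02
    condition_label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "time_grid", grid)
        if grid.min() < TIME_WINDOW[0] - 1e-12 or grid.max() > TIME_WINDOW[1] + 1e-12:
            raise ValueError(f"time grid must lie within {TIME_WINDOW} s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ReplicateSet:
    """Replicate time courses sharing a grid, band set, and condition."""

    replicates: list[ObservedTimeCourse]
    condition_label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a ReplicateSet needs at least one replicate")
        first = self.replicates[0]
        for r in self.replicates[1:]:
            if r.bands != first.bands or not np.array_equal(r.times, first.times):
                raise ValueError("replicates must share band set and time grid")

    def __iter__(self):
        return iter(self.replicates)

    def __len__(self) -> int:
        return len(self.replicates)

    @property
    def times(self) -> np.ndarray:
        return self.replicates[0].times

    @property
    def bands(self) -> tuple[int, ...]:
        return self.replicates[0].bands

    def mean_fractions(self) -> np.ndarray:
        return np.mean([r.fractions for r in self.replicates], axis=0)


def _grid() -> np.ndarray:
    return np.geomspace(*TIME_WINDOW, 20)


def default_scenarios() -> list[Scenario]:
    """The six built-in polymerase/condition scenarios (see module docstring)."""
    grid = _grid()

    pol1_vehicle = {f"k{i + 1}": v for i, v in enumerate(
        [70.0, 62.0, 56.0, 60.0, 48.0, 52.0, 44.0, 40.0, 36.0])}
    pol1_vehicle["k10"] = 0.3

    # BMH-21: 13-mer (k3) and 14-mer (k4) appearance slowed > 2-fold relative
    # to vehicle; strong pause entry at the 11-/12-mer with slow exit.
    pol1_bmh21 = {f"k{i + 1}": v for i, v in enumerate(
        [45.0, 40.0, 22.0, 24.0, 38.0, 35.0, 32.0, 30.0, 28.0])}
    pol1_bmh21.update(k10=0.2, k1_on=20.0, k1_off=0.5, k2_on=15.0, k2_off=0.6)

    # Pol II: slowest of the three, reversible at every step; BMH-21 leaves the
    # true parameters unchanged (the compound has no effect on Pol II).
    pol2 = {}
    for i, (f, r) in enumerate(zip(
        [12.0, 10.0, 14.0, 9.0, 11.0, 13.0, 8.0, 10.5, 9.5],
        [3.0, 2.5, 4.0, 2.0, 3.5, 2.8, 2.2, 3.2, 2.6],
    )):
        pol2[f"kF{i + 1}"] = f
        pol2[f"kR{i + 1}"] = r

    # Pol III: mean(k1..k9) = 49 (vehicle) and 39 (BMH-21) exactly by
    # construction, with an inactive subpopulation activating at k_act.
    pol3_vehicle = {f"k{i + 1}": v for i, v in enumerate(
        [65.0, 60.0, 56.0, 52.0, 49.0, 46.0, 42.0, 38.0, 33.0])}
    pol3_vehicle.update(k10=0.5, k_act=2.0, f_inactive=0.25)
    pol3_bmh21 = {f"k{i + 1}": v for i, v in enumerate(
        [52.0, 48.0, 45.0, 41.0, 39.0, 36.0, 33.0, 30.0, 27.0])}
    pol3_bmh21.update(k10=0.5, k_act=2.0, f_inactive=0.25)

    def scn(name, scheme_id, params, label):
        return Scenario(
            name=name,
            scheme_id=scheme_id,
            true_params=RateParams(params),
            time_grid=grid,
            condition_label=label,
        )

    return [
        scn("pol1_vehicle", "S1", pol1_vehicle, "vehicle"),
        scn("pol1_bmh21", "S2", pol1_bmh21, "BMH-21 1 uM"),
        scn("pol2_vehicle", "S3", pol2, "vehicle"),
        scn("pol2_bmh21", "S3", dict(pol2), "BMH-21 1 uM"),
        scn("pol3_vehicle", "S4", pol3_vehicle, "vehicle"),
        scn("pol3_bmh21", "S4", pol3_bmh21, "BMH-21 1 uM"),
    ]


def get_scenario(name: str) -> Scenario:
    for s in default_scenarios():
        if s.name == name:
            return s
    known = [s.name for s in default_scenarios()]
    raise KeyError(f"unknown scenario {name!r}; known: {known}")


def noiseless_timecourse(scenario: Scenario) -> ObservedTimeCourse:
    """Exact forward-model band fractions for a scenario (no noise)."""
    scheme = build_scheme(scenario.scheme_id)
    traj = solve_timecourse(scheme, scenario.true_params, scenario.time_grid)
    return project_observables(traj, condition_label=scenario.condition_label)


def generate_dataset(scenario: Scenario, seed: int) -> ReplicateSet:
    """Noisy replicate set: forward model + clipped additive Gaussian noise.

    Deterministic given (scenario, seed); one master seed spawns independent
    per-replicate streams.
    """
    clean = noiseless_timecourse(scenario)
    streams = np.random.SeedSequence(seed).spawn(scenario.n_replicates)
    replicates = []
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        noisy = clean.fractions + rng.normal(0.0, scenario.noise_sd, clean.fractions.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
        replicates.append(
            ObservedTimeCourse(
                times=clean.times,
                bands=clean.bands,
                fractions=noisy,
                condition_label=scenario.condition_label,
                replicate_id=r + 1,
            )
        )
    return ReplicateSet(
        replicates=replicates,
        condition_label=scenario.condition_label,
        provenance={"scenario": scenario.name, "seed": int(seed)},
    )


def clipped_mean(truth: np.ndarray, sd: float) -> np.ndarray:
    """Exact expectation of ``clip(truth + N(0, sd), 0, 1)``.

    Used to quantify the truncation bias of the noise model analytically.
    """
    mu = np.asarray(truth, dtype=float)
    if sd == 0:
        return np.clip(mu, 0.0, 1.0)
    a = (0.0 - mu) / sd
    b = (1.0 - mu) / sd
    return (
        1.0 * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + sd * (norm.pdf(a) - norm.pdf(b))
    )


# -- stability assay -------------------------------------------------------


@dataclass(frozen=True)
class StabilityScenario:
    """Ground truth for a synthetic RNase-protection collapse experiment.

    The collapse fraction follows a single-exponential rise to plateau,
    ``f(t) = baseline + amplitude * (1 - exp(-decay_rate * t))``; the exact
    sampling times of the original experiment are not published, so a
    logarithmic grid over 0–10 min stands in.
    """

    name: str
    decay_rate: float  # s^-1; EC disassembly rate
    amplitude: float = 0.9
    baseline: float = 0.05
    time_grid: np.ndarray = field(default_factory=lambda: np.geomspace(1.0, 600.0, 15))
    n_replicates: int = 3
    noise_sd: float = 0.02
    condition_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_grid", np.asarray(self.time_grid, dtype=float))
        if self.decay_rate < 0 or self.amplitude < 0:
            raise ValueError("decay_rate and amplitude must be nonnegative")
        if not 0 <= self.baseline <= 1 or self.baseline + self.amplitude > 1 + 1e-12:
            raise ValueError("baseline and baseline+amplitude must lie in [0, 1]")

    def collapse_curve(self, times: np.ndarray | None = None) -> np.ndarray:
        t = self.time_grid if times is None else np.asarray(times, dtype=float)
        return self.baseline + self.amplitude * (1.0 - np.exp(-self.decay_rate * t))


def default_stability_scenarios() -> list[StabilityScenario]:
    """Vehicle/treated stability pair with identical truth (no compound effect)."""
    k = np.log(2) / 60.0  # 60 s disassembly half-life
    return [
        StabilityScenario("stability_vehicle", decay_rate=k, condition_label="vehicle"),
        StabilityScenario("stability_bmh21", decay_rate=k, condition_label="BMH-21 1 uM"),
    ]


def generate_stability_lanes(scenario: StabilityScenario, seed: int) -> list[StabilityLane]:
    """Noisy stability lanes (7-mer vs 10-mer signal) for one condition.

    Total lane signal is normalized to 1; noise is applied to the collapse
    fraction and clipped to [0, 1], mirroring the band-fraction noise model.
    """
    truth = scenario.collapse_curve()
    streams = np.random.SeedSequence(seed).spawn(scenario.n_replicates)
    lanes = []
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        noisy = np.clip(truth + rng.normal(0.0, scenario.noise_sd, truth.shape), 0.0, 1.0)
        for t, f in zip(scenario.time_grid, noisy):
            lanes.append(
                StabilityLane(
                    time=float(t),
                    signal_7mer=float(f),
                    signal_10mer=float(1.0 - f),
                    condition_label=scenario.condition_label,
                    replicate_id=r + 1,
                )
            )
    return lanes
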