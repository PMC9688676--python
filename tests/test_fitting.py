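"""Objective contract, round-trip recovery, and replicate aggregation."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from quenchfit.estimators import DegenerateDataError
from quenchfit.fitting import (
    FitConfig,
    FitResult,
    aggregate_replicates,
    fit_global,
    objective,
)
from quenchfit.kinetics import ObservedTimeCourse, model_band_fractions
from quenchfit.schemes import RateParams, build_scheme
from quenchfit.synthetic import generate_dataset, noiseless_timecourse

FITTED = tuple(range(11, 20))


def test_objective_is_zero_on_self_consistent_data(clean_timecourses, scenarios):
    scn = scenarios["pol1_vehicle"]
    val = objective(clean_timecourses["pol1_vehicle"], "S1", scn.true_params)
    assert val <= 1e-16


def test_objective_counts_a_constant_offset(clean_timecourses, scenarios):
    scn = scenarios["pol1_vehicle"]
    clean = clean_timecourses["pol1_vehicle"]
    shifted = clean.fractions.copy()
    shifted[:, clean.bands.index(11)] += 0.1
    data = ObservedTimeCourse(clean.times, clean.bands, shifted)
    assert objective(data, "S1", scn.true_params) == pytest.approx(
        0.1**2 * clean.times.size, abs=1e-12
    )


def test_objective_invariant_to_table_row_order(clean_timecourses, scenarios):
    scn = scenarios["pol1_vehicle"]
    clean = clean_timecourses["pol1_vehicle"]
    frame = clean.to_frame().sample(frac=1.0, random_state=0)  # shuffled rows
    reloaded = ObservedTimeCourse.from_frame(frame)
    assert objective(reloaded, "S1", scn.true_params) == pytest.approx(
        objective(clean, "S1", scn.true_params), abs=1e-18
    )


def test_noiseless_s1_round_trip_recovers_all_rates(clean_timecourses, scenarios, fast_config):
    scn = scenarios["pol1_vehicle"]
    fit = fit_global(clean_timecourses["pol1_vehicle"], "S1", fast_config)
    for name, truth in scn.true_params.as_dict().items():
        assert abs(fit.params[name] - truth) / truth < 1e-3


def test_noiseless_s2_round_trip_recovers_pause_rates(clean_timecourses, scenarios, fast_config):
    scn = scenarios["pol1_bmh21"]
    fit = fit_global(clean_timecourses["pol1_bmh21"], "S2", fast_config)
    for name in ("k1_on", "k1_off", "k2_on", "k2_off"):
        truth = scn.true_params[name]
        assert abs(fit.params[name] - truth) / truth < 0.05


def test_noiseless_s3_round_trip_recovers_step_ratios(clean_timecourses, scenarios, fast_config):
    """Individual reverse rates may be weakly constrained; per-step
    forward/reverse ratios must come back within 10%."""
    scn = scenarios["pol2_vehicle"]
    fit = fit_global(clean_timecourses["pol2_vehicle"], "S3", fast_config)
    for i in range(1, 10):
        truth = scn.true_params[f"kF{i}"] / scn.true_params[f"kR{i}"]
        got = fit.params[f"kF{i}"] / fit.params[f"kR{i}"]
        assert abs(got - truth) / truth < 0.10


def test_all_zero_fractions_is_rejected_not_silently_fit(times20):
    data = ObservedTimeCourse(times20, tuple(range(10, 20)), np.zeros((20, 10)))
    with pytest.raises(DegenerateDataError):
        fit_global(data, "S1", FitConfig(seed=0))


def test_hybrid_no_worse_than_pure_nlls_restarts(scenarios):
    """On a pause-scheme problem the GA-seeded polish must beat (or match) the
    best of the same number of pure random-start least-squares fits."""
    scn = scenarios["pol1_bmh21"]
    data = generate_dataset(scn, 0).replicates[0]
    scheme = build_scheme("S2")
    names = list(scheme.parameter_names)
    target = np.column_stack([data.band(b) for b in FITTED])

    def residual(x):
        params = RateParams({n: 10.0**v for n, v in zip(names, x)})
        return (model_band_fractions(scheme, params, data.times, FITTED) - target).ravel()

    config = FitConfig(seed=3, ga_population=24, ga_generations=25, n_polish=3)
    fit = fit_global(data, scheme, config)

    rng = np.random.default_rng(3)
    best_pure = math.inf
    for _ in range(config.n_polish):
        x0 = rng.uniform(-3, 4, size=len(names))
        try:
            res = least_squares(residual, x0, bounds=(-3, 4), method="trf")
            best_pure = min(best_pure, float(np.sum(res.fun**2)))
        except Exception:
            pass
    assert fit.ssr <= best_pure + 1e-12


def test_fit_trace_is_monotone_and_result_consistent(scenarios, fast_config):
    data = generate_dataset(scenarios["pol1_vehicle"], 2).replicates[0]
    fit = fit_global(data, "S1", fast_config)
    assert np.all(np.diff(fit.trace) <= 1e-15)
    assert fit.n_obs == 20 * 9
    assert fit.n_params == 10
    assert fit.ssr == pytest.approx(objective(data, "S1", fit.params), rel=1e-6)


def _fake_fit(values, scheme_id="S1"):
    return FitResult(
        scheme_id=scheme_id,
        params=RateParams(values),
        ssr=0.1,
        n_obs=180,
        n_params=len(values),
        trace=np.array([0.1]),
        converged=True,
    )


def test_aggregate_textbook_moments():
    fits = [_fake_fit({"k1": v}) for v in (1.0, 2.0, 3.0)]
    agg = aggregate_replicates(fits)
    assert agg.mean["k1"] == pytest.approx(2.0)
    assert agg.sd["k1"] == pytest.approx(1.0)


def test_aggregate_single_fit_flags_undefined_sd():
    agg = aggregate_replicates([_fake_fit({"k1": 5.0})])
    assert agg.mean["k1"] == 5.0
    assert math.isnan(agg.sd["k1"])
    assert agg.n_replicates == 1


def test_aggregate_identical_fits_gives_zero_sd():
    agg = aggregate_replicates([_fake_fit({"k1": 5.0})] * 3)
    assert agg.sd["k1"] == 0.0


def test_aggregate_rejects_mismatched_parameter_sets():
    with pytest.raises(ValueError, match="share scheme and parameter names"):
        aggregate_replicates([_fake_fit({"k1": 1.0}), _fake_fit({"k2": 1.0})])
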