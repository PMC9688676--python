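"""Solver correctness, the Bateman oracle, and observable projection."""

import numpy as np
import pytest

from quenchfit.kinetics import (
    ConfluenceError,
    ObservedTimeCourse,
    StateTrajectory,
    band_peak_time,
    bateman_chain,
    count_local_maxima,
    model_band_fractions,
    project_observables,
    solve_timecourse,
)
from quenchfit.schemes import (
    ACTIVE,
    CLEAVED_SINK,
    KineticScheme,
    RateParams,
    Species,
    Transition,
    build_scheme,
)
from quenchfit.synthetic import noiseless_timecourse

BANDS = tuple(range(10, 20))


def _chain_scheme(n_links):
    species = tuple(Species(10 + i, ACTIVE) for i in range(n_links + 1))
    transitions = tuple(
        Transition(species[i], species[i + 1], f"k{i + 1}") for i in range(n_links)
    )
    return KineticScheme(
        scheme_id="S1",
        species=species,
        transitions=transitions,
        initial_fractions=((species[0], 1.0),),
    )


def _rates(scheme, mapping):
    return RateParams(mapping)


def test_frozen_system_stays_at_initial_state():
    scheme = build_scheme("S1")
    params = RateParams({name: 0.0 for name in scheme.rate_names})
    traj = solve_timecourse(scheme, params, [0.01, 1.0, 10.0])
    assert np.allclose(traj.states, scheme.initial_vector(), atol=1e-14)


def test_single_exponential_decay():
    a, b = Species(10, ACTIVE), Species(9, CLEAVED_SINK)
    scheme = KineticScheme(
        "S1", (a, b), (Transition(a, b, "k"),), ((a, 1.0),)
    )
    traj = solve_timecourse(scheme, RateParams({"k": 2.0}), [0.5])
    assert traj.states[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-10)


def test_three_species_chain_matches_closed_form():
    """A -1.0-> B -0.5-> C at t=1 s; frozen values from the Bateman solution."""
    scheme = _chain_scheme(2)
    traj = solve_timecourse(scheme, RateParams({"k1": 1.0, "k2": 0.5}), [1.0])
    expected = (0.36787944, 0.47730244, 0.15481812)
    assert np.allclose(traj.states[0], expected, atol=1e-8)
    oracle = bateman_chain([1.0, 0.5], np.array([1.0]))
    assert np.allclose(traj.states, oracle.states, atol=1e-10)


def test_bateman_initial_condition_and_completion_limit():
    tr0 = bateman_chain([0.7, 2.3, 1.1], np.array([0.0, 1e-9]))
    assert np.allclose(tr0.states[0], [1, 0, 0, 0], atol=1e-12)
    tr_inf = bateman_chain([0.7], np.array([1e4]))
    assert tr_inf.states[-1, -1] == pytest.approx(1.0, abs=1e-10)


def test_bateman_rejects_near_equal_rates():
    with pytest.raises(ConfluenceError):
        bateman_chain([1.0, 1.0 + 1e-9], np.array([1.0]))


def test_solver_matches_bateman_on_random_chains():
    """Matrix-exponential solver vs independent closed form, 30 random chains."""
    rng = np.random.default_rng(42)
    times = np.geomspace(0.005, 10, 20)
    scheme = build_scheme("S1")
    for _ in range(30):
        rates = 10 ** rng.uniform(-1, 2, size=9)
        if np.min(np.abs(np.subtract.outer(rates, rates))[~np.eye(9, dtype=bool)]) < 1e-5:
            continue
        params = RateParams({**{f"k{i+1}": r for i, r in enumerate(rates)}, "k10": 0.0})
        traj = solve_timecourse(scheme, params, times, method="expm")
        oracle = bateman_chain(rates, times)
        assert np.max(np.abs(traj.states[:, :10] - oracle.states)) < 1e-7


@pytest.mark.parametrize("scenario_name,scheme_id", [("pol1_bmh21", "S2"), ("pol3_vehicle", "S4")])
def test_expm_agrees_with_stiff_integrator(scenario_name, scheme_id, scenarios):
    params = scenarios[scenario_name].true_params
    times = np.geomspace(0.005, 10, 20)
    t1 = solve_timecourse(build_scheme(scheme_id), params, times, method="expm")
    t2 = solve_timecourse(build_scheme(scheme_id), params, times, method="ode")
    assert np.max(np.abs(t1.states - t2.states)) < 1e-6


def test_spectral_propagator_agrees_with_expm(scenarios):
    params = scenarios["pol2_vehicle"].true_params
    times = np.geomspace(0.005, 10, 20)
    t1 = solve_timecourse(build_scheme("S3"), params, times, method="expm")
    t2 = solve_timecourse(build_scheme("S3"), params, times, method="eig")
    assert np.max(np.abs(t1.states - t2.states)) < 1e-9


def test_invalid_times_and_method_raise():
    scheme = build_scheme("S1")
    params = RateParams({name: 1.0 + 0.1 * i for i, name in enumerate(scheme.rate_names)})
    with pytest.raises(ValueError):
        solve_timecourse(scheme, params, [1.0, 0.5])
    with pytest.raises(ValueError):
        solve_timecourse(scheme, params, [-1.0, 0.5])
    with pytest.raises(ValueError):
        solve_timecourse(scheme, params, [1.0], method="magic")


def test_paused_and_active_species_comigrate():
    """Gel bands sum all species of equal RNA length regardless of state."""
    scheme = build_scheme("S2")
    labels = tuple(s.label for s in scheme.species)
    states = np.zeros((1, scheme.n_species))
    states[0, labels.index("EC11")] = 0.3
    states[0, labels.index("EC11*")] = 0.2
    states[0, labels.index("EC19")] = 0.5
    traj = StateTrajectory(np.array([1.0]), states, scheme.species)
    otc = project_observables(traj)
    assert otc.band(11)[0] == pytest.approx(0.5)
    assert otc.band(19)[0] == pytest.approx(0.5)


def test_s1_projection_is_identity_without_pausing(clean_timecourses, scenarios):
    scn = scenarios["pol1_vehicle"]
    traj = solve_timecourse(build_scheme("S1"), scn.true_params, scn.time_grid)
    otc = project_observables(traj)
    assert np.allclose(otc.fractions, traj.states[:, :10])


def test_band_sum_is_one_minus_sink_and_decreasing(scenarios):
    scn = scenarios["pol1_vehicle"]
    traj = solve_timecourse(build_scheme("S1"), scn.true_params, scn.time_grid)
    otc = project_observables(traj)
    sink = traj.states[:, -1]
    band_sum = otc.fractions.sum(axis=1)
    assert np.allclose(band_sum, 1.0 - sink, atol=1e-9)
    # strictly decreasing while the 10-mer pool drains; flat at round-off
    # level once the nuclease flux has stopped
    assert np.all(np.diff(band_sum) <= 1e-12)
    assert band_sum[-1] < band_sum[0]
    assert band_sum.max() <= 1 + 1e-9


def test_cleaved_band_option_restores_mass():
    scn_params = RateParams({**{f"k{i}": 10.0 + i for i in range(1, 10)}, "k10": 5.0})
    traj = solve_timecourse(build_scheme("S1"), scn_params, np.geomspace(0.01, 5, 10))
    otc = project_observables(traj, cleaved_band=9)
    assert np.allclose(otc.fractions.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("name,scheme_id", [
    ("pol1_vehicle", "S1"), ("pol1_bmh21", "S2"), ("pol3_vehicle", "S4"),
])
def test_full_length_product_is_nondecreasing(name, scheme_id, scenarios):
    scn = scenarios[name]
    traj = solve_timecourse(build_scheme(scheme_id), scn.true_params, np.geomspace(0.005, 10, 200))
    otc = project_observables(traj)
    assert np.all(np.diff(otc.band(19)) >= -1e-12)


def test_limit_reductions_reproduce_simpler_schemes(scenarios):
    """S2 with pause rates 0, S4 with f_inactive 0, and S3 with reverse rates 0
    all collapse onto the corresponding irreversible model."""
    times = np.geomspace(0.005, 10, 20)
    base = scenarios["pol1_vehicle"].true_params.as_dict()
    ref = model_band_fractions(build_scheme("S1"), RateParams(base), times, BANDS, method="expm")

    s2_params = RateParams({**base, "k1_on": 0, "k1_off": 0, "k2_on": 0, "k2_off": 0})
    got = model_band_fractions(build_scheme("S2"), s2_params, times, BANDS, method="expm")
    assert np.max(np.abs(got - ref)) < 1e-9

    s4_params = RateParams({**base, "k_act": 3.0, "f_inactive": 0.0})
    got = model_band_fractions(build_scheme("S4"), s4_params, times, BANDS, method="expm")
    assert np.max(np.abs(got - ref)) < 1e-9

    fwd = 10 ** np.linspace(-0.5, 1.5, 9)
    s3_params = {f"kF{i+1}": fwd[i] for i in range(9)}
    s3_params.update({f"kR{i}": 0.0 for i in range(1, 10)})
    got = model_band_fractions(build_scheme("S3"), RateParams(s3_params), times, BANDS, method="expm")
    oracle = bateman_chain(fwd, times)
    assert np.max(np.abs(got - oracle.states)) < 1e-9


def test_pause_signature_delayed_release_can_split_downstream_band():
    """Strong pausing at the 11-mer releases a delayed second cohort, which can
    make a downstream band (here the 12-mer) bimodal; the 11-mer band itself is
    always unimodal because its only supply is the single-exponential 10-mer
    pool."""
    params = RateParams(dict(
        k1=150, k2=110, k3=27, k4=1.4, k5=79, k6=54, k7=78, k8=24, k9=137,
        k10=0.007, k1_on=42, k1_off=0.83, k2_on=30, k2_off=0.024,
    ))
    dense = np.geomspace(0.0005, 30, 10000)
    otc = project_observables(solve_timecourse(build_scheme("S2"), params, dense, method="eig"))
    assert count_local_maxima(otc.band(12), prominence=1e-3) == 2
    assert count_local_maxima(otc.band(11), prominence=1e-3) == 1


def test_bmh21_scenario_shows_persistence_and_right_shift(scenarios):
    """Inhibitor condition: 11-mer persists late and downstream peaks shift
    right relative to vehicle — the fitted-scheme behaviour the assay shows."""
    dense = np.geomspace(0.005, 10, 10000)
    veh = project_observables(
        solve_timecourse(build_scheme("S1"), scenarios["pol1_vehicle"].true_params, dense)
    )
    bmh = project_observables(
        solve_timecourse(build_scheme("S2"), scenarios["pol1_bmh21"].true_params, dense)
    )
    i1 = int(np.argmin(np.abs(dense - 1.0)))
    assert bmh.band(11)[i1] > 0.1 > veh.band(11)[i1]
    for band in (13, 14, 15, 16):
        assert band_peak_time(bmh, band) > band_peak_time(veh, band)


def test_trajectory_validation():
    with pytest.raises(ValueError):
        StateTrajectory(np.array([1.0, 0.5]), np.ones((2, 1)), ("a",))
    with pytest.raises(ValueError):
        StateTrajectory(np.array([0.5, 1.0]), np.array([[0.6, 0.6], [0.5, 0.5]]), ("a", "b"))
    with pytest.raises(ValueError):
        ObservedTimeCourse(np.array([0.5]), (11,), np.array([[1.5]]))
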