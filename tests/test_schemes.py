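"""Scheme construction, generator matrices, and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quenchfit.schemes import (
    ACTIVE,
    CLEAVED_SINK,
    INACTIVE,
    PAUSED,
    KineticScheme,
    ParameterError,
    RateParams,
    SchemeError,
    Species,
    Transition,
    build_scheme,
    rate_matrix,
    scheme_from_json,
    scheme_to_json,
)


def _unit_rates(scheme, value=1.0):
    params = {name: value for name in scheme.rate_names}
    if scheme.split_param:
        params[scheme.split_param] = 0.3
    return RateParams(params)


@pytest.mark.parametrize(
    "scheme_id,n_species,n_transitions",
    [("S1", 11, 10), ("S2", 13, 14), ("S3", 10, 18), ("S4", 12, 11)],
)
def test_builtin_scheme_topology(scheme_id, n_species, n_transitions):
    scheme = build_scheme(scheme_id)
    assert scheme.n_species == n_species
    assert len(scheme.transitions) == n_transitions
    if scheme_id == "S3":
        assert all(s.state_tag != CLEAVED_SINK for s in scheme.species)
    else:
        assert sum(s.state_tag == CLEAVED_SINK for s in scheme.species) == 1


def test_build_scheme_is_deterministic():
    assert build_scheme("S2") == build_scheme("S2")


def test_unknown_scheme_id_raises():
    with pytest.raises(SchemeError, match="unknown scheme id"):
        build_scheme("S9")


def test_initial_state_all_mass_in_ec10():
    scheme = build_scheme("S1")
    p0 = scheme.initial_vector()
    assert p0[scheme.index(Species(10, ACTIVE))] == 1.0
    assert p0.sum() == 1.0


def test_s4_initial_split_follows_f_inactive():
    scheme = build_scheme("S4")
    params = _unit_rates(scheme)
    p0 = scheme.initial_vector(params)
    assert p0[scheme.index(Species(10, ACTIVE))] == pytest.approx(0.7)
    assert p0[scheme.index(Species(10, INACTIVE))] == pytest.approx(0.3)
    with pytest.raises(ParameterError, match="f_inactive"):
        scheme.initial_vector(RateParams({n: 1.0 for n in scheme.rate_names}))


def test_irreversible_schemes_have_no_backward_elongation():
    """Only the nuclease sink transition decreases RNA length in S1/S2/S4."""
    for sid in ("S1", "S2", "S4"):
        for t in build_scheme(sid).transitions:
            if t.target.state_tag == CLEAVED_SINK:
                continue
            assert t.target.rna_length >= t.source.rna_length


def test_s3_is_a_reversible_chain():
    scheme = build_scheme("S3")
    pairs = {(t.source.rna_length, t.target.rna_length) for t in scheme.transitions}
    for n in range(10, 19):
        assert (n, n + 1) in pairs and (n + 1, n) in pairs


def test_paused_species_cannot_elongate():
    """A paused complex must revert to the active state before extension."""
    scheme = build_scheme("S2")
    for t in scheme.transitions:
        if t.source.state_tag == PAUSED:
            assert t.target == Species(t.source.rna_length, ACTIVE)


def test_species_invariants():
    with pytest.raises(SchemeError):
        Species(13, PAUSED)
    with pytest.raises(SchemeError):
        Species(11, INACTIVE)
    with pytest.raises(SchemeError):
        Species(6, ACTIVE)
    with pytest.raises(SchemeError):
        Species(10, "wobbly")


def test_rate_params_validation():
    with pytest.raises(ParameterError, match="negative"):
        RateParams({"k1": -1.0})
    with pytest.raises(ParameterError, match="finite"):
        RateParams({"k1": float("nan")})
    with pytest.raises(ParameterError, match="f_inactive"):
        RateParams({"f_inactive": 1.5})
    with pytest.raises(ParameterError, match="missing"):
        RateParams({})["k1"]


def test_rate_matrix_zero_rates_gives_zero_matrix():
    scheme = build_scheme("S1")
    K = rate_matrix(scheme, _unit_rates(scheme, value=0.0))
    assert np.all(K == 0)


def test_rate_matrix_two_species_chain():
    a, b = Species(10, ACTIVE), Species(11, ACTIVE)
    scheme = KineticScheme(
        scheme_id="S1",
        species=(a, b),
        transitions=(Transition(a, b, "k"),),
        initial_fractions=((a, 1.0),),
    )
    K = rate_matrix(scheme, RateParams({"k": 1.0}))
    assert np.array_equal(K, np.array([[-1.0, 0.0], [1.0, 0.0]]))


def test_s2_matrix_with_zero_pause_rates_embeds_s1():
    s1, s2 = build_scheme("S1"), build_scheme("S2")
    rates = {f"k{i}": float(i) for i in range(1, 11)}
    K1 = rate_matrix(s1, RateParams(rates))
    K2 = rate_matrix(
        s2, RateParams({**rates, "k1_on": 0, "k1_off": 0, "k2_on": 0, "k2_off": 0})
    )
    idx = [s2.index(sp) for sp in s1.species]
    assert np.allclose(K2[np.ix_(idx, idx)], K1)
    paused = [i for i, sp in enumerate(s2.species) if sp.state_tag == PAUSED]
    assert np.all(K2[paused, :] == 0) and np.all(K2[:, paused] == 0)


def test_rate_matrix_missing_parameter_raises():
    scheme = build_scheme("S1")
    with pytest.raises(ParameterError, match="k10"):
        rate_matrix(scheme, RateParams({f"k{i}": 1.0 for i in range(1, 10)}))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    scheme_id=st.sampled_from(["S1", "S2", "S3", "S4"]),
    data=st.data(),
)
def test_generator_columns_sum_to_zero(scheme_id, data):
    """Mass conservation: every generator column sums to 0 (sink included)."""
    scheme = build_scheme(scheme_id)
    values = {
        name: data.draw(st.floats(0, 1e3, allow_nan=False))
        for name in scheme.rate_names
    }
    if scheme.split_param:
        values[scheme.split_param] = data.draw(st.floats(0, 1))
    K = rate_matrix(scheme, RateParams(values))
    assert np.max(np.abs(K.sum(axis=0))) <= 1e-12 * max(1.0, np.abs(K).max())


@pytest.mark.parametrize("scheme_id", ["S1", "S2", "S3", "S4"])
def test_json_round_trip(scheme_id):
    scheme = build_scheme(scheme_id)
    assert scheme_from_json(scheme_to_json(scheme)) == scheme


def test_json_load_validates_invariants():
    import json

    payload = json.loads(scheme_to_json(build_scheme("S1")))
    payload["initial_fractions"][0][1] = 0.5  # no longer sums to 1
    with pytest.raises(SchemeError, match="initial fractions"):
        scheme_from_json(json.dumps(payload))
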