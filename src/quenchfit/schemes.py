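"""Kinetic reaction schemes for multi-nucleotide addition by RNA polymerases.

Four minimal first-order kinetic schemes describe single-turnover extension of a
10-mer RNA to a 19-mer by a stalled elongation complex (EC) after rapid mixing
with saturating NTPs:

``S1``
    Irreversible chain EC10 -> EC11 -> ... -> EC19 with per-step observed rate
    constants ``k1..k9``, plus an intrinsic-nuclease loss path EC10 -> cleaved
    (``k10``).  Describes Pol I under vehicle treatment.
``S2``
    ``S1`` extended with two off-pathway paused species, EC11* and EC12*,
    entered and exited via ``k1_on/k1_off`` and ``k2_on/k2_off``.  Paused
    complexes cannot add the next nucleotide until they revert to the active
    state.  Describes Pol I in the presence of the inhibitor BMH-21.
``S3``
    Fully reversible chain EC10 <-> ... <-> EC19 with forward/reverse rate
    constants ``kF1..kF9`` / ``kR1..kR9`` (pyrophosphorolysis), no nuclease
    path.  Describes Pol II in either condition.
``S4``
    ``S1`` plus an elongation-incompetent starting subpopulation EC10_i that
    activates into EC10 with rate ``k_act``; the initial mass splits
    ``(1 - f_inactive, f_inactive)`` between EC10 and EC10_i.  Describes
    Pol III in either condition.

All rate constants are observed pseudo-first-order values (s^-1) at a single
saturating NTP concentration; elementary substeps (NTP binding, catalysis,
translocation) are deliberately not resolved.

Schemes are plain declarative data (species, transitions, initial state) and
serialize to/from JSON so custom topologies can be supplied without code
changes.  :func:`rate_matrix` converts a scheme plus a parameter set into the
standard mass-action generator matrix of the linear ODE system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ACTIVE",
    "PAUSED",
    "INACTIVE",
    "CLEAVED_SINK",
    "SCHEME_IDS",
    "Species",
    "Transition",
    "KineticScheme",
    "RateParams",
    "SchemeError",
    "ParameterError",
    "build_scheme",
    "rate_matrix",
    "scheme_to_json",
    "scheme_from_json",
]

ACTIVE = "active"
PAUSED = "paused"
INACTIVE = "inactive"
CLEAVED_SINK = "cleaved_sink"

_STATE_TAGS = (ACTIVE, PAUSED, INACTIVE, CLEAVED_SINK)

SCHEME_IDS = ("S1", "S2", "S3", "S4")

#: length of the nuclease cleavage product; the cleaved RNA is not mapped to a
#: gel band by default (see kinetics.project_observables).
CLEAVED_LENGTH = 9


class SchemeError(ValueError):
    """Invalid scheme identifier or inconsistent scheme topology."""


class ParameterError(ValueError):
    """Missing, negative, or non-finite rate parameter."""


@dataclass(frozen=True, order=True)
class Species:
    """One kinetic species: an elongation complex carrying an RNA of a given length.

    ``state_tag`` distinguishes the on-pathway (active) complex from off-pathway
    paused complexes (permitted only at lengths 11 and 12), the inactive
    starting subpopulation (length 10 only), and the cleaved-RNA sink which has
    no outgoing transitions.
    """

    rna_length: int
    state_tag: str = ACTIVE

    def __post_init__(self) -> None:
        if self.state_tag not in _STATE_TAGS:
            raise SchemeError(f"unknown state tag {self.state_tag!r}")
        if not (7 <= self.rna_length <= 19):
            raise SchemeError(f"RNA length {self.rna_length} outside 7..19")
        if self.state_tag == PAUSED and self.rna_length not in (11, 12):
            raise SchemeError("paused species only permitted at lengths 11 and 12")
        if self.state_tag == INACTIVE and self.rna_length != 10:
            raise SchemeError("inactive species only permitted at length 10")

    @property
    def label(self) -> str:
        if self.state_tag == ACTIVE:
            return f"EC{self.rna_length}"
        if self.state_tag == PAUSED:
            return f"EC{self.rna_length}*"
        if self.state_tag == INACTIVE:
            return f"EC{self.rna_length}_i"
        return "cleaved"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class Transition:
    """A first-order transition ``source -> target`` parameterized by ``rate_name``."""

    source: Species
    target: Species
    rate_name: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise SchemeError("transition source and target must differ")
        if self.source.state_tag == CLEAVED_SINK:
            raise SchemeError("the cleaved sink carries no outgoing transitions")


@dataclass
class RateParams:
    """Named nonnegative rate constants (s^-1) parameterizing a scheme.

    The special entry ``f_inactive`` (dimensionless, in [0, 1]) gives the
    initial inactive fraction for scheme S4 and is not a rate.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for name, value in self.values.items():
            v = float(value)
            if not np.isfinite(v):
                raise ParameterError(f"parameter {name!r} is not finite: {value!r}")
            if v < 0:
                raise ParameterError(f"parameter {name!r} is negative: {value!r}")
            clean[name] = v
        if "f_inactive" in clean and not 0.0 <= clean["f_inactive"] <= 1.0:
            raise ParameterError("f_inactive must lie in [0, 1]")
        self.values = clean

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"missing rate parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class KineticScheme:
    """Directed graph of species and first-order transitions, plus initial state.

    ``initial_fractions`` holds the parameter-independent part of the initial
    state.  If ``split_param`` is set (scheme S4), that fraction of the first
    species' initial mass is moved to the species named by ``split_species`` at
    solve time, so the split can be fitted as a free parameter.
    """

    scheme_id: str
    species: tuple[Species, ...]
    transitions: tuple[Transition, ...]
    initial_fractions: tuple[tuple[Species, float], ...]
    split_param: str | None = None
    split_species: Species | None = None

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise SchemeError("duplicate species in scheme")
        index = {s: i for i, s in enumerate(self.species)}
        seen_pairs: set[tuple[Species, Species]] = set()
        for t in self.transitions:
            if t.source not in index or t.target not in index:
                raise SchemeError(f"transition {t.rate_name} references unknown species")
            if (t.source, t.target) in seen_pairs:
                raise SchemeError(f"duplicate transition {t.source}->{t.target}")
            seen_pairs.add((t.source, t.target))
        total = sum(f for _, f in self.initial_fractions)
        if abs(total - 1.0) > 1e-12:
            raise SchemeError(f"initial fractions sum to {total}, not 1")
        if (self.split_param is None) != (self.split_species is None):
            raise SchemeError("split_param and split_species must be set together")
        if self.split_species is not None and self.split_species not in index:
            raise SchemeError("split species not in scheme")
        self._check_reachability(index)

    def _check_reachability(self, index: Mapping[Species, int]) -> None:
        adj: dict[Species, list[Species]] = {s: [] for s in self.species}
        for t in self.transitions:
            adj[t.source].append(t.target)
        start = [s for s, f in self.initial_fractions if f > 0]
        if self.split_species is not None:
            start.append(self.split_species)
        seen = set(start)
        stack = list(start)
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        unreachable = [s.label for s in self.species if s not in seen]
        if unreachable:
            raise SchemeError(f"species unreachable from initial state: {unreachable}")

    # -- conveniences -----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def rate_names(self) -> tuple[str, ...]:
        """Rate names in transition order (excludes any initial-split parameter)."""
        return tuple(t.rate_name for t in self.transitions)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """All free parameter names: transition rates plus the initial split, if any."""
        names = list(dict.fromkeys(self.rate_names))
        if self.split_param is not None:
            names.append(self.split_param)
        return tuple(names)

    def index(self, species: Species) -> int:
        return self.species.index(species)

    def initial_vector(self, params: RateParams | None = None) -> np.ndarray:
        """Initial state as a fraction vector over ``self.species``.

        For S4 the split ``f_inactive`` is read from ``params``; other schemes
        ignore ``params``.
        """
        p0 = np.zeros(self.n_species)
        for sp, frac in self.initial_fractions:
            p0[self.index(sp)] = frac
        if self.split_param is not None:
            if params is None or self.split_param not in params:
                raise ParameterError(
                    f"scheme {self.scheme_id} requires parameter {self.split_param!r}"
                )
            f = params[self.split_param]
            first = self.initial_fractions[0][0]
            p0[self.index(first)] -= f
            p0[self.index(self.split_species)] += f
        return p0


def _ec(n: int) -> Species:
    return Species(n, ACTIVE)


def build_scheme(scheme_id: str) -> KineticScheme:
    """Construct one of the four built-in schemes.

    Deterministic: species ordering is fixed as active EC10..EC19, then paused
    species by length, then the inactive species, then the cleaved sink.
    """
    if scheme_id not in SCHEME_IDS:
        raise SchemeError(f"unknown scheme id {scheme_id!r}; expected one of {SCHEME_IDS}")

    chain = [_ec(n) for n in range(10, 20)]
    sink = Species(CLEAVED_LENGTH, CLEAVED_SINK)
    forward = [
        Transition(chain[i], chain[i + 1], f"k{i + 1}") for i in range(9)
    ]

    if scheme_id == "S1":
        species = (*chain, sink)
        transitions = (*forward, Transition(chain[0], sink, "k10"))
    elif scheme_id == "S2":
        p11 = Species(11, PAUSED)
        p12 = Species(12, PAUSED)
        species = (*chain, p11, p12, sink)
        transitions = (
            *forward,
            Transition(chain[0], sink, "k10"),
            Transition(chain[1], p11, "k1_on"),
            Transition(p11, chain[1], "k1_off"),
            Transition(chain[2], p12, "k2_on"),
            Transition(p12, chain[2], "k2_off"),
        )
    elif scheme_id == "S3":
        species = tuple(chain)
        reverse = [
            Transition(chain[i + 1], chain[i], f"kR{i + 1}") for i in range(9)
        ]
        fwd = [
            Transition(chain[i], chain[i + 1], f"kF{i + 1}") for i in range(9)
        ]
        transitions = tuple(x for pair in zip(fwd, reverse) for x in pair)
    else:  # S4
        inactive = Species(10, INACTIVE)
        species = (*chain, inactive, sink)
        transitions = (
            *forward,
            Transition(chain[0], sink, "k10"),
            Transition(inactive, chain[0], "k_act"),
        )
        return KineticScheme(
            scheme_id="S4",
            species=species,
            transitions=transitions,
            initial_fractions=((chain[0], 1.0),),
            split_param="f_inactive",
            split_species=inactive,
        )

    return KineticScheme(
        scheme_id=scheme_id,
        species=species,
        transitions=transitions,
        initial_fractions=((chain[0], 1.0),),
    )


def rate_matrix(scheme: KineticScheme, params: RateParams) -> np.ndarray:
    """Mass-action generator matrix K of d(state)/dt = K @ state.

    Entry (target, source) carries the rate of that transition; each diagonal
    entry is minus the total outgoing rate, so every column sums to zero and
    total mass (including the sink) is conserved.
    """
    n = scheme.n_species
    K = np.zeros((n, n))
    for t in scheme.transitions:
        k = params[t.rate_name]
        i, j = scheme.index(t.target), scheme.index(t.source)
        K[i, j] += k
        K[j, j] -= k
    return K


# -- JSON serialization ----------------------------------------------------


def _species_to_dict(sp: Species) -> dict:
    return {"rna_length": sp.rna_length, "state_tag": sp.state_tag}


def _species_from_dict(d: Mapping) -> Species:
    return Species(int(d["rna_length"]), str(d["state_tag"]))


def scheme_to_json(scheme: KineticScheme) -> str:
    """Serialize a scheme (species, transitions, initial state) to JSON."""
    payload = {
        "scheme_id": scheme.scheme_id,
        "species": [_species_to_dict(s) for s in scheme.species],
        "transitions": [
            {
                "source": _species_to_dict(t.source),
                "target": _species_to_dict(t.target),
                "rate_name": t.rate_name,
            }
            for t in scheme.transitions
        ],
        "initial_fractions": [
            [_species_to_dict(s), f] for s, f in scheme.initial_fractions
        ],
        "split_param": scheme.split_param,
        "split_species": (
            _species_to_dict(scheme.split_species)
            if scheme.split_species is not None
            else None
        ),
    }
    return json.dumps(payload, indent=2)


def scheme_from_json(text: str) -> KineticScheme:
    """Inverse of :func:`scheme_to_json`; validates all scheme invariants."""
    d = json.loads(text)
    return KineticScheme(
        scheme_id=str(d["scheme_id"]),
        species=tuple(_species_from_dict(s) for s in d["species"]),
        transitions=tuple(
            Transition(
                _species_from_dict(t["source"]),
                _species_from_dict(t["target"]),
                str(t["rate_name"]),
            )
            for t in d["transitions"]
        ),
        initial_fractions=tuple(
            (_species_from_dict(s), float(f)) for s, f in d["initial_fractions"]
        ),
        split_param=d.get("split_param"),
        split_species=(
            _species_from_dict(d["split_species"])
            if d.get("split_species")
            else None
        ),
    )
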