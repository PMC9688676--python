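"""Forward simulation of kinetic schemes and projection onto gel observables.

The schemes are linear first-order networks, so the state obeys
``d p / d t = K p`` with generator ``K`` from :func:`quenchfit.schemes.rate_matrix`
and has the exact solution ``p(t) = expm(K t) p(0)``.  Three interchangeable
evaluation methods are provided:

``expm``
    Matrix exponential per time point (scipy.linalg.expm).  Default.
``eig``
    Spectral propagator: one eigendecomposition of K, then vectorized
    evaluation over all time points.  Much faster inside fitting loops; falls
    back to ``expm`` automatically if the eigenvector basis is ill-conditioned
    or the result violates mass conservation.
``ode``
    Adaptive stiff integration (scipy.integrate.solve_ivp, LSODA) used as an
    independent cross-check; fitted rate constants can span several orders of
    magnitude, which makes the system stiff.

:func:`bateman_chain` is the closed-form sequential-decay solution for an
irreversible chain with pairwise-distinct rates; it serves as an analytic
oracle for scheme-S1-like topologies and never shares code with the solvers.

:func:`project_observables` collapses the latent species trajectory onto the
band fractions a sequencing gel reports: paused and active complexes of equal
RNA length co-migrate into a single band, while the cleaved sink is invisible
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .schemes import (
    CLEAVED_SINK,
    KineticScheme,
    ParameterError,
    RateParams,
    Species,
    rate_matrix,
)

__all__ = [
    "StateTrajectory",
    "ObservedTimeCourse",
    "ConfluenceError",
    "solve_timecourse",
    "bateman_chain",
    "project_observables",
    "model_band_fractions",
    "count_local_maxima",
    "band_peak_time",
]

#: round-off clamp: negative fractions of magnitude below this are zeroed at
#: output; anything more negative raises.
CLAMP_TOL = 1e-9

#: headroom for per-lane band-fraction sums in measured data: bands are
#: quantified with independent noise, so a lane sum is itself noisy (sd about
#: noise_sd * sqrt(n_bands)) and its extreme over many lanes can sit several
#: of those sds above 1.
NOISY_SUM_TOL = 0.5


class ConfluenceError(ValueError):
    """Bateman rates too close to equal for the closed form to be stable."""


@dataclass
class StateTrajectory:
    """Fractional occupancy of every species at every time point.

    ``states`` has shape (n_times, n_species); rows sum to 1 (mass
    conservation, the cleaved sink being an explicit species).
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if self.states.shape != (self.times.size, len(self.species)):
            raise ValueError("states shape does not match times x species")
        if self.states.min() < -CLAMP_TOL or self.states.max() > 1 + CLAMP_TOL:
            raise ValueError("state fractions outside [0, 1] beyond round-off")
        sums = self.states.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ValueError("species fractions do not sum to 1 within 1e-9")

    def fraction(self, species: Hashable) -> np.ndarray:
        return self.states[:, self.species.index(species)]


@dataclass
class ObservedTimeCourse:
    """Gel-observable band fractions versus time for one reaction replicate.

    ``fractions`` has shape (n_times, n_bands); per-time sums may be below 1
    when mass has left through the invisible cleaved sink.  Model output sums
    to at most 1 (within round-off); measured data may exceed 1 slightly
    because each band is quantified with independent noise, so the container
    enforces only a loose sanity bound (see NOISY_SUM_TOL).
    """

    times: np.ndarray
    bands: tuple[int, ...]
    fractions: np.ndarray
    condition_label: str = ""
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.bands = tuple(int(b) for b in self.bands)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if self.fractions.shape != (self.times.size, len(self.bands)):
            raise ValueError("fractions shape does not match times x bands")
        if self.fractions.min() < -CLAMP_TOL or self.fractions.max() > 1 + CLAMP_TOL:
            raise ValueError("band fractions outside [0, 1] beyond round-off")
        if np.max(self.fractions.sum(axis=1)) > 1 + NOISY_SUM_TOL:
            raise ValueError("per-time band-fraction sum exceeds 1 beyond noise headroom")

    def band(self, length: int) -> np.ndarray:
        """Fraction time course of one band (RNA length in nucleotides)."""
        try:
            return self.fractions[:, self.bands.index(int(length))]
        except ValueError:
            raise KeyError(f"band {length} not present; have {self.bands}") from None

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_s, band_length, fraction, condition, replicate)."""
        n_t, n_b = self.fractions.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n_b),
                "band_length": np.tile(self.bands, n_t),
                "fraction": self.fractions.ravel(),
                "condition": self.condition_label,
                "replicate": self.replicate_id,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservedTimeCourse":
        """Inverse of :meth:`to_frame` for a single condition/replicate table."""
        conditions = frame["condition"].unique()
        replicates = frame["replicate"].unique()
        if len(conditions) != 1 or len(replicates) != 1:
            raise ValueError("from_frame expects exactly one condition and replicate")
        wide = frame.pivot(index="time_s", columns="band_length", values="fraction")
        wide = wide.sort_index().sort_index(axis=1)
        return cls(
            times=wide.index.to_numpy(dtype=float),
            bands=tuple(int(b) for b in wide.columns),
            fractions=wide.to_numpy(dtype=float),
            condition_label=str(conditions[0]),
            replicate_id=int(replicates[0]),
        )


def _clamp(states: np.ndarray, tol: float = CLAMP_TOL) -> np.ndarray:
    low = states.min()
    if low < -tol:
        raise ValueError(f"solver produced fraction {low}, below -{tol}")
    return np.where(states < 0, 0.0, states)


def _propagate_expm(K: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    return np.stack([expm(K * t) @ p0 for t in times])


def _propagate_eig(K: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray | None:
    """Spectral propagation; returns None when the basis is unusable."""
    lam, V = np.linalg.eig(K)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return None
    if not np.isfinite(cond) or cond > 1e10:
        return None
    c = np.linalg.solve(V, p0.astype(complex))
    E = np.exp(np.multiply.outer(times, lam))  # (T, n)
    states = (E * c) @ V.T
    states = states.real
    # sanity: mass conservation and positivity within round-off
    if np.max(np.abs(states.sum(axis=1) - p0.sum())) > 1e-8:
        return None
    if states.min() < -CLAMP_TOL:
        return None
    return states


def _propagate_ode(K: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    sol = solve_ivp(
        lambda t, y: K @ y,
        (0.0, t_end),
        p0,
        method="LSODA",
        jac=lambda t, y: K,
        t_eval=times,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust on these systems
        raise RuntimeError(f"stiff integrator failed: {sol.message}")
    return sol.y.T


def solve_timecourse(
    scheme: KineticScheme,
    params: RateParams,
    times: Sequence[float],
    method: str = "expm",
) -> StateTrajectory:
    """Exact species trajectory of ``d p/dt = K p`` from the scheme's initial state.

    Parameters
    ----------
    method:
        ``"expm"`` (default), ``"eig"`` (fast spectral propagator with
        automatic fallback to ``expm``), or ``"ode"`` (adaptive stiff
        integrator cross-check).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and nonnegative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    states = _raw_states(scheme, params, times, method)
    return StateTrajectory(times=times, states=_clamp(states), species=scheme.species)


def bateman_chain(rates: Sequence[float], times: Sequence[float]) -> StateTrajectory:
    """Closed-form solution of the irreversible chain A1 -k1-> A2 -k2-> ... -> A_{n+1}.

    All mass starts in the first species; the terminal species does not decay.
    Requires pairwise-distinct rates (relative separation > 1e-6); raises
    :class:`ConfluenceError` otherwise — use :func:`solve_timecourse` for
    confluent rate sets.

    This is an independent analytic oracle: it never calls the matrix solvers.
    """
    rates = np.asarray(rates, dtype=float)
    times = np.asarray(times, dtype=float)
    if rates.ndim != 1 or rates.size == 0:
        raise ValueError("rates must be a non-empty 1-D sequence")
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be positive and finite")
    if times.ndim != 1 or np.any(times < 0):
        raise ValueError("times must be 1-D and nonnegative")

    # decay constants per species; the terminal species has lambda = 0
    lam = np.concatenate([rates, [0.0]])
    scale = max(lam)
    for i in range(lam.size):
        for j in range(i + 1, lam.size):
            if abs(lam[i] - lam[j]) <= 1e-6 * scale:
                raise ConfluenceError(
                    f"rates {lam[i]} and {lam[j]} are too close for the closed form"
                )

    n = lam.size
    states = np.zeros((times.size, n))
    for i in range(n):
        # Bateman: N_i(t) = (prod_{m<i} k_m) * sum_{j<=i} exp(-lam_j t) /
        #                   prod_{l<=i, l!=j} (lam_l - lam_j)
        prefactor = np.prod(rates[:i]) if i > 0 else 1.0
        acc = np.zeros(times.size)
        for j in range(i + 1):
            denom = 1.0
            for l in range(i + 1):
                if l != j:
                    denom *= lam[l] - lam[j]
            acc += np.exp(-lam[j] * times) / denom
        states[:, i] = prefactor * acc

    labels = tuple(f"chain_{i}" for i in range(n))
    # guard round-off the same way as the solvers
    states = _clamp(states, tol=1e-8)
    return StateTrajectory(times=times, states=states, species=labels)


def project_observables(
    traj: StateTrajectory,
    condition_label: str = "",
    replicate_id: int = 1,
    cleaved_band: int | None = None,
) -> ObservedTimeCourse:
    """Collapse a species trajectory onto gel band fractions.

    All species of equal RNA length co-migrate into one band regardless of
    state (active, paused, inactive).  The cleaved sink contributes to no band
    unless ``cleaved_band`` maps it onto a visible RNA length.
    """
    lengths: list[int] = []
    for sp in traj.species:
        if not isinstance(sp, Species):
            raise TypeError("project_observables requires a scheme-species trajectory")
        if sp.state_tag == CLEAVED_SINK:
            continue
        if sp.rna_length not in lengths:
            lengths.append(sp.rna_length)
    bands = tuple(sorted(set(lengths) | ({cleaved_band} if cleaved_band else set())))

    fractions = np.zeros((traj.times.size, len(bands)))
    for i, sp in enumerate(traj.species):
        if sp.state_tag == CLEAVED_SINK:
            if cleaved_band is not None:
                fractions[:, bands.index(cleaved_band)] += traj.states[:, i]
            continue
        fractions[:, bands.index(sp.rna_length)] += traj.states[:, i]

    return ObservedTimeCourse(
        times=traj.times,
        bands=bands,
        fractions=fractions,
        condition_label=condition_label,
        replicate_id=replicate_id,
    )


def _raw_states(
    scheme: KineticScheme, params: RateParams, times: np.ndarray, method: str
) -> np.ndarray:
    """Propagate without container validation (hot path for optimizers).

    Optimizer populations explore extreme rate combinations (k*t ~ 1e5) where
    the matrix exponential conserves mass only to ~1e-7; those evaluations
    just feed the objective and must not raise, so the strict trajectory
    invariants are enforced only at the public solve_timecourse boundary.
    """
    K = rate_matrix(scheme, params)
    p0 = scheme.initial_vector(params)
    if method == "eig":
        states = _propagate_eig(K, p0, times)
        if states is None:
            states = _propagate_expm(K, p0, times)
    elif method == "expm":
        states = _propagate_expm(K, p0, times)
    elif method == "ode":
        states = _propagate_ode(K, p0, times)
    else:
        raise ValueError(f"unknown method {method!r}")
    return states


def model_band_fractions(
    scheme: KineticScheme,
    params: RateParams,
    times: Sequence[float],
    bands: Sequence[int],
    method: str = "eig",
) -> np.ndarray:
    """Model band-fraction matrix (n_times, len(bands)) — the fit's forward model."""
    times = np.asarray(times, dtype=float)
    states = np.clip(_raw_states(scheme, params, times, method), 0.0, 1.0)
    out = np.zeros((times.size, len(bands)))
    lengths = [int(b) for b in bands]
    for i, sp in enumerate(scheme.species):
        if sp.state_tag == CLEAVED_SINK:
            continue
        if sp.rna_length in lengths:
            out[:, lengths.index(sp.rna_length)] += states[:, i]
    return out


def count_local_maxima(y: np.ndarray, prominence: float = 1e-4) -> int:
    """Number of interior local maxima of a sampled curve, ignoring wiggles
    smaller than ``prominence`` (absolute, in fraction units)."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(np.asarray(y, dtype=float), prominence=prominence)
    return int(peaks.size)


def band_peak_time(otc: ObservedTimeCourse, band: int) -> float:
    """Time at which a band's fraction is maximal (grid resolution)."""
    y = otc.band(band)
    return float(otc.times[int(np.argmax(y))])
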