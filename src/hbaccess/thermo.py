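"""Equilibrium (thermodynamic) promoter models of the hunchback P2 enhancer.

Two variants are implemented:

* the thermodynamic MWC model, in which chromatin thermally fluctuates between
  an inaccessible state (statistical weight ``exp(delta_eps_chrom)``, in k_BT
  units, relative to the bare accessible state) and accessible states in which
  Bicoid, Zelda and RNAP bind independently -- Zelda contributes a factor
  ``(1+z)^n_z`` to every accessible state, Bicoid recruits RNAP through the
  interaction ``omega_bp`` and self-cooperates through ``omega_b``;
* a generalized thermodynamic model with arbitrary non-negative state weights
  ``P_{r,i}`` for r RNAP and i Bicoid molecules bound, which contains every
  equilibrium model of Bicoid-activated transcription (Zelda and cooperativity
  factors fold into the weights), including Bicoid binding to inaccessible
  chromatin through a polynomial inaccessible weight.

Transcription follows the occupancy hypothesis: the RNAP loading rate is
``R * p_bound``, gated by a mitotic-repression window ``t_mitrep`` after
anaphase during which the rate is zero.

All closed forms are evaluated in log space so that large site numbers and
concentrations cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import comb
from typing import Iterable

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ThermoParams",
    "GeneralizedThermoParams",
    "StateWeight",
    "enumerate_states",
    "pbound_enumerated",
    "pbound_mwc",
    "pbound_generalized",
    "mwc_to_generalized",
    "loading_rate",
    "ThermoMWCModel",
    "GeneralizedThermoModel",
]


@dataclass
class ThermoParams:
    """Parameters of the thermodynamic MWC model.

    Energies are in k_BT units; dissociation constants are in the arbitrary
    concentration units of the matching input channel, so only ratios such as
    [Bicoid]/K_b are meaningful.  ``rnap_level`` is the dimensionless RNAP
    occupancy parameter p = [RNAP]/K_p, constant because RNAP concentration is
    not measured.  ``R`` is the transcription rate in the RNAP-bound states
    (RNAP loadings per minute) and ``t_mitrep`` the mitotic repression window
    in minutes.
    """

    n_b: int = 6
    n_z: int = 10
    K_b: float = 0.1
    K_z: float = 0.3
    omega_b: float = 1.0
    omega_bp: float = 3.0
    delta_eps_chrom: float = 4.0
    rnap_level: float = 0.1
    R: float = 15.0
    t_mitrep: float = 3.0

    def __post_init__(self) -> None:
        if self.K_b <= 0 or self.K_z <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.omega_b < 0 or self.omega_bp < 0 or self.rnap_level < 0:
            raise ValueError("omega terms and rnap_level must be non-negative")
        if self.n_b < 0 or self.n_z < 0:
            raise ValueError("site counts must be non-negative")
        if self.R < 0 or self.t_mitrep < 0:
            raise ValueError("R and t_mitrep must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoParams":
        return cls(**d)


@dataclass
class GeneralizedThermoParams:
    """Arbitrary-weight equilibrium model with n_b Bicoid sites (n_b <= 12).

    ``weights[r, i]`` is the non-negative weight of the accessible states with
    r in {0,1} RNAP and i in {0..n_b} Bicoid molecules bound; it carries units
    of concentration^-i so every term ``weights[r, i] * [Bicoid]^i`` is
    dimensionless.  ``p_inacc`` is the inaccessible-state weight: a scalar, or
    a polynomial-coefficient array in [Bicoid] to let Bicoid bind inaccessible
    chromatin.
    """

    n_b: int
    weights: np.ndarray
    p_inacc: float | np.ndarray = 1.0
    R: float = 15.0
    t_mitrep: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_b <= 12:
            raise ValueError("n_b must be between 0 and 12")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (2, self.n_b + 1):
            raise ValueError("weights must have shape (2, n_b + 1)")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        self._p_inacc_coeffs = np.atleast_1d(np.asarray(self.p_inacc, dtype=float))
        if np.any(self._p_inacc_coeffs < 0):
            raise ValueError("inaccessible-state weight must be non-negative")
        if self.R < 0 or self.t_mitrep < 0:
            raise ValueError("R and t_mitrep must be non-negative")

    def p_inacc_at(self, bicoid: np.ndarray) -> np.ndarray:
        """Inaccessible-state weight evaluated at a Bicoid concentration."""
        bicoid = np.asarray(bicoid, dtype=float)
        return np.polynomial.polynomial.polyval(bicoid, self._p_inacc_coeffs)

    def to_dict(self) -> dict:
        return {
            "n_b": self.n_b,
            "weights": self.weights.tolist(),
            "p_inacc": self._p_inacc_coeffs.tolist(),
            "R": self.R,
            "t_mitrep": self.t_mitrep,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneralizedThermoParams":
        d = dict(d)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        d["p_inacc"] = np.asarray(d["p_inacc"], dtype=float)
        return cls(**d)


@dataclass(frozen=True)
class StateWeight:
    """One microstate of the enumerated MWC promoter and its Boltzmann weight."""

    bicoid_occupancy: int
    zelda_occupancy: int
    rnap_bound: int
    accessible: bool

    def weight(self, params: ThermoParams, bicoid: float, zelda: float) -> float:
        """Numeric statistical weight at reduced activities b=[Bcd]/K_b, z=[Zld]/K_z."""
        if not self.accessible:
            return float(np.exp(params.delta_eps_chrom))
        b = bicoid / params.K_b
        z = zelda / params.K_z
        i, k, j = self.bicoid_occupancy, self.zelda_occupancy, self.rnap_bound
        w = comb(params.n_b, i) * b**i * params.omega_b ** max(i - 1, 0)
        w *= comb(params.n_z, k) * z**k
        w *= params.rnap_level**j * params.omega_bp ** (i * j)
        return float(w)


def enumerate_states(n_b: int, n_z: int) -> list[StateWeight]:
    """All promoter microstates: one inaccessible state plus every accessible
    (Bicoid occupancy, Zelda occupancy, RNAP) combination.

    This brute-force enumeration is the oracle for :func:`pbound_mwc`.
    """
    if n_b < 0 or n_z < 0:
        raise ValueError("site counts must be non-negative")
    states = [StateWeight(0, 0, 0, accessible=False)]
    for i in range(n_b + 1):
        for k in range(n_z + 1):
            for j in (0, 1):
                states.append(StateWeight(i, k, j, accessible=True))
    return states


def pbound_enumerated(params: ThermoParams, bicoid: float, zelda: float) -> float:
    """RNAP-bound probability by explicit summation over enumerated states."""
    states = enumerate_states(params.n_b, params.n_z)
    weights = np.array([s.weight(params, bicoid, zelda) for s in states])
    bound = np.array([s.rnap_bound == 1 for s in states])
    return float(weights[bound].sum() / weights.sum())


def _log_or_neginf(x: float) -> float:
    return float(np.log(x)) if x > 0 else -np.inf


def pbound_mwc(
    params: ThermoParams,
    bicoid: np.ndarray | float,
    zelda: np.ndarray | float,
) -> np.ndarray | float:
    """Closed-form probability of finding RNAP bound to the promoter.

    Vectorized over ``bicoid`` and ``zelda`` (broadcast together).  The Zelda
    factor ``(1+z)^n_z`` multiplies every accessible state and is divided out,
    so the inaccessible weight enters as
    ``exp(delta_eps_chrom) / (1+z)^n_z`` relative to the accessible sum.
    """
    bicoid = np.asarray(bicoid, dtype=float)
    zelda = np.asarray(zelda, dtype=float)
    if np.any(bicoid < 0) or np.any(zelda < 0):
        raise ValueError("concentrations must be non-negative")
    b, z = np.broadcast_arrays(bicoid / params.K_b, zelda / params.K_z)

    log_omega_b = _log_or_neginf(params.omega_b)
    log_omega_bp = _log_or_neginf(params.omega_bp)
    log_p = _log_or_neginf(params.rnap_level)
    with np.errstate(divide="ignore"):
        log_b = np.where(b > 0, np.log(np.where(b > 0, b, 1.0)), -np.inf)

    i = np.arange(params.n_b + 1)
    log_binom = np.array([np.log(comb(params.n_b, ii)) for ii in i])
    # accessible terms, shape (n_b+1, 2) + broadcast shape
    shape = (params.n_b + 1, 2) + b.shape
    log_terms = np.full(shape, -np.inf)
    for ii in i:
        base = log_binom[ii] + (ii * log_b if ii > 0 else 0.0)
        if ii > 1:
            base = base + (ii - 1) * log_omega_b
        for j in (0, 1):
            t = base if np.ndim(base) else np.full(b.shape, base)
            t = np.asarray(t, dtype=float).copy()
            if j == 1:
                t += log_p + ii * log_omega_bp
            log_terms[ii, j] = t
    log_terms = log_terms.reshape(-1, *b.shape)
    log_acc_all = logsumexp(log_terms, axis=0)
    log_acc_bound = logsumexp(log_terms.reshape(params.n_b + 1, 2, *b.shape)[:, 1], axis=0)
    log_inacc = params.delta_eps_chrom - params.n_z * np.log1p(z)
    log_denom = np.logaddexp(log_inacc, log_acc_all)
    out = np.exp(log_acc_bound - log_denom)
    return float(out) if out.ndim == 0 else out


def pbound_generalized(
    params: GeneralizedThermoParams, bicoid: np.ndarray | float
) -> np.ndarray | float:
    """RNAP-bound probability of the generalized thermodynamic model."""
    bicoid = np.asarray(bicoid, dtype=float)
    if np.any(bicoid < 0):
        raise ValueError("bicoid concentration must be non-negative")
    if not np.any(params.weights > 0):
        raise ValueError("degenerate model: all state weights are zero")
    with np.errstate(divide="ignore"):
        log_B = np.where(bicoid > 0, np.log(np.where(bicoid > 0, bicoid, 1.0)), -np.inf)
        log_w = np.where(params.weights > 0, np.log(np.where(params.weights > 0, params.weights, 1.0)), -np.inf)
    i = np.arange(params.n_b + 1)
    # log of weights[r, i] * B^i, broadcast over input shape
    with np.errstate(invalid="ignore"):
        powers = np.where(i[:, None] > 0, i[:, None] * log_B.reshape(1, -1), 0.0)
    log_terms = log_w[:, :, None].reshape(2, params.n_b + 1, -1) + powers.reshape(
        1, params.n_b + 1, -1
    )
    log_all = logsumexp(log_terms.reshape(2 * (params.n_b + 1), -1), axis=0)
    log_bound = logsumexp(log_terms[1], axis=0)
    p_inacc = np.maximum(params.p_inacc_at(bicoid), 0.0).reshape(-1)
    with np.errstate(divide="ignore"):
        log_inacc = np.where(p_inacc > 0, np.log(np.where(p_inacc > 0, p_inacc, 1.0)), -np.inf)
    log_denom = np.logaddexp(log_inacc, log_all)
    out = np.exp(log_bound - log_denom).reshape(bicoid.shape)
    return float(out) if out.ndim == 0 else out


def mwc_to_generalized(params: ThermoParams, zelda: float) -> GeneralizedThermoParams:
    """Exact embedding of the MWC model at a fixed Zelda concentration.

    ``P_{r,i} = C(n_b,i) omega_b^max(i-1,0) p^r omega_bp^(i r) (1+z)^n_z / K_b^i``
    and ``p_inacc = exp(delta_eps_chrom)``, so the generalized model reproduces
    :func:`pbound_mwc` at every Bicoid concentration.
    """
    z = zelda / params.K_z
    zfac = (1.0 + z) ** params.n_z
    weights = np.zeros((2, params.n_b + 1))
    for i in range(params.n_b + 1):
        base = comb(params.n_b, i) * params.omega_b ** max(i - 1, 0) * zfac / params.K_b**i
        weights[0, i] = base
        weights[1, i] = base * params.rnap_level * params.omega_bp**i
    return GeneralizedThermoParams(
        n_b=params.n_b,
        weights=weights,
        p_inacc=float(np.exp(params.delta_eps_chrom)),
        R=params.R,
        t_mitrep=params.t_mitrep,
    )


def loading_rate(
    pbound: np.ndarray | float,
    R: float,
    t: np.ndarray | float,
    t_mitrep: float,
) -> np.ndarray | float:
    """Occupancy-hypothesis RNAP loading rate with mitotic repression:
    0 for t < t_mitrep, R * p_bound afterwards."""
    out = np.where(np.asarray(t, dtype=float) < t_mitrep, 0.0, R * np.asarray(pbound, dtype=float))
    return float(out) if out.ndim == 0 else out


class ThermoMWCModel:
    """Forward model: thermodynamic MWC p_bound driven by dynamic inputs."""

    name = "thermo_mwc"

    def __init__(self, params: ThermoParams | None = None):
        self.params = params if params is not None else ThermoParams()

    def loading_rates(self, input_field) -> np.ndarray:
        """(n_positions, n_times) RNAP loading rates for an InputField."""
        p = pbound_mwc(self.params, input_field.bicoid, input_field.zelda[None, :])
        return loading_rate(p, self.params.R, input_field.time_grid[None, :], self.params.t_mitrep)


class GeneralizedThermoModel:
    """Forward model for the generalized thermodynamic model (Bicoid only)."""

    name = "generalized_thermo"

    def __init__(self, params: GeneralizedThermoParams):
        self.params = params

    def loading_rates(self, input_field) -> np.ndarray:
        p = pbound_generalized(self.params, input_field.bicoid)
        return loading_rate(p, self.params.R, input_field.time_grid[None, :], self.params.t_mitrep)
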