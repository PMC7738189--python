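"""Transcription-factor-driven chromatin accessibility model.

Instead of thermal accessible/inaccessible fluctuations, the locus traverses
``m`` transcriptionally silent states through irreversible transitions that are
catalyzed by the activators: each step proceeds at the common rate

    pi(t) = c_b * [Bicoid](t) + c_z * [Zelda](t).

Once the final transition has fired, chromatin is irreversibly accessible and
the promoter equilibrates instantly, so transcription proceeds at the
accessible-limit thermodynamic rate ``R * p_bound_accessible`` (no
inaccessible state, hence the Zelda binding factor cancels between numerator
and denominator and the accessible equilibrium depends on Bicoid alone).  No
mitotic-repression window is applied: the silent chain itself produces the
quiet period after anaphase.

The population-mean loading rate is ``P_open(t) * R * p_bound_accessible(t)``,
and a nucleus whose chain has not completed by the next mitosis never
transcribes, so the predicted fraction of active nuclei at a position is
``P_open(nc_duration)``.

The silent chain with a shared time-varying rate is an inhomogeneous Poisson
counting process: with cumulative hazard ``L(t) = int_0^t pi(s) ds`` the
probability of having completed at least m steps is the regularized lower
incomplete gamma function P(m, L(t)) -- the Erlang CDF when pi is constant.
This closed form is the exact solution of the chain ODEs
dP_k/dt = pi(t) (P_{k-1} - P_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import gammainc

from hbaccess.thermo import ThermoParams, pbound_mwc

__all__ = [
    "TFDrivenParams",
    "pi_rate",
    "opening_probability",
    "pbound_accessible",
    "mean_loading_rate",
    "fraction_active",
    "TFDrivenModel",
]


def _accessible_params(equilibrium: ThermoParams) -> ThermoParams:
    """Equilibrium sub-model restricted to accessible states.

    Implemented by sending the chromatin-opening cost to a very negative
    value, which removes the inaccessible state's weight from the partition
    function (and with it any Zelda dependence).
    """
    d = equilibrium.to_dict()
    d["delta_eps_chrom"] = -745.0  # exp() underflows to 0: accessible limit
    d["t_mitrep"] = 0.0
    return ThermoParams(**d)


@dataclass
class TFDrivenParams:
    """Parameters of the transcription-factor-driven accessibility model.

    ``m`` silent steps, each catalyzed at rate ``c_b * [Bcd] + c_z * [Zld]``
    (``c_b``, ``c_z`` in 1/(min * concentration unit)); ``equilibrium`` is the
    accessible-state thermodynamic sub-model (its ``delta_eps_chrom`` and
    ``t_mitrep`` are ignored); ``nc_duration`` is the time until the next
    mitosis in minutes (nuclear cycle 13 lasts about 17 min).
    """

    m: int = 3
    c_b: float = 1.0
    c_z: float = 3.0
    equilibrium: ThermoParams = field(default_factory=ThermoParams)
    nc_duration: float = 17.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.c_b < 0 or self.c_z < 0:
            raise ValueError("rate constants must be non-negative")
        if self.nc_duration <= 0:
            raise ValueError("nc_duration must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TFDrivenParams":
        d = dict(d)
        if isinstance(d.get("equilibrium"), dict):
            d["equilibrium"] = ThermoParams(**d["equilibrium"])
        return cls(**d)


def pi_rate(
    c_b: float,
    c_z: float,
    bicoid: np.ndarray | float,
    zelda: np.ndarray | float,
) -> np.ndarray | float:
    """Per-step transition rate pi = c_b [Bicoid] + c_z [Zelda] (1/min)."""
    bicoid = np.asarray(bicoid, dtype=float)
    zelda = np.asarray(zelda, dtype=float)
    if np.any(bicoid < 0) or np.any(zelda < 0):
        raise ValueError("concentrations must be non-negative")
    out = c_b * bicoid + c_z * zelda
    return float(out) if out.ndim == 0 else out


def opening_probability(
    m: int,
    pi_timecourse: np.ndarray,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Probability that the chain of ``m`` silent steps has completed by t.

    Solves dP_k/dt = pi(t) (P_{k-1} - P_k), k = 1..m, P_0(0) = 1 through the
    exact inhomogeneous-Poisson form: P_open(t) = P(m, L(t)) with L the
    trapezoidal cumulative integral of pi.  Monotone non-decreasing in t.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    pi_timecourse = np.asarray(pi_timecourse, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(pi_timecourse < 0):
        raise ValueError("pi(t) must be non-negative")
    if pi_timecourse.shape != time_grid.shape:
        raise ValueError("pi timecourse must cover the time grid")
    hazard = cumulative_trapezoid(pi_timecourse, time_grid, initial=0.0)
    return gammainc(m, hazard)


def pbound_accessible(
    equilibrium: ThermoParams,
    bicoid: np.ndarray | float,
    zelda: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """RNAP-bound probability of the accessible-limit equilibrium sub-model.

    Provably independent of Zelda (the (1+z)^n_z factor cancels); the ``zelda``
    argument is accepted so the cancellation can be asserted, not assumed.
    """
    return pbound_mwc(_accessible_params(equilibrium), bicoid, zelda)


def mean_loading_rate(
    params: TFDrivenParams,
    bicoid: np.ndarray,
    zelda: np.ndarray,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Population-mean RNAP loading rate P_open(t) * R * p_bound_accessible(t)."""
    pi = pi_rate(params.c_b, params.c_z, bicoid, zelda)
    p_open = opening_probability(params.m, np.atleast_1d(pi), time_grid)
    pb = pbound_accessible(params.equilibrium, bicoid, zelda)
    return p_open * params.equilibrium.R * pb


def fraction_active(
    params: TFDrivenParams,
    bicoid: np.ndarray,
    zelda: np.ndarray,
    time_grid: np.ndarray,
) -> float:
    """Probability a nucleus becomes accessible before the next mitosis."""
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid[-1] < params.nc_duration - 1e-9:
        raise ValueError("trajectories must cover [0, nc_duration]")
    pi = pi_rate(params.c_b, params.c_z, bicoid, zelda)
    p_open = opening_probability(params.m, np.atleast_1d(pi), time_grid)
    return float(np.interp(params.nc_duration, time_grid, p_open))


class TFDrivenModel:
    """Forward model: TF-catalyzed opening followed by accessible equilibrium."""

    name = "tf_driven"

    def __init__(self, params: TFDrivenParams | None = None):
        self.params = params if params is not None else TFDrivenParams()

    def loading_rates(self, input_field) -> np.ndarray:
        t = input_field.time_grid
        z = input_field.zelda
        rates = np.empty((input_field.positions.size, t.size))
        for k in range(input_field.positions.size):
            rates[k] = mean_loading_rate(self.params, input_field.bicoid[k], z, t)
        return rates

    def fraction_active_profile(self, input_field) -> np.ndarray:
        """Predicted fraction of transcribing nuclei at each position."""
        return np.array(
            [
                fraction_active(self.params, input_field.bicoid[k], input_field.zelda, input_field.time_grid)
                for k in range(input_field.positions.size)
            ]
        )
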