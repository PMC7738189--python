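"""Non-equilibrium MWC promoter model.

The same state space as the thermodynamic MWC model (inaccessible chromatin,
accessible chromatin crossed with Bicoid occupancy and an RNAP flag) is endowed
with free, independent transition rates and solved as a system of coupled
linear ODEs, dP/dt = M(t) P, starting from all probability in the inaccessible
state (chromatin is inaccessible at the start of the nuclear cycle).

Concentration dependence enters only through binding edges: a Bicoid-binding
edge has propensity ``rate_constant * [Bicoid](t)`` and an RNAP-binding edge
``rate_constant * rnap_level``; unbinding and chromatin opening/closing edges
are concentration-independent.  No detailed-balance constraint is imposed, so
the model can dissipate energy; the thermodynamic model is recovered in the
fast-rate, detailed-balance limit (see :func:`detailed_balance_graph`).

Mitotic repression comes in two variants: ``transcription-only`` (the states
evolve from anaphase but the transcription rate is clamped to zero before
``t_mitrep``) and ``frozen-evolution`` (the state vector itself is held at the
initial condition until ``t_mitrep``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import comb
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from hbaccess.thermo import ThermoParams, loading_rate

__all__ = [
    "StateGraph",
    "NoneqParams",
    "build_state_graph",
    "propagate",
    "pbound_timecourse",
    "detailed_balance_graph",
    "NoneqMWCModel",
]

MAX_SITES = 5  # combinatorial guard: the state space grows too fast beyond this

Dependence = Literal["none", "bicoid", "rnap"]


@dataclass
class StateGraph:
    """Labelled promoter state space with per-edge rate constants.

    ``states`` are tuples ``(accessible, bicoid_config, rnap)`` where
    ``bicoid_config`` is an occupancy count (occupancy mode) or a tuple of
    per-site flags (configuration mode).  ``rate_entries`` maps a directed
    state-index pair ``(i, j)`` to ``(rate_constant, dependence)`` with
    dependence one of 'none', 'bicoid', 'rnap'.  Rate-constant units are 1/min,
    or 1/(min * concentration unit) for concentration-dependent edges.
    """

    states: list[tuple]
    rate_entries: dict[tuple[int, int], tuple[float, Dependence]]

    def __post_init__(self) -> None:
        for (i, j), (k, dep) in self.rate_entries.items():
            if i == j:
                raise ValueError("self-edges are not allowed")
            if k < 0:
                raise ValueError("rates must be non-negative")
            if dep not in ("none", "bicoid", "rnap"):
                raise ValueError(f"unknown dependence {dep!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rnap_bound_mask(self) -> np.ndarray:
        return np.array([bool(s[2]) for s in self.states])

    def with_rates(self, rates: np.ndarray | dict) -> "StateGraph":
        """Copy of the graph with new rate constants (edge order preserved)."""
        keys = list(self.rate_entries)
        if isinstance(rates, dict):
            new = {k: (float(rates[k]), self.rate_entries[k][1]) for k in keys}
        else:
            rates = np.asarray(rates, dtype=float)
            if rates.shape != (len(keys),):
                raise ValueError("rates must match the number of edges")
            new = {k: (float(r), self.rate_entries[k][1]) for k, r in zip(keys, rates)}
        return StateGraph(states=list(self.states), rate_entries=new)

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a table (state_i, state_j, rate_constant, dependence)."""
        rows = [
            {"state_i": i, "state_j": j, "rate_constant": k, "dependence": dep}
            for (i, j), (k, dep) in self.rate_entries.items()
        ]
        return pd.DataFrame(rows)

    def with_rates_from_frame(self, frame: pd.DataFrame) -> "StateGraph":
        """Apply rate constants from an edge-list table written by to_frame.

        The graph skeleton (states and edge set) must match; unknown edges in
        the table raise a ValueError.
        """
        required = {"state_i", "state_j", "rate_constant"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        rates = dict(self.rate_entries)
        for _, row in frame.iterrows():
            key = (int(row["state_i"]), int(row["state_j"]))
            if key not in rates:
                raise ValueError(f"edge {key} not present in this graph")
            rates[key] = (float(row["rate_constant"]), rates[key][1])
        return StateGraph(states=list(self.states), rate_entries=rates)


@dataclass
class NoneqParams:
    """Non-equilibrium MWC model parameters: a rate graph plus output scaling."""

    n_b: int
    graph: StateGraph
    R: float = 15.0
    t_mitrep: float = 3.0
    mitrep_variant: Literal["transcription-only", "frozen-evolution"] = "transcription-only"
    rnap_level: float = 1.0

    def __post_init__(self) -> None:
        if self.n_b > MAX_SITES:
            raise ValueError(f"n_b > {MAX_SITES} is unsupported (combinatorial guard)")
        if self.mitrep_variant not in ("transcription-only", "frozen-evolution"):
            raise ValueError(f"unknown mitotic-repression variant {self.mitrep_variant!r}")


def build_state_graph(
    n_b: int,
    site_resolution: Literal["occupancy", "configuration"] = "configuration",
    rate_constant: float = 1.0,
) -> StateGraph:
    """Promoter state graph for ``n_b`` Bicoid sites.

    One inaccessible state plus accessible states crossed with Bicoid
    configuration and an RNAP flag.  In occupancy mode Bicoid configurations
    are counts 0..n_b (binding edge i -> i+1 carries a combinatorial factor
    ``n_b - i`` and unbinding i -> i-1 a factor ``i``); in configuration mode
    every subset of sites is a distinct state and edges flip single sites.
    Chromatin opening/closing edges connect the inaccessible state to the
    empty accessible state only.  All edges start at ``rate_constant``.
    """
    if not 0 <= n_b <= MAX_SITES:
        raise ValueError(f"n_b must be between 0 and {MAX_SITES}")
    states: list[tuple] = [("inaccessible", None, 0)]
    if site_resolution == "occupancy":
        configs: list = list(range(n_b + 1))
    elif site_resolution == "configuration":
        configs = [tuple(bits) for bits in product((0, 1), repeat=n_b)]
    else:
        raise ValueError(f"unknown site_resolution {site_resolution!r}")
    for cfg in configs:
        for rnap in (0, 1):
            states.append(("accessible", cfg, rnap))
    index = {s: i for i, s in enumerate(states)}

    entries: dict[tuple[int, int], tuple[float, Dependence]] = {}

    def add(a: tuple, b: tuple, dep: Dependence, multiplicity: float = 1.0) -> None:
        entries[(index[a], index[b])] = (rate_constant * multiplicity, dep)

    empty = 0 if site_resolution == "occupancy" else tuple([0] * n_b)
    add(("inaccessible", None, 0), ("accessible", empty, 0), "none")  # opening
    add(("accessible", empty, 0), ("inaccessible", None, 0), "none")  # closing
    for cfg in configs:
        for rnap in (0, 1):
            s = ("accessible", cfg, rnap)
            # RNAP binding / unbinding
            add(s, ("accessible", cfg, 1 - rnap), "rnap" if rnap == 0 else "none")
            # Bicoid binding / unbinding
            if site_resolution == "occupancy":
                if cfg < n_b:
                    add(s, ("accessible", cfg + 1, rnap), "bicoid", multiplicity=n_b - cfg)
                if cfg > 0:
                    add(s, ("accessible", cfg - 1, rnap), "none", multiplicity=cfg)
            else:
                for site in range(n_b):
                    flipped = list(cfg)
                    flipped[site] = 1 - cfg[site]
                    dep: Dependence = "bicoid" if cfg[site] == 0 else "none"
                    add(s, ("accessible", tuple(flipped), rnap), dep)
    return StateGraph(states=states, rate_entries=entries)


def _rate_matrix_builder(params: NoneqParams, bicoid_of_t):
    """Return M(t) such that dP/dt = M(t) P."""
    graph = params.graph
    n = graph.n_states
    edges = [(ij, k, dep) for ij, (k, dep) in graph.rate_entries.items()]

    def M(t: float) -> np.ndarray:
        b = float(bicoid_of_t(t))
        mat = np.zeros((n, n))
        for (i, j), k, dep in edges:
            rate = k
            if dep == "bicoid":
                rate *= b
            elif dep == "rnap":
                rate *= params.rnap_level
            mat[j, i] += rate
            mat[i, i] -= rate
        return mat

    return M


def propagate(
    params: NoneqParams,
    bicoid: np.ndarray,
    time_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: Literal["bdf", "expm"] = "bdf",
    expm_substep: float = 0.1,
) -> np.ndarray:
    """Solve the master equation from an all-inaccessible initial condition.

    ``bicoid`` is the Bicoid concentration sampled on ``time_grid``
    (interpolated linearly between samples).  Returns the state-probability
    table with shape (n_states, n_times); columns sum to one.

    Two integrators are available: ``bdf`` (implicit stiff solver at the given
    tolerances) and ``expm`` (matrix-exponential stepping with the generator
    held at its midpoint value over substeps of at most ``expm_substep``
    minutes -- exact for constant inputs and arbitrarily stiff rates, used by
    the parameter-space sweeps for speed).
    """
    time_grid = np.asarray(time_grid, dtype=float)
    bicoid = np.asarray(bicoid, dtype=float)
    if bicoid.shape != time_grid.shape:
        raise ValueError("bicoid trajectory must cover the time grid")

    def bicoid_of_t(t: float) -> float:
        return float(np.interp(t, time_grid, bicoid))

    M = _rate_matrix_builder(params, bicoid_of_t)
    p0 = np.zeros(params.graph.n_states)
    p0[0] = 1.0  # inaccessible start

    t_start = time_grid[0]
    frozen = params.mitrep_variant == "frozen-evolution" and params.t_mitrep > t_start
    if frozen:
        t_start = min(params.t_mitrep, time_grid[-1])

    out = np.tile(p0[:, None], (1, time_grid.size))
    active = time_grid > t_start
    eval_times = time_grid[active]
    if eval_times.size:
        if method == "bdf":
            sol = solve_ivp(
                lambda t, p: M(t) @ p,
                (t_start, time_grid[-1]),
                p0,
                method="BDF",
                t_eval=eval_times,
                rtol=rtol,
                atol=atol,
                jac=lambda t, p: M(t),
            )
            if not sol.success:
                raise RuntimeError(f"master-equation integration failed: {sol.message}")
            out[:, active] = sol.y
        elif method == "expm":
            from scipy.linalg import expm

            p = p0.copy()
            t_prev = t_start
            cols = np.nonzero(active)[0]
            for col in cols:
                t_next = time_grid[col]
                n_sub = max(1, int(np.ceil((t_next - t_prev) / expm_substep)))
                for s in range(n_sub):
                    a = t_prev + (t_next - t_prev) * s / n_sub
                    b_ = t_prev + (t_next - t_prev) * (s + 1) / n_sub
                    p = expm(M((a + b_) / 2) * (b_ - a)) @ p
                out[:, col] = p
                t_prev = t_next
        else:
            raise ValueError(f"unknown method {method!r}")
    # clip tiny negative excursions from the solver
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=0, keepdims=True)
    return out


def pbound_timecourse(state_probs: np.ndarray, graph: StateGraph) -> np.ndarray:
    """Probability of the RNAP-bound states at each time point."""
    mask = graph.rnap_bound_mask()
    return state_probs[mask].sum(axis=0)


def detailed_balance_graph(
    thermo: ThermoParams,
    graph: StateGraph,
    bicoid: float,
    zelda: float = 0.0,
    scale: float = 1.0,
) -> StateGraph:
    """Rates satisfying detailed balance with the thermodynamic Boltzmann weights.

    For every directed edge the rate is ``scale * sqrt(w_target / w_source)``
    with ``w`` the equilibrium weight of the state at the given (constant)
    concentrations; concentration factors are folded into the constants and
    every edge marked concentration-independent.  As ``scale`` grows, the
    kinetic model equilibrates faster and its p_bound converges to the
    thermodynamic one -- the equilibrium-limit oracle.
    """
    weights = equilibrium_weights(thermo, graph, bicoid, zelda)
    logw = np.where(weights > 0, np.log(np.where(weights > 0, weights, 1.0)), -np.inf)
    entries = {}
    for (i, j), (_, _dep) in graph.rate_entries.items():
        if not np.isfinite(logw[i]) or not np.isfinite(logw[j]):
            rate = 0.0
        else:
            rate = scale * float(np.exp(0.5 * (logw[j] - logw[i])))
        entries[(i, j)] = (rate, "none")
    return StateGraph(states=list(graph.states), rate_entries=entries)


def equilibrium_weights(
    thermo: ThermoParams, graph: StateGraph, bicoid: float, zelda: float = 0.0
) -> np.ndarray:
    """Thermodynamic Boltzmann weight of each graph state at fixed inputs.

    The graph has no explicit Zelda states; the Zelda factor ``(1+z)^n_z``
    multiplies every accessible weight exactly as in the closed form.
    """
    b = bicoid / thermo.K_b
    zfac = (1.0 + zelda / thermo.K_z) ** thermo.n_z
    weights = np.empty(graph.n_states)
    for idx, (acc, cfg, rnap) in enumerate(graph.states):
        if acc == "inaccessible":
            weights[idx] = np.exp(thermo.delta_eps_chrom)
            continue
        i = int(cfg) if np.isscalar(cfg) else int(sum(cfg))
        mult = comb(thermo.n_b, i) if np.isscalar(cfg) else 1  # configs already distinct
        w = mult * b**i * thermo.omega_b ** max(i - 1, 0)
        w *= thermo.rnap_level**rnap * thermo.omega_bp ** (i * rnap)
        weights[idx] = zfac * w
    return weights


class NoneqMWCModel:
    """Forward model: non-equilibrium MWC state graph driven by Bicoid dynamics."""

    name = "noneq_mwc"

    def __init__(self, params: NoneqParams, method: Literal["bdf", "expm"] = "bdf"):
        self.params = params
        self.method = method

    def loading_rates(self, input_field) -> np.ndarray:
        """(n_positions, n_times) loading rates; Zelda plays no role here."""
        t = input_field.time_grid
        rates = np.empty((input_field.positions.size, t.size))
        for k in range(input_field.positions.size):
            probs = propagate(self.params, input_field.bicoid[k], t, method=self.method)
            pb = pbound_timecourse(probs, self.params.graph)
            rates[k] = loading_rate(pb, self.params.R, t, self.params.t_mitrep)
        return rates
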