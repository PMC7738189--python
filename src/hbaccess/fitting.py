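"""Least-squares fitting of promoter models to onset/rate position profiles.

:class:`ProfileFit` is a statsmodels-style Model object: it is constructed
from one or more datasets (a :class:`~hbaccess.features.PositionProfile` with
its :class:`~hbaccess.inputs.InputField`; zelda-null datasets zero the Zelda
channel) and a model class name.  ``fit()`` minimizes the SEM-weighted sum of
squared residuals of the initial RNAP loading rate and t_on simultaneously
over all datasets with a single shared parameter set, using bounded
least-squares with seeded multi-starts (the objective is non-convex in the
interaction and chromatin-energy parameters), and returns a
:class:`ProfileFitResults` carrying estimates, curvature-based standard
errors, diagnostics and a ``summary()`` table.

Positions failing the 30% activity filter are excluded from the residuals; a
configurable penalty is charged per position where model and data disagree
about whether transcription happens at all.  :func:`select_m` fits the
TF-driven model for each number of silent steps m and returns the smallest m
whose reduced objective is within a tolerance factor of the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from hbaccess.features import FeatureConfig, PositionProfile
from hbaccess.inputs import InputField
from hbaccess.tfdriven import TFDrivenModel, TFDrivenParams
from hbaccess.thermo import ThermoMWCModel, ThermoParams
from hbaccess.trace import ElongationParams, predict_position_profile

__all__ = ["ProfileFit", "ProfileFitResults", "select_m"]


_FREE_PARAMS: dict[str, dict[str, tuple[float, float, bool]]] = {
    # name -> (lower, upper, log_scale)
    "thermo_mwc": {
        "K_b": (1e-3, 1e2, True),
        "K_z": (1e-3, 1e2, True),
        "omega_b": (1e-2, 1e3, True),
        "omega_bp": (1e-2, 1e3, True),
        "delta_eps_chrom": (-10.0, 10.0, False),
        "t_mitrep": (0.0, 6.0, False),
        "R": (1.0, 100.0, True),
    },
    "tf_driven": {
        "c_b": (1e-3, 1e2, True),
        "c_z": (1e-4, 1e2, True),
        "K_b": (1e-3, 1e2, True),
        "R": (1.0, 100.0, True),
    },
}


def _build_model(model_class: str, params: dict, fixed: dict):
    if model_class == "thermo_mwc":
        return ThermoMWCModel(ThermoParams(**{**fixed, **params}))
    if model_class == "tf_driven":
        merged = {**fixed, **params}
        eq = ThermoParams(
            K_b=merged.pop("K_b"),
            R=merged.pop("R"),
            omega_b=merged.pop("omega_b", 1.0),
            omega_bp=merged.pop("omega_bp", 3.0),
        )
        return TFDrivenModel(TFDrivenParams(equilibrium=eq, **merged))
    raise ValueError(f"unsupported model class for fitting: {model_class!r}")


@dataclass
class _Dataset:
    profile: PositionProfile
    input_field: InputField
    genotype: str = "wild-type"

    def __post_init__(self) -> None:
        if self.genotype == "zelda-null":
            self.input_field = self.input_field.zelda_nulled()


class ProfileFit:
    """Simultaneous fit of a promoter model class to position profiles.

    Parameters
    ----------
    model_class : 'thermo_mwc' or 'tf_driven'
    datasets : sequence of (PositionProfile, InputField, genotype) tuples;
        all datasets share one parameter set.
    fixed : parameter values held constant (e.g. ``{"m": 3}``).
    bounds : overrides of the default per-parameter bounds.
    mismatch_penalty : residual charged per position where the model predicts
        activity and the data show none, or vice versa.
    """

    def __init__(
        self,
        model_class: str,
        datasets: Sequence[tuple],
        fixed: dict | None = None,
        bounds: dict | None = None,
        elong: ElongationParams | None = None,
        feature_config: FeatureConfig | None = None,
        mismatch_penalty: float = 10.0,
    ):
        if model_class not in _FREE_PARAMS:
            raise ValueError(f"unsupported model class {model_class!r}")
        self.model_class = model_class
        self.datasets = [_Dataset(*d) for d in datasets]
        if not self.datasets:
            raise ValueError("need at least one dataset")
        self.fixed = dict(fixed or {})
        self.elong = elong if elong is not None else ElongationParams()
        self.feature_config = feature_config if feature_config is not None else FeatureConfig()
        self.mismatch_penalty = mismatch_penalty
        spec = {k: v for k, v in _FREE_PARAMS[model_class].items() if k not in self.fixed}
        if bounds:
            spec = {k: (bounds.get(k, v)[0], bounds.get(k, v)[1], v[2]) for k, v in spec.items()}
        self.param_names = list(spec)
        self._spec = spec

    # -- internal transforms: optimize log-scale parameters in log space -----
    def _to_internal(self, values: dict) -> np.ndarray:
        return np.array(
            [
                np.log(values[k]) if self._spec[k][2] else values[k]
                for k in self.param_names
            ]
        )

    def _from_internal(self, x: np.ndarray) -> dict:
        return {
            k: float(np.exp(v)) if self._spec[k][2] else float(v)
            for k, v in zip(self.param_names, x)
        }

    def _internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [np.log(s[0]) if s[2] else s[0] for s in (self._spec[k] for k in self.param_names)]
        )
        hi = np.array(
            [np.log(s[1]) if s[2] else s[1] for s in (self._spec[k] for k in self.param_names)]
        )
        return lo, hi

    def residuals(self, params: dict) -> np.ndarray:
        """SEM-weighted residual vector over all datasets and observables.

        The vector has a fixed length independent of the parameters: positions
        active in the data contribute one residual per observable (the
        mismatch penalty when the model predicts no activity there), and
        data-inactive positions contribute one slot that is zero unless the
        model wrongly predicts activity.
        """
        model = _build_model(self.model_class, params, self.fixed)
        out = []
        for ds in self.datasets:
            pred = predict_position_profile(model, ds.input_field, self.elong, self.feature_config)
            data = ds.profile
            both = data.active_mask & pred.active_mask
            for obs, sem_arr in (("init_rate", data.init_rate_sem), ("t_on", data.t_on_sem)):
                d = getattr(data, obs)
                p = getattr(pred, obs)
                sem = sem_arr if sem_arr is not None else np.ones_like(d)
                sem = np.clip(np.nan_to_num(sem, nan=1.0), 1e-3, None)
                r = np.where(both, (np.nan_to_num(p) - np.nan_to_num(d)) / sem, 0.0)
                r = np.where(data.active_mask & ~pred.active_mask, self.mismatch_penalty, r)
                out.append(r[data.active_mask])
            false_positive = ~data.active_mask & pred.active_mask
            out.append(np.where(false_positive, self.mismatch_penalty, 0.0)[~data.active_mask])
        total = np.concatenate(out)
        # never hand the optimizer an empty residual vector
        return total if total.size else np.array([self.mismatch_penalty])

    def objective(self, params: dict) -> float:
        r = self.residuals(params)
        return float(np.sum(r**2))

    def fit(
        self,
        start: dict | None = None,
        n_starts: int = 8,
        seed: int = 0,
        xtol: float = 1e-10,
        ftol: float = 1e-10,
    ) -> "ProfileFitResults":
        """Bounded least squares from ``n_starts`` seeded random initializations
        (plus ``start`` if given); returns the best local optimum found."""
        rng = np.random.default_rng(seed)
        lo, hi = self._internal_bounds()
        starts = []
        if start is not None:
            midpoint = self._from_internal((lo + hi) / 2)
            starts.append(self._to_internal({**midpoint, **start}))
        for _ in range(n_starts):
            starts.append(rng.uniform(lo, hi))

        def fun(x: np.ndarray) -> np.ndarray:
            return self.residuals(self._from_internal(x))

        best = None
        n_fail = 0
        objectives = []
        for x0 in starts:
            try:
                sol = least_squares(
                    fun, np.clip(x0, lo, hi), bounds=(lo, hi), xtol=xtol, ftol=ftol,
                    x_scale="jac", method="trf",
                )
            except Exception:
                n_fail += 1
                continue
            cost = 2 * sol.cost
            objectives.append(cost)
            if best is None or cost < 2 * best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        params = self._from_internal(best.x)
        bse = self._standard_errors(best)
        n_resid = best.fun.size
        return ProfileFitResults(
            model=self,
            params=params,
            bse=bse,
            objective=float(2 * best.cost),
            residuals=best.fun,
            nobs=n_resid,
            n_starts=len(starts),
            n_failed_starts=n_fail,
            start_objectives=np.array(objectives),
            success=bool(best.success),
            seed=seed,
        )

    def _standard_errors(self, sol) -> dict:
        """Curvature (J^T J) based standard errors, mapped out of log space."""
        J = sol.jac
        try:
            cov = np.linalg.pinv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((J.shape[1], J.shape[1]), np.nan)
        se_internal = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        out = {}
        for k, x, se in zip(self.param_names, sol.x, se_internal):
            # d(exp x) = exp(x) dx for log-scale parameters
            out[k] = float(np.exp(x) * se) if self._spec[k][2] else float(se)
        return out


@dataclass
class ProfileFitResults:
    """Estimates, uncertainties and diagnostics of a ProfileFit."""

    model: ProfileFit
    params: dict
    bse: dict
    objective: float
    residuals: np.ndarray
    nobs: int
    n_starts: int
    n_failed_starts: int
    start_objectives: np.ndarray
    success: bool
    seed: int

    @property
    def objective_reduced(self) -> float:
        dof = max(self.nobs - len(self.params), 1)
        return self.objective / dof

    def predicted_profiles(self) -> list[PositionProfile]:
        m = _build_model(self.model.model_class, self.params, self.model.fixed)
        return [
            predict_position_profile(m, ds.input_field, self.model.elong, self.model.feature_config)
            for ds in self.model.datasets
        ]

    def summary(self) -> str:
        lines = [
            f"{'Promoter model fit':^60}",
            "=" * 60,
            f"model class:        {self.model.model_class}",
            f"datasets:           {len(self.model.datasets)} "
            f"({', '.join(ds.genotype for ds in self.model.datasets)})",
            f"residuals:          {self.nobs}",
            f"objective (SSR):    {self.objective:.6g}",
            f"reduced objective:  {self.objective_reduced:.6g}",
            f"multi-starts:       {self.n_starts} ({self.n_failed_starts} failed)",
            f"converged:          {self.success}",
            "-" * 60,
            f"{'parameter':<18}{'estimate':>14}{'std err':>14}",
            "-" * 60,
        ]
        for k in self.model.param_names:
            lines.append(f"{k:<18}{self.params[k]:>14.5g}{self.bse.get(k, np.nan):>14.3g}")
        for k, v in self.model.fixed.items():
            lines.append(f"{k:<18}{v!s:>14} (fixed)")
        lines.append("=" * 60)
        return "\n".join(lines)


def select_m(
    datasets: Sequence[tuple],
    m_range: Sequence[int] = (1, 2, 3, 4),
    criterion: float = 1.2,
    fixed: dict | None = None,
    n_starts: int = 4,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of silent steps m for the TF-driven model.

    Fits the model for every m in ``m_range`` and returns the smallest m whose
    reduced objective is within ``criterion`` times the minimum across the
    range, together with the per-m objective table.
    """
    if not len(m_range):
        raise ValueError("m_range must be non-empty")
    rows = []
    for m in m_range:
        fit = ProfileFit("tf_driven", datasets, fixed={**(fixed or {}), "m": int(m)}, **fit_kwargs)
        res = fit.fit(n_starts=n_starts, seed=seed)
        rows.append({"m": int(m), "objective": res.objective, "objective_reduced": res.objective_reduced})
    table = pd.DataFrame(rows)
    best = table["objective_reduced"].min()
    chosen = int(table.loc[table["objective_reduced"] <= criterion * best, "m"].min())
    return chosen, table
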