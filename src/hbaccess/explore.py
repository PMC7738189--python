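"""Parameter-space exploration of the promoter model classes.

Each model class is sampled log-uniformly within per-parameter bounds; every
draw is pushed through the full forward chain (dynamic inputs -> loading rate
-> RNAP-number trace -> onset features) and condensed to a
(t_on offset, average t_on delay) point.  The cloud of attainable points is
rasterized on a fixed-bin occupancy grid so that attainable regions of
different model classes can be compared against measured signature points --
the discrimination geometry at the heart of the analysis: classes whose
response is slaved to the input dynamics cannot produce position-dependent
onset delays, while transcription-factor-driven opening can.

A plateau constraint normalizes the overall rate scale R of each draw so that
its largest initial loading rate matches a reference plateau value (the
anterior plateau of the measured loading-rate profile constrains the maximum
theoretically allowed rate).  Onset times are invariant under this rescaling;
it only anchors detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from hbaccess.features import FeatureConfig, PositionProfile, SignaturePoint, ton_offset, avg_ton_delay
from hbaccess.inputs import InputField
from hbaccess.kinetic import NoneqMWCModel, NoneqParams, build_state_graph
from hbaccess.tfdriven import TFDrivenModel, TFDrivenParams
from hbaccess.thermo import (
    GeneralizedThermoModel,
    GeneralizedThermoParams,
    ThermoMWCModel,
    ThermoParams,
)
from hbaccess.trace import ElongationParams, predict_position_profile

__all__ = [
    "RegionSample",
    "default_ranges",
    "sample_parameter_space",
    "region_contains",
    "compare_regions",
]

RASTER_BIN = 0.1  # minutes, offset x delay cell size; finer than the data SEM ellipses

MODEL_CLASSES = ("thermo_mwc", "generalized_thermo", "noneq_mwc", "tf_driven")


@dataclass
class RegionSample:
    """A sampled cloud of (offset, delay) points and its rasterized region."""

    model_class: str
    samples: pd.DataFrame  # one row per draw: parameters, offset, avg_delay, all_active
    raster: np.ndarray  # boolean occupancy grid, shape (n_offset_bins, n_delay_bins)
    offset_edges: np.ndarray
    delay_edges: np.ndarray
    seed: int
    n_requested: int

    @property
    def n_valid(self) -> int:
        return int(self.samples["valid"].sum())

    @property
    def area(self) -> float:
        """Occupied raster area in min^2."""
        cell = (self.offset_edges[1] - self.offset_edges[0]) * (
            self.delay_edges[1] - self.delay_edges[0]
        )
        return float(self.raster.sum() * cell)


def default_ranges(model_class: str) -> dict[str, tuple]:
    """Log-bounds (or integer choices) per parameter for each model class.

    Dissociation constants span 1e-2..1e2 in input concentration units, the
    cooperativity/interaction factors 1e-2..1e3, the chromatin opening cost
    -10..+10 k_BT (linear), the mitotic repression window 0..4 min (linear),
    catalytic rate constants 1e-4..1e1, and m ranges over 1..6.
    """
    if model_class == "thermo_mwc":
        return {
            "K_b": (1e-2, 1e2, "log"),
            "K_z": (1e-2, 1e2, "log"),
            "omega_b": (1e-2, 1e3, "log"),
            "omega_bp": (1e-2, 1e3, "log"),
            "delta_eps_chrom": (-10.0, 10.0, "linear"),
            "t_mitrep": (0.0, 4.0, "linear"),
        }
    if model_class == "generalized_thermo":
        return {
            "n_b": (1, 12, "int"),
            "log_weight": (-6.0, 6.0, "linear"),  # per-weight decadic exponent
            "t_mitrep": (0.0, 4.0, "linear"),
        }
    if model_class == "noneq_mwc":
        return {
            "n_b": (1, 5, "int"),
            "rate": (1e-2, 1e2, "log"),  # every edge rate constant, 1/min
            "t_mitrep": (0.0, 4.0, "linear"),
        }
    if model_class == "tf_driven":
        return {
            "m": (1, 6, "int"),
            "c_b": (1e-4, 1e1, "log"),
            "c_z": (1e-4, 1e1, "log"),
            "K_b": (1e-2, 1e2, "log"),
            "omega_bp": (1e-2, 1e3, "log"),
        }
    raise ValueError(f"unknown model class {model_class!r}")


def _draw(rng: np.random.Generator, lo, hi, kind: str):
    if kind == "log":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if kind == "linear":
        return float(rng.uniform(lo, hi))
    if kind == "int":
        return int(rng.integers(lo, hi + 1))
    raise ValueError(f"unknown draw kind {kind!r}")


def _model_from_draw(model_class: str, draw: dict, rng: np.random.Generator, ranges: dict):
    if model_class == "thermo_mwc":
        params = ThermoParams(
            K_b=draw["K_b"],
            K_z=draw["K_z"],
            omega_b=draw["omega_b"],
            omega_bp=draw["omega_bp"],
            delta_eps_chrom=draw["delta_eps_chrom"],
            t_mitrep=draw["t_mitrep"],
        )
        return ThermoMWCModel(params)
    if model_class == "generalized_thermo":
        n_b = draw["n_b"]
        lo, hi, _ = ranges["log_weight"]
        weights = 10.0 ** rng.uniform(lo, hi, size=(2, n_b + 1))
        p_inacc = 10.0 ** rng.uniform(lo, hi, size=rng.integers(1, 3))  # optionally linear in Bicoid
        params = GeneralizedThermoParams(
            n_b=n_b, weights=weights, p_inacc=p_inacc, t_mitrep=draw["t_mitrep"]
        )
        return GeneralizedThermoModel(params)
    if model_class == "noneq_mwc":
        n_b = draw["n_b"]
        graph = build_state_graph(n_b, site_resolution="occupancy")
        lo, hi, _ = ranges["rate"]
        rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(graph.rate_entries)))
        params = NoneqParams(n_b=n_b, graph=graph.with_rates(rates), t_mitrep=draw["t_mitrep"])
        return NoneqMWCModel(params, method="expm")
    if model_class == "tf_driven":
        eq = ThermoParams(K_b=draw["K_b"], omega_bp=draw["omega_bp"], omega_b=1.0)
        params = TFDrivenParams(m=draw["m"], c_b=draw["c_b"], c_z=draw["c_z"], equilibrium=eq)
        return TFDrivenModel(params)
    raise ValueError(f"unknown model class {model_class!r}")


def _apply_plateau_constraint(
    profile: PositionProfile, target_rate: float, detection_floor: float
) -> PositionProfile | None:
    """Rescale the draw so its maximum initial rate equals the reference
    plateau, then mask positions whose rescaled trace peak falls below the
    detection floor (features cannot be measured on undetectable signals).

    Onset times are invariant under the rescaling; rates and peaks scale
    linearly, so the constraint is applied without re-running the model.
    """
    finite = profile.init_rate[np.isfinite(profile.init_rate)]
    if finite.size == 0 or finite.max() <= 0:
        return None
    scale = target_rate / finite.max()
    detectable = profile.peak_signal * scale >= detection_floor
    mask = profile.active_mask & detectable
    if not mask.any():
        return None
    nan = lambda a: np.where(mask, a, np.nan)  # noqa: E731
    return PositionProfile(
        positions=profile.positions,
        init_rate=nan(profile.init_rate * scale),
        t_on=nan(profile.t_on),
        fraction_active=profile.fraction_active,
        active_mask=mask,
        peak_signal=profile.peak_signal * scale,
    )


def sample_parameter_space(
    model_class: str,
    input_field: InputField,
    n_samples: int,
    seed: int = 0,
    ranges: dict | None = None,
    elong: ElongationParams | None = None,
    plateau_rate: float = 15.0,
    detection_floor: float = 1.0,
    raster_bin: float = RASTER_BIN,
) -> RegionSample:
    """Sample a model class and map each draw to its (offset, delay) signature.

    Draws are log-uniform within ``ranges``.  For each draw the position
    profile is computed through the full trace/feature chain over the positions
    of ``input_field``; the overall rate R is then normalized to the plateau
    constraint and the onset metrics evaluated.  Draws whose offset bin is
    inactive, or that fail to produce two active bins in the delay window, are
    recorded as invalid and excluded from the raster.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    ranges = ranges if ranges is not None else default_ranges(model_class)
    elong = elong if elong is not None else ElongationParams()
    rng = np.random.default_rng(seed)
    feature_config = FeatureConfig(min_signal=0.0)  # activity anchored by the plateau rescale
    rows = []
    for _ in range(n_samples):
        draw = {
            name: _draw(rng, lo, hi, kind)
            for name, (lo, hi, kind) in ranges.items()
            if name not in ("log_weight", "rate")
        }
        model = _model_from_draw(model_class, draw, rng, ranges)
        row = dict(draw)
        row.update({"offset": np.nan, "avg_delay": np.nan, "all_active": False, "valid": False})
        try:
            profile = predict_position_profile(model, input_field, elong, feature_config)
            constrained = _apply_plateau_constraint(profile, plateau_rate, detection_floor)
            if constrained is not None:
                row["offset"] = ton_offset(constrained)
                row["avg_delay"] = avg_ton_delay(constrained)
                row["all_active"] = bool(constrained.active_mask.all())
                row["valid"] = True
        except (ValueError, RuntimeError):
            pass  # recorded invalid, excluded, counted
        rows.append(row)
    samples = pd.DataFrame(rows)
    valid = samples[samples["valid"]]
    if len(valid):
        o = valid["offset"].to_numpy()
        d = valid["avg_delay"].to_numpy()
        o_edges = _edges(o, raster_bin)
        d_edges = _edges(d, raster_bin)
        raster, _, _ = np.histogram2d(o, d, bins=[o_edges, d_edges])
        raster = raster > 0
    else:
        o_edges = np.array([0.0, raster_bin])
        d_edges = np.array([0.0, raster_bin])
        raster = np.zeros((1, 1), dtype=bool)
    return RegionSample(
        model_class=model_class,
        samples=samples,
        raster=raster,
        offset_edges=o_edges,
        delay_edges=d_edges,
        seed=seed,
        n_requested=n_samples,
    )


def _edges(values: np.ndarray, bin_size: float) -> np.ndarray:
    lo = np.floor(values.min() / bin_size) * bin_size
    hi = np.ceil(values.max() / bin_size) * bin_size + bin_size / 2
    return np.arange(lo, hi + bin_size, bin_size)


def region_contains(region: RegionSample, point: SignaturePoint) -> str:
    """'inside' if the point's raster cell is occupied, 'boundary' if any cell
    intersecting its uncertainty ellipse is, else 'outside'."""
    i = np.searchsorted(region.offset_edges, point.offset, side="right") - 1
    j = np.searchsorted(region.delay_edges, point.avg_delay, side="right") - 1
    if 0 <= i < region.raster.shape[0] and 0 <= j < region.raster.shape[1]:
        if region.raster[i, j]:
            return "inside"
    if point.sem_offset > 0 or point.sem_delay > 0:
        oc = (region.offset_edges[:-1] + region.offset_edges[1:]) / 2
        dc = (region.delay_edges[:-1] + region.delay_edges[1:]) / 2
        oo, dd = np.meshgrid(oc, dc, indexing="ij")
        so = max(point.sem_offset, 1e-12)
        sd = max(point.sem_delay, 1e-12)
        ellipse = ((oo - point.offset) / so) ** 2 + ((dd - point.avg_delay) / sd) ** 2 <= 1.0
        if np.any(region.raster & ellipse):
            return "boundary"
    return "outside"


def compare_regions(
    regions: Sequence[RegionSample],
    points: Sequence[SignaturePoint] = (),
) -> pd.DataFrame:
    """Tabulate raster areas and point containment across model classes.

    Note that one class's raster need not contain another's even when the
    model families nest mathematically, because the sampling constraints
    differ between classes.
    """
    rows = []
    for region in regions:
        row = {
            "model_class": region.model_class,
            "n_requested": region.n_requested,
            "n_valid": region.n_valid,
            "area_min2": region.area,
            "max_avg_delay": float(region.samples["avg_delay"].max())
            if region.n_valid
            else np.nan,
        }
        for k, point in enumerate(points):
            row[f"point{k}_containment"] = region_contains(region, point)
        rows.append(row)
    return pd.DataFrame(rows)
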