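"""CSV schemas, configuration files and run manifests.

All interchange happens through plain CSV with required headers (validated on
read) -- positions in %EL, times in minutes since anaphase, fluorescence in
RNAP-number units -- plus YAML for model/run configuration and JSON manifests
recording seeds and parameters, sufficient to reproduce deterministic stages
bit for bit.

Schemas
-------
embryo traces : embryo_id, genotype, nucleus_id, position_pct, time_min,
                fluorescence_rnap[, active]
input field   : position_pct, time_min, bicoid, zelda
profile       : position_pct, init_rate, init_rate_sem, t_on, t_on_sem,
                fraction_active[, active]
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hbaccess.features import PositionProfile
from hbaccess.inputs import InputField
from hbaccess.synthetic import SyntheticEmbryo
from hbaccess.tfdriven import TFDrivenParams
from hbaccess.thermo import GeneralizedThermoParams, ThermoParams

logger = logging.getLogger(__name__)

__all__ = [
    "write_embryos",
    "read_traces",
    "write_input_field",
    "read_input_field",
    "write_profile",
    "read_profile",
    "load_params",
    "dump_params",
    "write_manifest",
]

TRACE_COLUMNS = ["embryo_id", "genotype", "nucleus_id", "position_pct", "time_min", "fluorescence_rnap"]


class FormatError(ValueError):
    """A file does not conform to the expected CSV schema."""


def _check_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{what} table is missing required columns: {missing}")


def write_embryos(embryos, path: str | Path) -> None:
    """Write one or more embryos to a single long-format CSV."""
    frames = [e.to_frame() for e in (embryos if isinstance(embryos, (list, tuple)) else [embryos])]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path, input_field: InputField | None = None) -> list[SyntheticEmbryo]:
    """Read embryos from a trace CSV (header validated).

    If ``input_field`` is omitted, a minimal field with zero concentrations is
    attached (enough for feature extraction, not for model prediction).
    """
    frame = pd.read_csv(path)
    _check_columns(frame, TRACE_COLUMNS, "trace")
    embryos = []
    for embryo_id, sub in frame.groupby("embryo_id", sort=False):
        genotype = sub["genotype"].iloc[0]
        times = np.sort(sub["time_min"].unique())
        if input_field is None:
            positions = np.sort(sub["position_pct"].unique())
            field = InputField(
                positions=positions,
                time_grid=times,
                bicoid=np.zeros((positions.size, times.size)),
                zelda=np.zeros(times.size),
            )
        else:
            field = input_field.zelda_nulled() if genotype == "zelda-null" else input_field
        traces = sub.drop(columns=["embryo_id", "genotype"]).reset_index(drop=True)
        if "active" not in traces.columns:
            logger.warning("trace table lacks an 'active' column; inferring from peaks")
            peak = traces.groupby("nucleus_id")["fluorescence_rnap"].transform("max")
            traces["active"] = (peak > 0).astype(int)
        embryos.append(
            SyntheticEmbryo(
                input_field=field,
                traces=traces,
                genotype=genotype,
                embryo_id=str(embryo_id),
            )
        )
    return embryos


def write_input_field(field: InputField, path: str | Path) -> None:
    field.to_frame().to_csv(path, index=False)


def read_input_field(path: str | Path) -> InputField:
    frame = pd.read_csv(path)
    _check_columns(frame, ["position_pct", "time_min", "bicoid", "zelda"], "input")
    return InputField.from_frame(frame)


def write_profile(profile: PositionProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_profile(path: str | Path) -> PositionProfile:
    frame = pd.read_csv(path)
    _check_columns(frame, ["position_pct", "init_rate", "t_on", "fraction_active"], "profile")
    for sem_col in ("init_rate_sem", "t_on_sem"):
        if sem_col not in frame.columns:
            logger.warning("profile lacks %s; unit weights will be used in fits", sem_col)
    return PositionProfile.from_frame(frame)


_PARAM_CLASSES = {
    "thermo_mwc": ThermoParams,
    "tf_driven": TFDrivenParams,
    "generalized_thermo": GeneralizedThermoParams,
}


def dump_params(params, path: str | Path) -> None:
    """Serialize a parameter bundle to YAML (units noted in comments)."""
    if isinstance(params, ThermoParams):
        kind = "thermo_mwc"
    elif isinstance(params, TFDrivenParams):
        kind = "tf_driven"
    elif isinstance(params, GeneralizedThermoParams):
        kind = "generalized_thermo"
    else:
        raise ValueError(f"cannot serialize {type(params).__name__}")
    doc = {"model_class": kind, "params": params.to_dict()}
    header = (
        "# dissociation constants in input concentration units; energies in k_BT;\n"
        "# rates in 1/min (c_b, c_z in 1/(min*concentration)); times in minutes\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path: str | Path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kind = doc.get("model_class")
    if kind not in _PARAM_CLASSES:
        raise FormatError(f"unknown model_class {kind!r} in {path}")
    cls = _PARAM_CLASSES[kind]
    return cls.from_dict(doc["params"])


def write_manifest(path: str | Path, **entries) -> None:
    """Record seeds, parameters and the package version for reproducibility."""
    from hbaccess import __version__

    manifest = {"hbaccess_version": __version__, **entries}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return str(o)

    Path(path).write_text(json.dumps(manifest, indent=2, default=default) + "\n")
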