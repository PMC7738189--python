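"""End-to-end pipeline driven by a single configuration mapping.

``run_pipeline`` executes simulate -> predict -> features -> fit -> explore
stages according to the config, writing CSV artifacts plus a JSON manifest
(config, seeds, package version) to the output directory.  Every random
operation consumes an explicit seed from the config.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from hbaccess import io
from hbaccess.explore import sample_parameter_space, compare_regions
from hbaccess.features import profile_from_embryo, signature_point
from hbaccess.fitting import ProfileFit
from hbaccess.inputs import default_input_field
from hbaccess.synthetic import average_embryos, gen_embryo
from hbaccess.tfdriven import TFDrivenModel, TFDrivenParams
from hbaccess.thermo import ThermoMWCModel, ThermoParams
from hbaccess.trace import predict_position_profile

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_CONFIG", "build_model"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "model_class": "tf_driven",
    "genotypes": ["wild-type", "zelda-null"],
    "n_embryos": 3,
    "n_nuclei_per_bin": 8,
    "noise_sd": 1.0,
    "activity_min_fraction": 0.30,
    "fit": {"enabled": True, "model_class": "tf_driven", "fixed": {"m": 3}, "n_starts": 4},
    "explore": {"enabled": False, "model_classes": ["thermo_mwc", "tf_driven"], "n_samples": 200},
}


def build_model(model_class: str, params: dict | None = None):
    """Construct a forward model from a class name and a parameter mapping."""
    if model_class == "thermo_mwc":
        return ThermoMWCModel(ThermoParams(**(params or {})))
    if model_class == "tf_driven":
        if params and "equilibrium" in params:
            return TFDrivenModel(TFDrivenParams.from_dict(params))
        return TFDrivenModel(TFDrivenParams(**(params or {})))
    raise ValueError(f"unsupported model class {model_class!r}")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages; returns a summary dict (also written as manifest)."""
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    field = default_input_field()
    io.write_input_field(field, outdir / "inputs.csv")
    model = build_model(cfg["model_class"], cfg.get("model_params"))

    summary: dict = {"stages": []}
    datasets = []
    for genotype in cfg["genotypes"]:
        tag = "wt" if genotype == "wild-type" else "znull"
        embryos = [
            gen_embryo(
                model,
                field,
                n_nuclei_per_bin=int(cfg["n_nuclei_per_bin"]),
                noise_sd=float(cfg["noise_sd"]),
                seed=seed * 1000 + 17 * i + (0 if genotype == "wild-type" else 500),
                genotype=genotype,
            )
            for i in range(int(cfg["n_embryos"]))
        ]
        io.write_embryos(embryos, outdir / f"embryos_{tag}.csv")
        averaged = average_embryos(embryos)
        profile = profile_from_embryo(
            averaged, embryos, min_fraction=float(cfg["activity_min_fraction"])
        )
        io.write_profile(profile, outdir / f"profile_{tag}.csv")
        datasets.append((profile, field, genotype))
        point = signature_point(profile)
        summary[f"{tag}_offset_min"] = point.offset
        summary[f"{tag}_avg_delay_min"] = point.avg_delay
    summary["stages"] += ["simulate", "features"]

    pred = predict_position_profile(model, field)
    io.write_profile(pred, outdir / "predicted_profile.csv")
    summary["stages"].append("predict")

    fit_cfg = cfg.get("fit", {})
    if fit_cfg.get("enabled"):
        fit = ProfileFit(fit_cfg.get("model_class", "tf_driven"), datasets, fixed=fit_cfg.get("fixed"))
        res = fit.fit(n_starts=int(fit_cfg.get("n_starts", 4)), seed=seed)
        (outdir / "fit_summary.txt").write_text(res.summary() + "\n")
        summary["fit_objective"] = res.objective
        summary["fit_params"] = res.params
        summary["stages"].append("fit")

    explore_cfg = cfg.get("explore", {})
    if explore_cfg.get("enabled"):
        regions = [
            sample_parameter_space(
                mc, field, int(explore_cfg.get("n_samples", 200)), seed=seed
            )
            for mc in explore_cfg.get("model_classes", [])
        ]
        report = compare_regions(regions)
        report.to_csv(outdir / "regions.csv", index=False)
        summary["region_areas"] = dict(zip(report["model_class"], report["area_min2"]))
        summary["stages"].append("explore")

    io.write_manifest(outdir / "manifest.json", config=cfg, summary=summary)
    return summary
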