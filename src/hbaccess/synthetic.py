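"""Synthetic embryos with the statistical structure of the live-imaging data.

A synthetic embryo carries per-nucleus MS2 traces on a common time grid,
generated as a promoter model's mean trace at the nucleus position plus
additive Gaussian measurement noise (truncated at zero), in RNAP-number units.
Nuclei sit in 2.5 %EL position bins; a zelda-null embryo zeroes the Zelda
input channel before prediction.  Multiple embryos synchronized at anaphase
are combined into an averaged embryo: nuclei are averaged within each position
bin, then across embryos, with the standard error of the mean per time point.

This emulates the structure of the measurements -- synchronized nuclear
cycles, binned positions, trace noise -- not pixel-level imaging, nuclear
movement or division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from hbaccess.inputs import InputField
from hbaccess.trace import ElongationParams, rnap_number

logger = logging.getLogger(__name__)

__all__ = ["SyntheticEmbryo", "gen_embryo", "average_embryos"]

Genotype = Literal["wild-type", "zelda-null"]


@dataclass
class SyntheticEmbryo:
    """One synthetic embryo: input field plus per-nucleus MS2 traces.

    ``traces`` is a long-format table with columns nucleus_id, position_pct,
    time_min, fluorescence_rnap, active (1 where the nucleus ever exceeds the
    generator's detection level).
    """

    input_field: InputField
    traces: pd.DataFrame
    genotype: Genotype = "wild-type"
    seed: int = 0
    noise_sd: float = 0.0
    embryo_id: str = "embryo0"

    def __post_init__(self) -> None:
        if self.genotype not in ("wild-type", "zelda-null"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.genotype == "zelda-null" and np.any(self.input_field.zelda != 0):
            raise ValueError("zelda-null embryos must have zelda identically zero")
        trace_times = np.unique(self.traces["time_min"].to_numpy())
        if not np.all(np.isin(trace_times, self.input_field.time_grid)):
            raise ValueError("trace time grids must be subsets of the embryo time grid")

    def to_frame(self) -> pd.DataFrame:
        """Long table with embryo_id and genotype columns (the CSV schema)."""
        out = self.traces.copy()
        out.insert(0, "embryo_id", self.embryo_id)
        out.insert(1, "genotype", self.genotype)
        return out


def gen_embryo(
    model,
    input_field: InputField,
    n_nuclei_per_bin: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    genotype: Genotype = "wild-type",
    elong: ElongationParams | None = None,
    embryo_id: str | None = None,
) -> SyntheticEmbryo:
    """Generate one embryo from a promoter model.

    Every nucleus trace is the model's mean RNAP-number trace at its position
    bin plus independent Gaussian noise of the stated sd, truncated at zero.
    A ``zelda-null`` genotype zeroes the Zelda channel before prediction.
    Reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_nuclei_per_bin < 1:
        raise ValueError("need at least one nucleus per bin")
    if genotype == "zelda-null":
        input_field = input_field.zelda_nulled()
    elong = elong if elong is not None else ElongationParams()
    rng = np.random.default_rng(seed)
    rates = model.loading_rates(input_field)
    t = input_field.time_grid
    records = []
    nucleus = 0
    for k, pos in enumerate(input_field.positions):
        mean_trace = rnap_number(rates[k], t, elong, position=pos).rnap_number
        for _ in range(n_nuclei_per_bin):
            noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0
            fluo = np.maximum(mean_trace + noise, 0.0)
            records.append(
                pd.DataFrame(
                    {
                        "nucleus_id": nucleus,
                        "position_pct": pos,
                        "time_min": t,
                        "fluorescence_rnap": fluo,
                    }
                )
            )
            nucleus += 1
    traces = pd.concat(records, ignore_index=True)
    detection = 3.0 * noise_sd if noise_sd > 0 else 0.0
    peak = traces.groupby("nucleus_id")["fluorescence_rnap"].transform("max")
    traces["active"] = (peak > detection).astype(int)
    return SyntheticEmbryo(
        input_field=input_field,
        traces=traces,
        genotype=genotype,
        seed=seed,
        noise_sd=noise_sd,
        embryo_id=embryo_id if embryo_id is not None else f"embryo{seed}",
    )


def average_embryos(embryos: Iterable[SyntheticEmbryo], bin_width: float = 2.5) -> pd.DataFrame:
    """Averaged embryo: mean trace and SEM per position bin and time point.

    Traces are aligned at anaphase (t = 0 by construction), averaged over
    nuclei within each ``bin_width`` %EL bin of each embryo, then averaged
    across embryos; the SEM per time point is taken over all contributing
    nuclei.  Returns a table (position_pct, time_min, mean_rnap, sem, n).
    """
    embryos = list(embryos)
    if not embryos:
        raise ValueError("need at least one embryo")
    genotypes = {e.genotype for e in embryos}
    if len(genotypes) > 1:
        raise ValueError("cannot average embryos of different genotypes")
    frames = []
    for e in embryos:
        f = e.traces[["nucleus_id", "position_pct", "time_min", "fluorescence_rnap"]].copy()
        f["embryo_id"] = e.embryo_id
        frames.append(f)
    data = pd.concat(frames, ignore_index=True)
    # snap positions to bin centres
    lo = data["position_pct"].min()
    data["bin"] = lo + bin_width * np.round((data["position_pct"] - lo) / bin_width)
    grouped = data.groupby(["bin", "time_min"])["fluorescence_rnap"]
    out = grouped.agg(mean_rnap="mean", sd="std", n="count").reset_index()
    empty = out["n"] == 0
    if empty.any():
        logger.warning("omitting %d empty position bins", int(empty.sum()))
        out = out[~empty]
    out["sem"] = out["sd"].fillna(0.0) / np.sqrt(out["n"])
    out = out.rename(columns={"bin": "position_pct"})
    return out[["position_pct", "time_min", "mean_rnap", "sem", "n"]].sort_values(
        ["position_pct", "time_min"], ignore_index=True
    )
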