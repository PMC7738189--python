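"""Dynamical features of MS2 traces and onset-time metrics.

Two features summarize each trace of actively transcribing RNAP number: the
initial rate of RNAP loading (slope of the initial rise) and the
transcriptional onset time t_on (x-intercept of a least-squares line fitted to
that rise).  Position profiles of these features are condensed into the two
scalar signatures used for model discrimination:

* the t_on *offset*: the onset time at x = 20 %EL, the most anterior position
  analysed;
* the *average t_on delay*: the area under t_on(x) - t_on(20%) from 20 to
  37.5 %EL (the window in which zelda-null embryos still show transcription in
  at least 30% of nuclei), divided by the distance.

An activity filter masks positions where fewer than 30% of nuclei ever show a
spot, mirroring how the measurements were selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "TraceFeatures",
    "PositionProfile",
    "SignaturePoint",
    "extract_features",
    "ton_offset",
    "avg_ton_delay",
    "signature_point",
    "fraction_active_profile",
    "apply_activity_filter",
    "profile_from_embryo",
]

OFFSET_POSITION = 20.0  # %EL, anterior anchor of the onset metrics
DELAY_WINDOW = (20.0, 37.5)  # %EL, integration window of the average delay


@dataclass
class FeatureConfig:
    """Rise-window rule for the initial-rise line fit.

    The fitted window starts at the first time the trace exceeds
    ``rise_fraction`` of its cycle maximum and ends at the earliest of: the
    first time it reaches ``rise_end_fraction`` of the maximum, the trace
    maximum itself, and window start + ``max_window`` minutes.  Ending the
    window well below the maximum keeps the fit on the quasi-linear part of
    the rise instead of the bend into the plateau, which would otherwise bias
    the x-intercept early.  Traces whose maximum never reaches ``min_signal``
    (RNAP units) are inactive.
    """

    rise_fraction: float = 0.1
    rise_end_fraction: float = 0.6
    max_window: float = 2.0  # minutes
    min_signal: float = 1.0  # RNAP units
    t_on_slack: float = 1.0  # minutes; intercepts earlier than -slack are unphysical


@dataclass
class TraceFeatures:
    init_rate: float  # RNAP / min
    t_on: float  # minutes
    init_rate_sem: float = np.nan
    t_on_sem: float = np.nan


def extract_features(
    time_grid: np.ndarray,
    trace: np.ndarray,
    config: FeatureConfig | None = None,
    trace_sem: np.ndarray | None = None,
) -> TraceFeatures | None:
    """Initial loading rate and onset time from a single trace.

    Returns ``None`` for inactive traces (never exceeding the rise threshold,
    or without a positive-slope rise window).  Feature uncertainties come from
    the line-fit covariance.
    """
    config = config if config is not None else FeatureConfig()
    time_grid = np.asarray(time_grid, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.any(trace < -1e-9):
        raise ValueError("trace must be non-negative")
    peak = float(trace.max(initial=0.0))
    if peak < config.min_signal:
        return None
    threshold = config.rise_fraction * peak
    above = np.nonzero(trace > threshold)[0]
    if above.size == 0:
        return None
    start = above[0]
    i_peak = int(np.argmax(trace))
    high = np.nonzero(trace >= config.rise_end_fraction * peak)[0]
    i_end = int(high[0]) if high.size else i_peak
    end_time = min(time_grid[min(i_end, i_peak)], time_grid[start] + config.max_window)
    window = (np.arange(time_grid.size) >= start) & (time_grid <= end_time + 1e-12)
    if window.sum() < 2:
        return None
    t_w = time_grid[window]
    y_w = trace[window]
    if trace_sem is not None:
        w = 1.0 / np.clip(np.asarray(trace_sem, dtype=float)[window], 1e-12, None)
    else:
        w = None
    try:
        (slope, intercept), cov = np.polyfit(t_w, y_w, 1, w=w, cov="unscaled" if w is not None else True)
    except (np.linalg.LinAlgError, ValueError):
        # window too short for a covariance estimate: fit without one
        slope, intercept = np.polyfit(t_w, y_w, 1, w=w)
        cov = np.zeros((2, 2))
    if slope <= 0:
        return None
    t_on = -intercept / slope
    # onset cannot precede anaphase (small slack for fit noise) nor fall
    # beyond the observed cycle: such fits come from undetectable late creeps
    if t_on < time_grid[0] - config.t_on_slack or t_on > time_grid[-1]:
        return None
    # error propagation of the x-intercept through the fit covariance
    g = np.array([intercept / slope**2, -1.0 / slope])
    t_on_var = float(g @ cov @ g)
    return TraceFeatures(
        init_rate=float(slope),
        t_on=float(t_on),
        init_rate_sem=float(np.sqrt(max(cov[0, 0], 0.0))),
        t_on_sem=float(np.sqrt(max(t_on_var, 0.0))),
    )


@dataclass
class PositionProfile:
    """Initial loading rate, onset time and fraction active along the AP axis."""

    positions: np.ndarray
    init_rate: np.ndarray
    t_on: np.ndarray
    fraction_active: np.ndarray
    init_rate_sem: np.ndarray | None = None
    t_on_sem: np.ndarray | None = None
    active_mask: np.ndarray | None = None
    peak_signal: np.ndarray | None = None  # trace maximum per position, RNAP units

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.init_rate = np.asarray(self.init_rate, dtype=float)
        self.t_on = np.asarray(self.t_on, dtype=float)
        self.fraction_active = np.asarray(self.fraction_active, dtype=float)
        n = self.positions.size
        for name in ("init_rate", "t_on", "fraction_active"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must match positions")
        if np.any((self.fraction_active < -1e-9) | (self.fraction_active > 1 + 1e-9)):
            raise ValueError("fraction_active must lie in [0, 1]")
        if self.active_mask is None:
            self.active_mask = np.isfinite(self.t_on)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.init_rate_sem is not None:
            self.init_rate_sem = np.asarray(self.init_rate_sem, dtype=float)
        if self.t_on_sem is not None:
            self.t_on_sem = np.asarray(self.t_on_sem, dtype=float)
        if self.peak_signal is not None:
            self.peak_signal = np.asarray(self.peak_signal, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "position_pct": self.positions,
            "init_rate": self.init_rate,
            "init_rate_sem": self.init_rate_sem
            if self.init_rate_sem is not None
            else np.full_like(self.positions, np.nan),
            "t_on": self.t_on,
            "t_on_sem": self.t_on_sem
            if self.t_on_sem is not None
            else np.full_like(self.positions, np.nan),
            "fraction_active": self.fraction_active,
            "active": self.active_mask.astype(int),
        }
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PositionProfile":
        required = {"position_pct", "init_rate", "t_on", "fraction_active"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"profile table missing columns: {sorted(missing)}")
        return cls(
            positions=frame["position_pct"].to_numpy(),
            init_rate=frame["init_rate"].to_numpy(),
            t_on=frame["t_on"].to_numpy(),
            fraction_active=frame["fraction_active"].to_numpy(),
            init_rate_sem=frame["init_rate_sem"].to_numpy() if "init_rate_sem" in frame else None,
            t_on_sem=frame["t_on_sem"].to_numpy() if "t_on_sem" in frame else None,
            active_mask=frame["active"].to_numpy(dtype=bool) if "active" in frame else None,
        )


@dataclass
class SignaturePoint:
    """A (t_on offset, average t_on delay) point with its uncertainty ellipse."""

    offset: float  # minutes
    avg_delay: float  # minutes
    sem_offset: float = 0.0
    sem_delay: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.offset) and np.isfinite(self.avg_delay)):
            raise ValueError("signature point must be finite")


def _nearest_active(profile: PositionProfile, position: float) -> int:
    active = np.nonzero(profile.active_mask)[0]
    if active.size == 0:
        raise ValueError("profile has no active positions")
    return int(active[np.argmin(np.abs(profile.positions[active] - position))])


def ton_offset(profile: PositionProfile) -> float:
    """Onset time at x = 20 %EL (nearest position bin)."""
    idx = int(np.argmin(np.abs(profile.positions - OFFSET_POSITION)))
    if not profile.active_mask[idx]:
        raise ValueError("onset offset undefined: 20 %EL bin is inactive")
    return float(profile.t_on[idx])


def avg_ton_delay(profile: PositionProfile) -> float:
    """Average onset delay: normalized integral of t_on - t_on(20%) over
    20-37.5 %EL (trapezoidal), or over the active sub-interval when activity
    ends before 37.5 %EL."""
    offset = ton_offset(profile)
    lo, hi = DELAY_WINDOW
    in_window = (profile.positions >= lo - 1e-9) & (profile.positions <= hi + 1e-9)
    usable = in_window & profile.active_mask
    # restrict to the contiguous active stretch starting at the offset bin
    idx = np.nonzero(usable)[0]
    if idx.size < 2:
        raise ValueError("average delay needs at least two active bins in the window")
    contiguous = [idx[0]]
    for k in idx[1:]:
        if k == contiguous[-1] + 1:
            contiguous.append(k)
        else:
            break
    idx = np.array(contiguous)
    x = profile.positions[idx]
    y = profile.t_on[idx] - offset
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("degenerate integration window")
    return float(np.trapezoid(y, x) / span)


def signature_point(profile: PositionProfile) -> SignaturePoint:
    """Offset/delay signature of a profile with propagated uncertainties."""
    offset = ton_offset(profile)
    delay = avg_ton_delay(profile)
    sem_offset = 0.0
    sem_delay = 0.0
    if profile.t_on_sem is not None:
        idx0 = int(np.argmin(np.abs(profile.positions - OFFSET_POSITION)))
        sem_offset = float(np.nan_to_num(profile.t_on_sem[idx0]))
        lo, hi = DELAY_WINDOW
        usable = (
            (profile.positions >= lo - 1e-9)
            & (profile.positions <= hi + 1e-9)
            & profile.active_mask
        )
        idx = np.nonzero(usable)[0]
        if idx.size >= 2:
            x = profile.positions[idx]
            span = x[-1] - x[0]
            w = np.gradient(x) / span  # trapezoid weights of the normalized integral
            var = np.nansum((w * np.nan_to_num(profile.t_on_sem[idx])) ** 2)
            sem_delay = float(np.sqrt(var + (sem_offset) ** 2))
    return SignaturePoint(offset=offset, avg_delay=delay, sem_offset=sem_offset, sem_delay=sem_delay)


def fraction_active_profile(embryo, detection_threshold: float | None = None) -> pd.DataFrame:
    """Per-position fraction of nuclei whose trace ever exceeds the detection
    threshold (default: 3x the embryo's noise sd, or 1 RNAP if noiseless)."""
    if detection_threshold is None:
        detection_threshold = 3.0 * embryo.noise_sd if embryo.noise_sd > 0 else 1.0
    rows = []
    frame = embryo.traces
    for pos, group in frame.groupby("position_pct"):
        per_nucleus = group.groupby("nucleus_id")["fluorescence_rnap"].max()
        rows.append(
            {
                "position_pct": float(pos),
                "fraction_active": float((per_nucleus > detection_threshold).mean()),
                "n_nuclei": int(per_nucleus.size),
            }
        )
    return pd.DataFrame(rows).sort_values("position_pct", ignore_index=True)


def apply_activity_filter(profile: PositionProfile, min_fraction: float = 0.30) -> PositionProfile:
    """Mask positions where fewer than ``min_fraction`` of nuclei ever transcribe."""
    keep = profile.fraction_active >= min_fraction
    mask = profile.active_mask & keep
    nan = lambda a: np.where(mask, a, np.nan)  # noqa: E731
    return PositionProfile(
        positions=profile.positions.copy(),
        init_rate=nan(profile.init_rate),
        t_on=nan(profile.t_on),
        fraction_active=profile.fraction_active.copy(),
        init_rate_sem=None if profile.init_rate_sem is None else nan(profile.init_rate_sem),
        t_on_sem=None if profile.t_on_sem is None else nan(profile.t_on_sem),
        active_mask=mask,
    )


def profile_from_embryo(
    averaged,
    raw_embryos=None,
    config: FeatureConfig | None = None,
    detection_threshold: float | None = None,
    min_fraction: float = 0.30,
) -> PositionProfile:
    """Extract a PositionProfile from an averaged embryo.

    ``averaged`` is the output of :func:`hbaccess.synthetic.average_embryos`
    (mean trace with SEM per position bin).  ``raw_embryos`` (the individual
    embryos) supply the fraction-active profile; without them every position
    with an extractable onset counts as fully active.
    """
    config = config if config is not None else FeatureConfig()
    positions = np.array(sorted(averaged["position_pct"].unique()))
    n = positions.size
    init_rate = np.full(n, np.nan)
    t_on = np.full(n, np.nan)
    init_rate_sem = np.full(n, np.nan)
    t_on_sem = np.full(n, np.nan)
    active = np.zeros(n, dtype=bool)
    for k, pos in enumerate(positions):
        sub = averaged[averaged["position_pct"] == pos].sort_values("time_min")
        sem = sub["sem"].to_numpy()
        feats = extract_features(
            sub["time_min"].to_numpy(),
            sub["mean_rnap"].to_numpy(),
            config=config,
            trace_sem=sem if np.all(np.isfinite(sem)) and np.any(sem > 0) else None,
        )
        if feats is not None:
            init_rate[k], t_on[k] = feats.init_rate, feats.t_on
            init_rate_sem[k], t_on_sem[k] = feats.init_rate_sem, feats.t_on_sem
            active[k] = True
    if raw_embryos:
        fracs = []
        for emb in raw_embryos:
            f = fraction_active_profile(emb, detection_threshold)
            fracs.append(f.set_index("position_pct")["fraction_active"])
        frac = pd.concat(fracs, axis=1).mean(axis=1).reindex(positions).to_numpy()
    else:
        frac = active.astype(float)
    profile = PositionProfile(
        positions=positions,
        init_rate=init_rate,
        t_on=t_on,
        fraction_active=np.nan_to_num(frac),
        init_rate_sem=init_rate_sem,
        t_on_sem=t_on_sem,
        active_mask=active,
    )
    return apply_activity_filter(profile, min_fraction=min_fraction)
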