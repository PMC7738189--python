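"""Synthetic nuclear-concentration inputs.

Bicoid forms an exponential gradient along the anterior-posterior (AP) axis and
is imported into nuclei after anaphase on a time scale of a couple of minutes;
Zelda is spatially uniform with comparable import dynamics.  Positions are in
percent embryo length (%EL, 0 anterior) and times in minutes since anaphase of
the previous division (all analyses live inside nuclear cycle 13).

Concentrations are in arbitrary fluorescence units; only ratios to the models'
dissociation constants matter, so the anterior Bicoid amplitude defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["InputField", "gen_bicoid", "gen_zelda", "default_input_field"]

#: default AP window analysed throughout: 2.5 %EL bins from 20 to 60 %EL
DEFAULT_POSITIONS = np.arange(20.0, 60.0 + 1e-9, 2.5)
#: default time grid: 0.5 min steps over a 17-min nuclear cycle
DEFAULT_TIME_GRID = np.arange(0.0, 17.0 + 1e-9, 0.5)


def _import_curve(time_grid: np.ndarray, import_timescale: float) -> np.ndarray:
    """Saturating nuclear-import curve g(t) = 1 - exp(-t/tau); g(0)=0, g(inf)=1."""
    return -np.expm1(-np.asarray(time_grid, dtype=float) / import_timescale)


def gen_bicoid(
    amplitude: float,
    length_scale: float,
    import_timescale: float,
    positions: np.ndarray,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Bicoid nuclear concentration on a (position x time) grid.

    ``value(x, t) = amplitude * exp(-x / length_scale) * g(t)`` with ``g`` the
    saturating import curve.  ``length_scale`` is the gradient decay length in
    %EL, ``import_timescale`` the nuclear-import time constant in minutes.
    """
    if amplitude <= 0 or length_scale <= 0 or import_timescale <= 0:
        raise ValueError("amplitude, length_scale and import_timescale must be positive")
    positions = np.asarray(positions, dtype=float)
    gradient = amplitude * np.exp(-positions / length_scale)
    return np.outer(gradient, _import_curve(time_grid, import_timescale))


def gen_zelda(amplitude: float, import_timescale: float, time_grid: np.ndarray) -> np.ndarray:
    """Zelda nuclear concentration vs time (spatially uniform along the embryo)."""
    if amplitude <= 0 or import_timescale <= 0:
        raise ValueError("amplitude and import_timescale must be positive")
    return amplitude * _import_curve(time_grid, import_timescale)


@dataclass
class InputField:
    """Bicoid and Zelda concentration dynamics over an AP-position x time grid.

    Attributes
    ----------
    positions : array, %EL
    time_grid : array, minutes since anaphase (strictly increasing, starts at 0)
    bicoid : array (n_positions, n_times)
    zelda : array (n_times,), identical at every position
    """

    positions: np.ndarray
    time_grid: np.ndarray
    bicoid: np.ndarray
    zelda: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.bicoid = np.asarray(self.bicoid, dtype=float)
        self.zelda = np.asarray(self.zelda, dtype=float)
        if self.time_grid.ndim != 1 or self.time_grid.size < 2:
            raise ValueError("time_grid must be a 1-D array with at least two samples")
        if self.time_grid[0] != 0.0 or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must start at 0 (anaphase) and strictly increase")
        if self.bicoid.shape != (self.positions.size, self.time_grid.size):
            raise ValueError("bicoid must have shape (n_positions, n_times)")
        if self.zelda.shape != (self.time_grid.size,):
            raise ValueError("zelda must have shape (n_times,)")
        if np.any(self.bicoid < 0) or np.any(self.zelda < 0):
            raise ValueError("concentrations must be non-negative")

    def bicoid_at(self, position: float) -> np.ndarray:
        """Bicoid time course at the grid position nearest to ``position``."""
        return self.bicoid[int(np.argmin(np.abs(self.positions - position)))]

    def zelda_nulled(self) -> "InputField":
        """A copy with the Zelda channel identically zero (zelda-null genotype)."""
        return InputField(
            positions=self.positions.copy(),
            time_grid=self.time_grid.copy(),
            bicoid=self.bicoid.copy(),
            zelda=np.zeros_like(self.zelda),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns position_pct, time_min, bicoid, zelda."""
        pos, t = np.meshgrid(self.positions, self.time_grid, indexing="ij")
        return pd.DataFrame(
            {
                "position_pct": pos.ravel(),
                "time_min": t.ravel(),
                "bicoid": self.bicoid.ravel(),
                "zelda": np.broadcast_to(self.zelda, self.bicoid.shape).ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InputField":
        required = {"position_pct", "time_min", "bicoid", "zelda"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"input table missing columns: {sorted(missing)}")
        positions = np.sort(frame["position_pct"].unique())
        time_grid = np.sort(frame["time_min"].unique())
        wide_b = frame.pivot_table(index="position_pct", columns="time_min", values="bicoid")
        wide_z = frame.pivot_table(index="position_pct", columns="time_min", values="zelda")
        return cls(
            positions=positions,
            time_grid=time_grid,
            bicoid=wide_b.loc[positions, time_grid].to_numpy(),
            zelda=wide_z.loc[positions[0], time_grid].to_numpy(),
        )


def default_input_field(
    bicoid_amplitude: float = 1.0,
    length_scale: float = 20.0,
    zelda_amplitude: float = 1.0,
    import_timescale: float = 1.0,
    positions: np.ndarray | None = None,
    time_grid: np.ndarray | None = None,
) -> InputField:
    """The study conditions: exponential Bicoid gradient (decay length 20 %EL,
    anterior amplitude 1) and uniform Zelda, both imported with a 1-min time
    constant so that nuclear levels saturate by ~3 min after anaphase."""
    positions = DEFAULT_POSITIONS.copy() if positions is None else np.asarray(positions, float)
    time_grid = DEFAULT_TIME_GRID.copy() if time_grid is None else np.asarray(time_grid, float)
    return InputField(
        positions=positions,
        time_grid=time_grid,
        bicoid=gen_bicoid(bicoid_amplitude, length_scale, import_timescale, positions, time_grid),
        zelda=gen_zelda(zelda_amplitude, import_timescale, time_grid),
    )
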