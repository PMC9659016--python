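"""Process-level drying metrics.

Quantities computed from raw measurements of a convective/infrared drying
run: dry-basis moisture content, total drying time under a stopping rule,
specific energy consumption (SEC) and rehydration capacity (RC).

Conventions
-----------
Moisture content is reported on a *dry basis* (kg water per kg dry solids).
The initial moisture fraction ``MC0`` that parameterises a run is a
*wet-basis* fraction (kg water per kg sample), so the dry-solids mass of a
sample of initial mass ``M0`` is ``M0 * (1 - MC0)``.  Converters between
the two bases are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NotDriedError

__all__ = [
    "MoistureSeries",
    "EnergyRecord",
    "RehydrationRecord",
    "moisture_content",
    "drying_time",
    "specific_energy",
    "rehydration_capacity",
    "wet_to_dry_basis",
    "dry_to_wet_basis",
]

#: Dry-basis moisture threshold (kg/kg) at which a run is considered finished.
DEFAULT_STOP_THRESHOLD = 0.05


def wet_to_dry_basis(mc_wet: float) -> float:
    """Convert a wet-basis moisture fraction to dry basis: w/(1-w)."""
    if not 0 <= mc_wet < 1:
        raise InvalidInputError(f"wet-basis fraction must be in [0, 1), got {mc_wet}")
    return mc_wet / (1.0 - mc_wet)


def dry_to_wet_basis(mc_dry: float) -> float:
    """Convert a dry-basis moisture content to a wet-basis fraction: d/(1+d)."""
    if mc_dry < 0:
        raise InvalidInputError(f"dry-basis moisture must be >= 0, got {mc_dry}")
    return mc_dry / (1.0 + mc_dry)


def moisture_content(Mt: float, M0: float, MC0: float) -> float:
    """Dry-basis moisture content of a sample of current mass ``Mt``.

    Parameters
    ----------
    Mt : current sample mass, kg.
    M0 : initial sample mass, kg.
    MC0 : initial moisture fraction of the sample (wet basis, 0 < MC0 < 1).

    Returns
    -------
    Moisture content in kg water / kg dry solids:
    ``(Mt - M0*(1 - MC0)) / (M0*(1 - MC0))``.
    """
    dry_solids = M0 * (1.0 - MC0)
    if dry_solids <= 0:
        raise InvalidInputError(
            f"dry-solids mass M0*(1-MC0) must be positive, got {dry_solids}"
        )
    if Mt < 0:
        raise InvalidInputError(f"sample mass must be >= 0, got {Mt}")
    return (Mt - dry_solids) / dry_solids


@dataclass(frozen=True)
class MoistureSeries:
    """A logged drying run: sample masses at strictly increasing times.

    times : minutes since the start of drying, strictly increasing.
    masses : sample masses in kg, one per time point.
    M0 : initial sample mass, kg.
    MC0 : initial moisture fraction, wet basis.
    """

    times: np.ndarray
    masses: np.ndarray
    M0: float
    MC0: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "masses", masses)
        if times.ndim != 1 or times.shape != masses.shape:
            raise InvalidInputError("times and masses must be 1-D and equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(times < 0):
            raise InvalidInputError("times must be nonnegative")
        if np.any(masses <= 0):
            raise InvalidInputError("masses must be positive")
        if self.M0 * (1.0 - self.MC0) <= 0:
            raise InvalidInputError("dry-solids mass M0*(1-MC0) must be positive")

    def moisture(self) -> np.ndarray:
        """Dry-basis moisture content at every logged time point."""
        dry_solids = self.M0 * (1.0 - self.MC0)
        return (self.masses - dry_solids) / dry_solids


def drying_time(series: MoistureSeries, threshold: float = DEFAULT_STOP_THRESHOLD) -> float:
    """First logged time at which moisture content falls *strictly below* threshold.

    The dryer's controller evaluates the stopping rule only at logged sample
    points (10-minute logging interval in the reference equipment); no
    interpolation is performed between points.

    Raises
    ------
    NotDriedError
        If no logged point is below the threshold.
    """
    if threshold <= 0:
        raise InvalidInputError(f"threshold must be > 0, got {threshold}")
    below = series.moisture() < threshold
    idx = np.flatnonzero(below)
    if idx.size == 0:
        raise NotDriedError(
            f"moisture never fell below {threshold} kg/kg within the logged series"
        )
    return float(series.times[idx[0]])


@dataclass(frozen=True)
class EnergyRecord:
    """Total electrical energy E (MJ) spent removing m_water (kg) of moisture."""

    E: float
    m_water: float

    def __post_init__(self) -> None:
        if self.E < 0:
            raise InvalidInputError(f"energy must be >= 0, got {self.E}")
        if self.m_water <= 0:
            raise InvalidInputError(f"m_water must be > 0, got {self.m_water}")


def specific_energy(rec: EnergyRecord) -> float:
    """Specific energy consumption, MJ per kg of water removed."""
    return rec.E / rec.m_water


@dataclass(frozen=True)
class RehydrationRecord:
    """Dried-sample mass W0 and post-soak mass Wt, both kg."""

    W0: float
    Wt: float

    def __post_init__(self) -> None:
        if self.W0 <= 0:
            raise InvalidInputError(f"W0 must be > 0, got {self.W0}")
        if self.Wt <= 0:
            raise InvalidInputError(f"Wt must be > 0, got {self.Wt}")


def rehydration_capacity(rec: RehydrationRecord) -> float:
    """Rehydration capacity: mass ratio after/before soaking (dimensionless)."""
    return rec.Wt / rec.W0
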