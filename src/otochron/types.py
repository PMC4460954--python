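"""Core data containers shared across the biochronology pipeline.

The pipeline moves through three representations: raw per-transect
increment widths indexed by fish age (:class:`IncrementSeries`), the same
widths keyed to calendar years of formation (:class:`DatedSeries`), and
dimensionless growth indices after standardization
(:class:`StandardizedSeries`).  A :class:`Chronology` is the per-year
average of standardized indices across fish, together with the number of
fish contributing to each year (the sample depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural invariant (bad series, bad table)."""


class FormatError(ValidationError):
    """A file could not be parsed in the declared format."""


@dataclass(frozen=True)
class IncrementSeries:
    """Raw increment widths for one measurement transect of one fish.

    Parameters
    ----------
    fish_id, transect_id : str
        Identifiers; the three transects of a fish conventionally carry
        single-letter ids ``"A"``, ``"B"``, ``"C"``.
    capture_year : int
        Calendar year the fish was caught.
    widths : array-like of float
        Increment widths in micrometres, ordered by age; element ``i``
        is the increment formed at age ``i + 1``.  Ages are therefore a
        contiguous 1-based run with no gaps.
    complete_final_increment : bool
        Whether the terminal increment had finished forming at capture.
        If False the terminal increment is dropped when calendar years
        are assigned.
    """

    fish_id: str
    transect_id: str
    capture_year: int
    widths: np.ndarray
    complete_final_increment: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValidationError(
                f"series {self.fish_id}{self.transect_id}: widths must be a "
                "non-empty 1-d sequence"
            )
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValidationError(
                f"series {self.fish_id}{self.transect_id}: all widths must be "
                "strictly positive and finite"
            )
        object.__setattr__(self, "widths", w)
        object.__setattr__(self, "capture_year", int(self.capture_year))

    @property
    def age_at_capture(self) -> int:
        """Maximum age, equal to the number of increments."""
        return int(self.widths.size)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(1, self.widths.size + 1)

    @property
    def label(self) -> str:
        """Series identifier, fish id with the transect letter appended."""
        return f"{self.fish_id}{self.transect_id}"


@dataclass(frozen=True)
class DatedSeries:
    """Increment widths keyed by calendar year of formation.

    ``widths`` maps year -> width (um); ``ages`` maps year -> fish age.
    Years are contiguous and the year<->age mapping is bijective.
    """

    fish_id: str
    transect_id: str
    widths: pd.Series
    ages: pd.Series

    def __post_init__(self) -> None:
        yrs = self.widths.index.to_numpy()
        if yrs.size == 0:
            raise ValidationError("dated series must be non-empty")
        if not np.array_equal(yrs, np.arange(yrs[0], yrs[0] + yrs.size)):
            raise ValidationError("calendar years must be contiguous")
        if not self.widths.index.equals(self.ages.index):
            raise ValidationError("widths and ages must share the same years")

    @property
    def years(self) -> np.ndarray:
        return self.widths.index.to_numpy()

    @property
    def label(self) -> str:
        return f"{self.fish_id}{self.transect_id}"


@dataclass(frozen=True)
class StandardizedSeries:
    """Dimensionless growth indices keyed by calendar year.

    Produced either by dividing widths by a smoothing-spline fit
    (high-frequency standardization used for crossdating) or by dividing
    by the population mean width-at-age curve (regional-curve style
    standardization used for chronology building).  ``transect_id`` is
    None after transects of a fish have been averaged.
    """

    fish_id: str
    indices: pd.Series
    transect_id: Optional[str] = None
    ages: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        vals = self.indices.to_numpy(dtype=float)
        if vals.size == 0:
            raise ValidationError("standardized series must be non-empty")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError(
                f"series {self.label}: standardized indices must be positive"
            )

    @property
    def years(self) -> np.ndarray:
        return self.indices.index.to_numpy()

    @property
    def label(self) -> str:
        t = self.transect_id if self.transect_id is not None else ""
        return f"{self.fish_id}{t}"


@dataclass(frozen=True)
class Chronology:
    """Master growth record: per-year mean index with sample depth."""

    index: pd.Series
    sample_depth: pd.Series
    stage: str = "adult"

    def __post_init__(self) -> None:
        if len(self.index) == 0:
            raise ValidationError("chronology must cover at least one year")
        yrs = self.index.index.to_numpy()
        if not np.array_equal(yrs, np.arange(yrs[0], yrs[0] + yrs.size)):
            raise ValidationError("chronology span must be contiguous")
        if not self.index.index.equals(self.sample_depth.index):
            raise ValidationError("index and sample_depth must share years")

    @property
    def years(self) -> np.ndarray:
        return self.index.index.to_numpy()

    @property
    def span(self) -> tuple[int, int]:
        yrs = self.years
        return int(yrs[0]), int(yrs[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "index": self.index.to_numpy(),
                "sample_depth": self.sample_depth.to_numpy(dtype=int),
            }
        )


@dataclass(frozen=True)
class MeanByAgeCurve:
    """Population mean increment width at each age (the RCS curve)."""

    mean_width: pd.Series
    n_at_age: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.mean_width.to_numpy() <= 0):
            raise ValidationError("mean widths must be positive")
        if np.any(self.n_at_age.to_numpy() < 1):
            raise ValidationError("n_at_age must be >= 1 wherever defined")


@dataclass(frozen=True)
class ChronologyStats:
    """Common-signal statistics for a chronology.

    rbar is the mean pairwise Pearson correlation among fish-level
    standardized series (fractional common variance); EPS is the
    expressed population signal n*rbar / (n*rbar + (1 - rbar)).
    """

    rbar: Optional[float]
    rbar_se: Optional[float]
    eps: Optional[float]
    n_eff: Optional[float]
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.rbar is not None and not -1.0 <= self.rbar <= 1.0:
            raise ValidationError("rbar must lie in [-1, 1]")
        if self.eps is not None and not (0.0 <= self.eps <= 1.0 or math.isnan(self.eps)):
            raise ValidationError("EPS must lie in [0, 1]")


@dataclass(frozen=True)
class DetrendConfig:
    """Smoothing-spline detrending parameters.

    ``rigidity`` is the wavelength (in years) at which the spline's
    amplitude frequency response equals ``response`` — the convention of
    the dendrochronology literature.  The default keeps 50% of the
    amplitude at a 22-year wavelength, passing the high-frequency
    variation to the standardized indices.
    """

    rigidity: float = 22.0
    response: float = 0.5

    def __post_init__(self) -> None:
        if self.rigidity < 2:
            raise ValidationError("rigidity must be >= 2 years")
        if not 0.0 < self.response < 1.0:
            raise ValidationError("response must be in (0, 1)")
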