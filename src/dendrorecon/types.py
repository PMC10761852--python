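"""Core domain containers for the reconstruction pipeline.

Ring widths are stored in millimetres at 0.01 mm recorded precision;
missing (locally absent) rings are encoded as 0.00 mm width, the ITRDB
convention, and treated as valid zero growth downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for missing monthly climate values
MISSING = np.nan


@dataclass
class RingSeries:
    """A single dated ring-width measurement series (one tree core).

    ``first_year`` is the calendar year CE of the innermost measured ring;
    ring year = calendar year of formation (no Schulman shift — Northern
    Hemisphere convention).
    """

    series_id: str
    first_year: int
    widths: np.ndarray  # mm, >= 0, no internal gaps
    site_id: str = ""
    tree_id: str | None = None
    core_id: str | None = None
    precision: float = 0.01  # mm, recorded measurement resolution

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"series {self.series_id!r}: widths must be a non-empty 1-d array")
        if np.any(self.widths < 0) or np.any(~np.isfinite(self.widths)):
            raise ValueError(f"series {self.series_id!r}: widths must be finite and >= 0")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.series_id)

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class SiteCollection:
    """All ring series from one site (or a pooled regional composite)."""

    site_id: str
    series: list[RingSeries] = field(default_factory=list)
    species_code: str = "UNKN"

    def __post_init__(self) -> None:
        ids = [s.series_id for s in self.series]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate series ids in collection {self.site_id!r}: {dup}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def ids(self) -> list[str]:
        return [s.series_id for s in self.series]

    def get(self, series_id: str) -> RingSeries:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)

    def to_frame(self) -> pd.DataFrame:
        """Year-indexed wide table of raw widths (NaN outside each series)."""
        return pd.DataFrame({s.series_id: s.to_series() for s in self.series}).sort_index()

    @property
    def first_year(self) -> int:
        return min(s.first_year for s in self.series)

    @property
    def last_year(self) -> int:
        return max(s.last_year for s in self.series)


def pool(collections: list[SiteCollection], site_id: str = "POOLED") -> SiteCollection:
    """Pool all series of several collections into one (regional composite input)."""
    series: list[RingSeries] = []
    for c in collections:
        series.extend(c.series)
    return SiteCollection(site_id=site_id, series=series, species_code="MIXD")


MONTH_ABBR = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
              "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"]


@dataclass
class MonthlyClimate:
    """Station monthly climate: one year x 12 matrix per variable.

    Variables use field-standard names: ``prcp`` (mm), ``tmean``/``tmax``/
    ``tmin`` (degC), optional ``rh`` (%), ``scpdsi`` (index).  Missing
    slots hold NaN.  The year span is contiguous.
    """

    station_id: str
    first_year: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = None
        for var, mat in self.data.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != 12:
                raise ValueError(f"variable {var!r}: need a year x 12 matrix")
            if n is None:
                n = mat.shape[0]
            elif mat.shape[0] != n:
                raise ValueError("all variables must cover the same year span")
            self.data[var] = mat
        if "prcp" in self.data:
            p = self.data["prcp"]
            if np.any(p[np.isfinite(p)] < 0):
                raise ValueError("negative precipitation")
        if all(v in self.data for v in ("tmax", "tmean", "tmin")):
            tx, tm, tn = (self.data[v] for v in ("tmax", "tmean", "tmin"))
            ok = np.isfinite(tx) & np.isfinite(tm) & np.isfinite(tn)
            if np.any(tx[ok] < tm[ok] - 1e-9) or np.any(tm[ok] < tn[ok] - 1e-9):
                raise ValueError("temperature ordering violated (need tmax >= tmean >= tmin)")

    @property
    def n_years(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_years - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def variable(self, name: str) -> np.ndarray:
        if name not in self.data:
            raise KeyError(f"climate variable {name!r} not present (have {sorted(self.data)})")
        return self.data[name]

    def to_frame(self, variable: str) -> pd.DataFrame:
        return pd.DataFrame(self.variable(variable), index=self.years, columns=MONTH_ABBR)
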