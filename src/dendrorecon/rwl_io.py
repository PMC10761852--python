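"""Tucson/RWL decadal-format ring-width I/O and station climate CSV reading.

The Tucson ("decadal") layout stores one measurement series as a run of
lines, each carrying the series id, the calendar year of the line's first
value, and up to ten values, so that every line after the first starts at
a decade boundary.  A stop marker terminates the series and encodes the
measurement precision: ``999`` for 0.01 mm units, ``-9999`` for 0.001 mm.
"""

from __future__ import annotations

import io
import os

import numpy as np
import pandas as pd

from .types import MISSING, MONTH_ABBR, MonthlyClimate, RingSeries, SiteCollection

STOP_001 = 999     # 0.01 mm precision stop marker
STOP_0001 = -9999  # 0.001 mm precision stop marker


class RWLFormatError(ValueError):
    """Raised on malformed Tucson input, carrying the offending line number."""


def _parse_line(line: str, lineno: int) -> tuple[str, int, list[int]]:
    sid = line[:8].strip()
    rest = line[8:].split()
    if not sid or len(rest) < 2:
        raise RWLFormatError(f"line {lineno}: expected 'id year values...', got {line!r}")
    try:
        year = int(rest[0])
    except ValueError:
        raise RWLFormatError(f"line {lineno}: non-numeric year field {rest[0]!r}") from None
    vals = []
    for tok in rest[1:]:
        try:
            vals.append(int(tok))
        except ValueError:
            raise RWLFormatError(f"line {lineno}: unparseable value token {tok!r}") from None
    return sid, year, vals


def read_rwl(path: str | os.PathLike | io.TextIOBase, site_id: str | None = None) -> SiteCollection:
    """Read a Tucson decadal ring-width file into a :class:`SiteCollection`.

    Stop markers are consumed and excluded from the widths; per-series
    precision (0.01 or 0.001 mm) is inferred from the marker.  Duplicate
    series ids and non-monotone decade lines are rejected.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = site_id or "RWL"
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        name = site_id or os.path.splitext(os.path.basename(path))[0]

    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        sid, year, vals = _parse_line(line, lineno)
        if sid not in raw:
            raw[sid] = []
            order.append(sid)
        elif raw[sid] and year <= raw[sid][-1][0]:
            raise RWLFormatError(
                f"line {lineno}: decade line for {sid!r} not after previous ({year} <= {raw[sid][-1][0]})")
        raw[sid].append((year, vals, lineno))

    series = []
    for sid in order:
        chunks = raw[sid]
        # the stop marker is only recognised as the very last value of the
        # series' last line -- 999 can legitimately occur as a 9.99 mm width
        divisor, values = 100.0, []
        last = chunks[-1][1]
        closed = bool(last) and last[-1] in (STOP_001, STOP_0001)
        if closed and last[-1] == STOP_0001:
            divisor = 1000.0
        for i, (year, vals, lineno) in enumerate(chunks):
            if closed and i == len(chunks) - 1:
                vals = vals[:-1]
            if i > 0:
                # each continuation line must start exactly where the previous ended
                prev_year, prev_vals, _ = chunks[i - 1]
                if year != prev_year + len(prev_vals):
                    raise RWLFormatError(
                        f"line {lineno}: series {sid!r} has a gap or overlap "
                        f"(line year {year}, expected {prev_year + len(prev_vals)})")
            values.extend(vals)
        widths = np.array(values, dtype=float) / divisor
        if np.any(widths < 0):
            bad = chunks[0][2]
            raise RWLFormatError(f"series {sid!r} (first line {bad}): negative ring width")
        series.append(RingSeries(series_id=sid, first_year=chunks[0][0], widths=widths,
                                 site_id=name, precision=1.0 / divisor))
    if not series:
        raise RWLFormatError("no series found in file")
    return SiteCollection(site_id=name, series=series)


def write_rwl(collection: SiteCollection, path: str | os.PathLike | io.TextIOBase,
              precision: float = 0.01) -> None:
    """Write a collection in Tucson decadal layout (0.01 mm units by default).

    ``read_rwl(write_rwl(c))`` is the identity on (series_id, first_year,
    widths) for widths representable at the chosen precision.
    """
    if len(collection) == 0:
        raise ValueError("nothing to serialize: empty collection")
    for s in collection:
        if len(s.series_id) > 8:
            raise ValueError(f"series id {s.series_id!r} exceeds 8 characters (RWL limit)")

    divisor = {0.01: 100, 0.001: 1000}[precision]
    stop = STOP_001 if precision == 0.01 else STOP_0001
    out = []
    for s in collection:
        ints = np.rint(s.widths * divisor).astype(int)
        year = s.first_year
        i = 0
        vals_with_stop = list(ints) + [stop]
        while i < len(vals_with_stop):
            # fill to the next decade boundary
            n = 10 - (year % 10)
            chunk = vals_with_stop[i:i + n]
            fields = "".join(f"{v:6d}" for v in chunk)
            out.append(f"{s.series_id:<8s}{year:4d}{fields}")
            i += len(chunk)
            year += len(chunk)
    text = "\n".join(out) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_climate_table(path: str | os.PathLike, layout: str = "wide",
                       variable: str = "prcp", station_id: str | None = None,
                       sentinel: float | None = None) -> MonthlyClimate:
    """Read a station monthly climate CSV into :class:`MonthlyClimate`.

    ``layout="wide"``: one file per variable with columns YEAR, JAN..DEC;
    ``variable`` names the variable the file holds.
    ``layout="long"``: columns year, month, variable, value (many variables
    in one file).  Year gaps are filled with all-NaN rows so the span is
    contiguous; an explicit ``sentinel`` value in the file is mapped to NaN.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().upper() for c in df.columns]
    name = station_id or os.path.splitext(os.path.basename(path))[0]

    if layout == "wide":
        if "YEAR" not in df.columns:
            raise ValueError("wide layout needs a YEAR column")
        missing = [m for m in MONTH_ABBR if m not in df.columns]
        if missing:
            raise ValueError(f"wide layout missing month columns: {missing}")
        if df["YEAR"].duplicated().any():
            raise ValueError("duplicate year rows")
        df = df.sort_values("YEAR")
        years = df["YEAR"].astype(int).to_numpy()
        span = np.arange(years[0], years[-1] + 1)
        mat = np.full((span.size, 12), MISSING)
        rows = years - years[0]
        mat[rows, :] = df[MONTH_ABBR].to_numpy(dtype=float)
        if sentinel is not None:
            mat[mat == sentinel] = MISSING
        data = {variable: mat}
        first_year = int(span[0])
    elif layout == "long":
        need = {"YEAR", "MONTH", "VARIABLE", "VALUE"}
        if not need.issubset(df.columns):
            raise ValueError(f"long layout needs columns {sorted(need)}")
        if ((df["MONTH"] < 1) | (df["MONTH"] > 12)).any():
            raise ValueError("month outside 1-12")
        if df.duplicated(subset=["YEAR", "MONTH", "VARIABLE"]).any():
            raise ValueError("duplicate (year, month, variable) entries")
        y0, y1 = int(df["YEAR"].min()), int(df["YEAR"].max())
        span = np.arange(y0, y1 + 1)
        data = {}
        for var, sub in df.groupby("VARIABLE"):
            mat = np.full((span.size, 12), MISSING)
            mat[sub["YEAR"].astype(int) - y0, sub["MONTH"].astype(int) - 1] = \
                sub["VALUE"].to_numpy(dtype=float)
            if sentinel is not None:
                mat[mat == sentinel] = MISSING
            data[str(var).lower()] = mat
        first_year = y0
    else:
        raise ValueError(f"unknown layout {layout!r} (use 'wide' or 'long')")

    return MonthlyClimate(station_id=name, first_year=first_year, data=data)


def write_climate_table(mc: MonthlyClimate, path: str | os.PathLike, variable: str) -> None:
    """Write one variable of a MonthlyClimate as a wide-layout CSV."""
    df = mc.to_frame(variable).reset_index(names="YEAR")
    df.to_csv(path, index=False)
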