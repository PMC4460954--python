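"""Readers and writers for the pipeline's interchange formats.

Increment widths travel either in the Tucson/RWL decadal ring-width
format (the interchange dialect of the dendrochronology toolchain) or in
a long-format CSV; chronologies and monthly climate tables are plain
CSV.  All readers validate structural invariants and reject, rather than
silently repair, malformed input.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .types import Chronology, FormatError, IncrementSeries, ValidationError

#: RWL stop markers and the micrometres-per-unit they imply.  A series
#: terminated by 999 is in 0.01 mm units, one terminated by -9999 is in
#: 0.001 mm units.
_STOP_UNITS = {999: 10.0, -9999: 1.0}

INCREMENT_CSV_COLUMNS = ("fish_id", "transect_id", "age", "width_um", "capture_year")


def _split_rwl_id(sid: str) -> tuple[str, str]:
    """Split an RWL series id into (fish_id, transect letter).

    RWL has no multi-transect concept, so transects are encoded as a
    trailing letter on the fish id (``FISH01A``).  Ids without a trailing
    letter are treated as single-transect series ``A``.
    """
    if len(sid) > 1 and sid[-1].isalpha():
        return sid[:-1], sid[-1]
    return sid, "A"


def read_rwl(path: str | os.PathLike) -> list[IncrementSeries]:
    """Read a Tucson decadal ring-width file into increment series.

    Each data line carries a series id, the calendar year of its first
    value, and up to ten integer widths; the series ends at a stop
    marker (999 for the 0.01 mm dialect, -9999 for 0.001 mm).  Widths
    are converted to micrometres according to the detected dialect, and
    the capture year is taken as the final dated year.
    """
    values: dict[str, list[int]] = {}
    first_year: dict[str, int] = {}
    next_year: dict[str, int] = {}
    units: dict[str, float] = {}
    order: list[str] = []

    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise FormatError(f"{path}: line {lineno}: expected id, year and values")
            sid = tokens[0]
            try:
                year = int(tokens[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: malformed decade year {tokens[1]!r}"
                ) from None
            if sid in units:
                raise FormatError(
                    f"{path}: line {lineno}: data after stop marker for series {sid}"
                )
            if sid not in values:
                values[sid] = []
                first_year[sid] = year
                next_year[sid] = year
                order.append(sid)
            elif year != next_year[sid]:
                raise FormatError(
                    f"{path}: line {lineno}: non-contiguous years for series {sid} "
                    f"(expected {next_year[sid]}, found {year})"
                )
            for tok in tokens[2:]:
                try:
                    v = int(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: malformed value {tok!r}"
                    ) from None
                if v in _STOP_UNITS:
                    units[sid] = _STOP_UNITS[v]
                    break
                values[sid].append(v)
                next_year[sid] += 1

    missing = [sid for sid in order if sid not in units]
    if missing:
        raise FormatError(f"{path}: series without stop marker: {', '.join(missing)}")

    out = []
    for sid in order:
        if not values[sid]:
            raise FormatError(f"{path}: series {sid} has no values")
        fish_id, transect_id = _split_rwl_id(sid)
        widths = np.asarray(values[sid], dtype=float) * units[sid]
        capture_year = first_year[sid] + len(values[sid]) - 1
        out.append(
            IncrementSeries(
                fish_id=fish_id,
                transect_id=transect_id,
                capture_year=capture_year,
                widths=widths,
            )
        )
    return out


def write_rwl(
    series_list: Sequence[IncrementSeries],
    path: str | os.PathLike,
    precision: str = "0.01mm",
) -> None:
    """Write increment series in Tucson decadal format.

    ``precision`` selects the dialect: ``"0.01mm"`` (stop marker 999) or
    ``"0.001mm"`` (stop marker -9999).  The series id is the fish id
    with the transect letter appended.
    """
    if precision == "0.01mm":
        unit, stop = 10.0, 999
    elif precision == "0.001mm":
        unit, stop = 1.0, -9999
    else:
        raise ValidationError(f"unknown RWL precision {precision!r}")

    lines: list[str] = []
    for s in series_list:
        sid = s.label
        if len(sid) > 8:
            raise ValidationError(f"RWL series id {sid!r} exceeds 8 characters")
        start = s.capture_year - s.age_at_capture + 1
        ints = np.rint(s.widths / unit).astype(int)
        if np.any(ints <= 0):
            raise ValidationError(
                f"series {sid}: width rounds to zero at precision {precision}"
            )
        fields = [str(v) for v in ints] + [str(stop)]
        year = start
        i = 0
        while i < len(fields):
            # each line runs to the end of the current decade
            room = 10 - (year % 10)
            chunk = fields[i : i + room]
            lines.append(f"{sid:<8}{year:>4}" + "".join(f"{f:>6}" for f in chunk))
            year += len(chunk)
            i += len(chunk)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")


def _series_from_group(
    fish_id: str, transect_id: str, grp: pd.DataFrame, source: str
) -> IncrementSeries:
    label = f"{fish_id}{transect_id}"
    ages = grp["age"].to_numpy(dtype=int)
    if len(np.unique(ages)) != len(ages):
        raise ValidationError(f"{source}: duplicate (fish, transect, age) rows for {label}")
    order = np.argsort(ages)
    ages = ages[order]
    if not np.array_equal(ages, np.arange(1, len(ages) + 1)):
        raise ValidationError(
            f"{source}: ages of series {label} must run contiguously from 1"
        )
    cap = grp["capture_year"].unique()
    if len(cap) != 1:
        raise ValidationError(f"{source}: conflicting capture years for {label}")
    complete = True
    if "complete_final_increment" in grp.columns:
        flags = grp["complete_final_increment"].astype(bool).unique()
        if len(flags) != 1:
            raise ValidationError(f"{source}: conflicting completeness flags for {label}")
        complete = bool(flags[0])
    return IncrementSeries(
        fish_id=str(fish_id),
        transect_id=str(transect_id),
        capture_year=int(cap[0]),
        widths=grp["width_um"].to_numpy(dtype=float)[order],
        complete_final_increment=complete,
    )


def read_increments_csv(path: str | os.PathLike) -> list[IncrementSeries]:
    """Read long-format increment measurements.

    Required columns: fish_id, transect_id, age, width_um, capture_year;
    an optional boolean complete_final_increment column is honoured.
    """
    df = pd.read_csv(path)
    missing = set(INCREMENT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no increment rows")
    out = [
        _series_from_group(fid, tid, grp, str(path))
        for (fid, tid), grp in df.groupby(["fish_id", "transect_id"], sort=True)
    ]
    return out


def write_increments_csv(
    series_list: Sequence[IncrementSeries], path: str | os.PathLike
) -> None:
    rows = []
    for s in series_list:
        for age, w in zip(s.ages, s.widths):
            rows.append(
                {
                    "fish_id": s.fish_id,
                    "transect_id": s.transect_id,
                    "age": int(age),
                    "width_um": float(w),
                    "capture_year": s.capture_year,
                    "complete_final_increment": s.complete_final_increment,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_chronology_csv(chron: Chronology, path: str | os.PathLike) -> None:
    """Write a chronology as year,index,sample_depth rows ordered by year."""
    chron.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_chronology_csv(path: str | os.PathLike, stage: str = "adult") -> Chronology:
    df = pd.read_csv(path)
    missing = {"year", "index", "sample_depth"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("year")
    years = pd.Index(df["year"].astype(int), name="year")
    return Chronology(
        index=pd.Series(df["index"].to_numpy(dtype=float), index=years),
        sample_depth=pd.Series(df["sample_depth"].to_numpy(dtype=int), index=years),
        stage=stage,
    )


def read_climate_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a monthly climate table: columns year, month, then one column
    per environmental factor."""
    df = pd.read_csv(path)
    if "year" not in df.columns or "month" not in df.columns:
        raise FormatError(f"{path}: climate table needs year and month columns")
    factors = [c for c in df.columns if c not in ("year", "month")]
    if not factors:
        raise FormatError(f"{path}: climate table has no factor columns")
    return df


def write_climate_csv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def write_standardized_csv(series_list, path: str | os.PathLike) -> None:
    """Write standardized series: fish_id, transect_id, year, age, index."""
    rows = []
    for s in series_list:
        ages = s.ages if s.ages is not None else pd.Series(np.nan, index=s.indices.index)
        for year in s.indices.index:
            rows.append(
                {
                    "fish_id": s.fish_id,
                    "transect_id": s.transect_id if s.transect_id is not None else "",
                    "year": int(year),
                    "age": ages.loc[year],
                    "index": float(s.indices.loc[year]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_standardized_csv(path: str | os.PathLike):
    """Read standardized series written by :func:`write_standardized_csv`."""
    from .types import StandardizedSeries

    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = {"fish_id", "transect_id", "year", "index"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (fid, tid), grp in df.groupby(["fish_id", "transect_id"], sort=True):
        grp = grp.sort_values("year")
        years = pd.Index(grp["year"].astype(int), name="year")
        ages = None
        if "age" in grp.columns and grp["age"].notna().all():
            ages = pd.Series(grp["age"].to_numpy(dtype=float).astype(int), index=years)
        out.append(
            StandardizedSeries(
                fish_id=str(fid),
                transect_id=str(tid) if str(tid) else None,
                indices=pd.Series(grp["index"].to_numpy(dtype=float), index=years),
                ages=ages,
            )
        )
    return out
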