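"""Master chronology construction and quality statistics.

Chronology development uses a regional-curve-style standardization that
preserves low-frequency common variation: increment widths are aligned
by fish age, the population mean width at each age is computed, and each
series is divided by that mean-by-age curve.  Transects of a fish are
averaged, series are split into adult (ages >= 8) and juvenile (ages
1-9) stages, and per-year averages with sample-depth filters give the
adult and juvenile master chronologies.

Chronology quality is summarized by rbar, the mean pairwise correlation
among fish-level series (fractional common variance), and the expressed
population signal EPS = n*rbar / (n*rbar + (1 - rbar)), the expected
squared correlation between the finite-sample chronology and the
hypothetical population chronology.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .crossdating import _pearson, _tukey_biweight_mean
from .series_prep import assign_calendar_years
from .types import (
    Chronology,
    ChronologyStats,
    IncrementSeries,
    MeanByAgeCurve,
    StandardizedSeries,
    ValidationError,
)

ADULT_MIN_AGE = 8  # "after age 7": increments formed at ages 8 and older
JUVENILE_MAX_AGE = 9
DEFAULT_ADULT_MIN_DEPTH = 20
DEFAULT_JUVENILE_MIN_DEPTH = 10


def mean_by_age_curve(series_list: Sequence[IncrementSeries]) -> MeanByAgeCurve:
    """Arithmetic mean increment width at each age across all series."""
    if len(series_list) < 2:
        raise ValidationError("mean-by-age curve requires at least 2 series")
    frame = pd.DataFrame(
        {s.label: pd.Series(s.widths, index=s.ages) for s in series_list}
    )
    return MeanByAgeCurve(
        mean_width=frame.mean(axis=1), n_at_age=frame.notna().sum(axis=1)
    )


def rcs_standardize(
    series: IncrementSeries, curve: MeanByAgeCurve
) -> StandardizedSeries:
    """Divide a series by the mean-by-age curve, keyed by calendar year."""
    dated = assign_calendar_years(series)
    ages = dated.ages.to_numpy()
    missing = set(ages) - set(curve.mean_width.index)
    if missing:
        raise ValidationError(
            f"series {series.label}: curve undefined at ages {sorted(missing)}"
        )
    ref = curve.mean_width.loc[ages].to_numpy()
    return StandardizedSeries(
        fish_id=series.fish_id,
        transect_id=series.transect_id,
        indices=pd.Series(dated.widths.to_numpy() / ref, index=dated.widths.index),
        ages=dated.ages,
    )


def average_within_fish(
    std_series: Sequence[StandardizedSeries],
) -> StandardizedSeries:
    """Per-year mean across the transect series of a single fish."""
    if not std_series:
        raise ValidationError("no series to average")
    fish_ids = {s.fish_id for s in std_series}
    if len(fish_ids) != 1:
        raise ValidationError(f"mixed fish ids in within-fish average: {sorted(fish_ids)}")
    frame = pd.DataFrame(
        {s.label: s.indices for s in std_series}
    ).sort_index()
    ages = None
    for s in std_series:
        if s.ages is not None:
            ages = s.ages.reindex(frame.index)
            break
    return StandardizedSeries(
        fish_id=std_series[0].fish_id,
        transect_id=None,
        indices=frame.mean(axis=1),
        ages=ages,
    )


def select_stage(std: StandardizedSeries, stage: str) -> Optional[StandardizedSeries]:
    """Restrict a series to adult (ages >= 8) or juvenile (ages 1-9) years.

    Returns ``None`` when no increments fall in the stage (allowed: a
    young fish has no adult increments).
    """
    if stage not in ("adult", "juvenile"):
        raise ValidationError(f"unknown stage {stage!r}")
    if std.ages is None:
        raise ValidationError(f"series {std.label}: ages required for stage selection")
    mask = (
        std.ages >= ADULT_MIN_AGE if stage == "adult" else std.ages <= JUVENILE_MAX_AGE
    )
    if not mask.any():
        return None
    return StandardizedSeries(
        fish_id=std.fish_id,
        transect_id=std.transect_id,
        indices=std.indices.loc[mask],
        ages=std.ages.loc[mask],
    )


def _longest_run(qualifying: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Years of the longest contiguous qualifying run (ties -> earlier run)."""
    best_start, best_len = None, 0
    i = 0
    n = qualifying.size
    while i < n:
        if qualifying[i]:
            j = i
            while j < n and qualifying[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_start is None:
        return np.empty(0, dtype=int)
    return years[best_start : best_start + best_len]


def build_chronology(
    fish_series: Sequence[StandardizedSeries],
    stage: str = "adult",
    min_depth: Optional[int] = None,
    depth_rule: Optional[str] = None,
    robust: bool = False,
) -> Chronology:
    """Average fish-level indices per year, applying the depth filter.

    ``depth_rule="threshold"`` (adult default, min depth 20) retains all
    years meeting the minimum depth; ``"longest_run"`` (juvenile
    default, min depth 10) keeps only the single longest contiguous run
    of qualifying years, ties broken towards the earlier run.  Either
    way the returned span is contiguous; a threshold chronology whose
    qualifying years are broken falls back to its longest run with a
    warning.
    """
    if stage not in ("adult", "juvenile"):
        raise ValidationError(f"unknown stage {stage!r}")
    if min_depth is None:
        min_depth = DEFAULT_ADULT_MIN_DEPTH if stage == "adult" else DEFAULT_JUVENILE_MIN_DEPTH
    if depth_rule is None:
        depth_rule = "threshold" if stage == "adult" else "longest_run"
    if depth_rule not in ("threshold", "longest_run"):
        raise ValidationError(f"unknown depth rule {depth_rule!r}")

    frame = pd.DataFrame({s.label: s.indices for s in fish_series}).sort_index()
    depth = frame.notna().sum(axis=1)
    years = frame.index.to_numpy()
    qualifying = (depth >= min_depth).to_numpy()
    if not qualifying.any():
        raise ValidationError(f"no year reaches sample depth {min_depth}")
    run = _longest_run(qualifying, years)
    if depth_rule == "threshold" and run.size != int(qualifying.sum()):
        warnings.warn(
            "qualifying years are non-contiguous; keeping the longest run",
            stacklevel=2,
        )
    kept = frame.loc[run]
    if robust:
        index = kept.apply(
            lambda row: _tukey_biweight_mean(row.dropna().to_numpy()), axis=1
        )
    else:
        index = kept.mean(axis=1)
    return Chronology(
        index=index, sample_depth=depth.loc[run].astype(int), stage=stage
    )


def rbar(
    std_series: Sequence[StandardizedSeries],
    min_overlap: int = 10,
) -> tuple[Optional[float], Optional[float], int]:
    """Mean pairwise Pearson correlation among fish-level series.

    Pairs must overlap by at least ``min_overlap`` years and both series
    must vary over the overlap.  Returns ``(rbar, se, n_pairs)``;
    ``(None, None, 0)`` when no pair qualifies.  The standard error is
    the SD of the pairwise correlations divided by sqrt(n_pairs).
    """
    frame = pd.DataFrame({s.label: s.indices for s in std_series})
    cols = frame.columns
    rs = []
    for a, b in itertools.combinations(cols, 2):
        sub = frame[[a, b]].dropna()
        if len(sub) < min_overlap:
            continue
        x = sub[a].to_numpy()
        y = sub[b].to_numpy()
        # constant over the overlap (to numerical precision): undefined r
        tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
        tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
        if np.ptp(x) <= tol_x or np.ptp(y) <= tol_y:
            continue
        rs.append(_pearson(x, y))
    if not rs:
        return None, None, 0
    rs_arr = np.asarray(rs)
    se = float(rs_arr.std(ddof=1) / np.sqrt(rs_arr.size)) if rs_arr.size > 1 else 0.0
    return float(rs_arr.mean()), se, int(rs_arr.size)


def eps(rbar_value: float, n: float) -> float:
    """Expressed population signal for mean correlation ``rbar_value``
    and ``n`` contributing series.

    EPS = n*rbar / (n*rbar + (1 - rbar)).  For rbar <= 0 the chronology
    carries no common signal and EPS is reported as 0 with a warning.
    """
    if n < 1:
        raise ValidationError("EPS requires n >= 1")
    if not -1.0 < rbar_value <= 1.0:
        raise ValidationError("rbar must lie in (-1, 1]")
    if rbar_value <= 0.0:
        warnings.warn("rbar <= 0: signal-free chronology, EPS reported as 0", stacklevel=2)
        return 0.0
    return float(n * rbar_value / (n * rbar_value + (1.0 - rbar_value)))


def chronology_stats(
    fish_series: Sequence[StandardizedSeries],
    chron: Chronology,
    min_overlap: int = 10,
) -> ChronologyStats:
    """Whole-period rbar and EPS over the chronology's retained span.

    The effective n for EPS is the median sample depth over the span
    (depth varies by year).
    """
    lo, hi = chron.span
    restricted = []
    for s in fish_series:
        sub = s.indices.loc[(s.indices.index >= lo) & (s.indices.index <= hi)]
        if len(sub):
            restricted.append(
                StandardizedSeries(
                    fish_id=s.fish_id, transect_id=s.transect_id, indices=sub
                )
            )
    rb, se, n_pairs = rbar(restricted, min_overlap)
    n_eff = float(np.median(chron.sample_depth.to_numpy()))
    if rb is None:
        return ChronologyStats(rbar=None, rbar_se=None, eps=None, n_eff=n_eff, n_pairs=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        e = eps(rb, n_eff)
    return ChronologyStats(rbar=rb, rbar_se=se, eps=e, n_eff=n_eff, n_pairs=n_pairs)


@dataclass(frozen=True)
class RunningStats:
    """Sliding-window rbar/EPS series plus their across-window mean."""

    table: pd.DataFrame
    mean_eps: Optional[float]


def running_stats(
    fish_series: Sequence[StandardizedSeries],
    window: int = 10,
    step: int = 1,
    min_overlap: int = 10,
) -> RunningStats:
    """rbar and EPS in sliding windows across the common span.

    Each window reports rbar over pairs overlapping by at least
    ``min(window, min_overlap)`` years within the window, EPS with
    n_eff = mean sample depth in the window, and the across-window mean
    EPS (the "averaged EPS" convention).  Windows without a qualifying
    pair are reported with missing values and excluded from the mean.
    """
    frame = pd.DataFrame({s.label: s.indices for s in fish_series}).sort_index()
    years = frame.index.to_numpy()
    if window > years.size:
        raise ValidationError(
            f"window {window} exceeds the covered span ({years.size} years)"
        )
    eff_overlap = min(window, min_overlap)
    rows = []
    for start in range(0, years.size - window + 1, step):
        sub = frame.iloc[start : start + window]
        subset = [
            StandardizedSeries(fish_id=str(c), indices=sub[c].dropna())
            for c in sub.columns
            if sub[c].notna().sum() > 0
        ]
        rb, _, n_pairs = rbar(subset, eff_overlap)
        n_eff = float(sub.notna().sum(axis=1).mean())
        if rb is None:
            e = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e = eps(rb, max(n_eff, 1.0))
        rows.append(
            {
                "start_year": int(years[start]),
                "end_year": int(years[start + window - 1]),
                "rbar": np.nan if rb is None else rb,
                "eps": e,
                "n_eff": n_eff,
                "n_pairs": n_pairs,
            }
        )
    table = pd.DataFrame(rows)
    valid = table["eps"].dropna()
    return RunningStats(table=table, mean_eps=float(valid.mean()) if len(valid) else None)


def build_stage_chronology(
    series_list: Sequence[IncrementSeries],
    stage: str = "adult",
    min_depth: Optional[int] = None,
    depth_rule: Optional[str] = None,
    robust: bool = False,
) -> tuple[Chronology, list[StandardizedSeries], ChronologyStats]:
    """Full RCS pipeline: curve, divide, average transects, stage filter,
    depth-filtered chronology, and quality statistics.

    Returns the chronology, the stage-restricted fish-level series, and
    the whole-period stats.
    """
    curve = mean_by_age_curve(series_list)
    std = [rcs_standardize(s, curve) for s in series_list]
    by_fish: dict[str, list[StandardizedSeries]] = {}
    for s in std:
        by_fish.setdefault(s.fish_id, []).append(s)
    fish_level = [average_within_fish(group) for group in by_fish.values()]
    staged = [s for s in (select_stage(f, stage) for f in fish_level) if s is not None]
    if len(staged) < 2:
        raise ValidationError(f"fewer than 2 fish contribute {stage} increments")
    chron = build_chronology(staged, stage, min_depth, depth_rule, robust)
    stats = chronology_stats(staged, chron)
    return chron, staged, stats
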