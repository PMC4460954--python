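"""Statistical crossdating quality control.

Each spline-standardized series is correlated against the leave-one-out
master (the per-year average of all other series); low correlations flag
series whose increment boundaries deserve visual re-inspection, and a
lagged-correlation scan detects series that are mis-dated by a shifted
year count (a missed or doubled increment).  The tool flags; correction
of dating errors is a human decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import StandardizedSeries, ValidationError

#: Default critical correlation: the 99% one-tailed critical level used
#: by classic crossdating software for 50-year segments.
DEFAULT_CRITICAL_R = 0.3665
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_LAG = 3


def _tukey_biweight_mean(x: np.ndarray, c: float = 9.0, n_iter: int = 10) -> float:
    """Tukey biweight robust location (used for the optional robust master)."""
    m = np.median(x)
    for _ in range(n_iter):
        s = np.median(np.abs(x - m))
        if s == 0:
            return float(m)
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return float(m)
        m = float(np.sum(w * x) / w.sum())
    return float(m)


def _series_frame(series_list: Sequence[StandardizedSeries]) -> pd.DataFrame:
    frame = pd.DataFrame({s.label: s.indices for s in series_list})
    return frame.sort_index()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def leave_one_out_master(
    series_list: Sequence[StandardizedSeries],
    exclude: str,
    robust: bool = False,
) -> StandardizedSeries:
    """Average of all series except ``exclude``, on years with depth >= 2.

    ``exclude`` is a series label (fish id + transect letter).  With
    ``robust`` True the per-year Tukey biweight mean replaces the
    arithmetic mean.
    """
    if len(series_list) < 3:
        raise ValidationError("leave-one-out master requires at least 3 series")
    frame = _series_frame(series_list)
    if exclude not in frame.columns:
        raise ValidationError(f"series {exclude!r} not found")
    rest = frame.drop(columns=exclude)
    if rest.shape[1] < 2:
        raise ValidationError("exclusion leaves fewer than 2 series")
    depth = rest.notna().sum(axis=1)
    rest = rest.loc[depth >= 2]
    if rest.empty:
        raise ValidationError("no year is covered by >= 2 remaining series")
    if robust:
        vals = rest.apply(
            lambda row: _tukey_biweight_mean(row.dropna().to_numpy()), axis=1
        )
    else:
        vals = rest.mean(axis=1)
    # master may have interior gaps where depth dips below 2; keep as-is
    return _master_series(vals)


def _master_series(vals: pd.Series) -> StandardizedSeries:
    # bypass StandardizedSeries validation: a master may be non-contiguous
    # where sample depth dips, which is legitimate for a reference average
    out = StandardizedSeries.__new__(StandardizedSeries)
    object.__setattr__(out, "fish_id", "master")
    object.__setattr__(out, "transect_id", None)
    object.__setattr__(out, "indices", vals)
    object.__setattr__(out, "ages", None)
    return out


def series_master_correlation(
    series: StandardizedSeries,
    master: StandardizedSeries,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[Optional[float], int]:
    """Pearson r between a series and the master over their common years.

    Returns ``(None, n_overlap)`` when the overlap is below
    ``min_overlap`` (insufficient to judge alignment).
    """
    joined = pd.concat([series.indices, master.indices], axis=1, join="inner").dropna()
    n = len(joined)
    if n < min_overlap:
        return None, n
    r = _pearson(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
    return (None if np.isnan(r) else r), n


def best_lag(
    series: StandardizedSeries,
    master: StandardizedSeries,
    max_lag: int = DEFAULT_MAX_LAG,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[Optional[int], Optional[float]]:
    """Lag in [-max_lag, max_lag] maximizing r against the master.

    A positive lag means the series' years must be increased by that
    amount to align with the master.  Ties are broken towards the
    smallest ``|lag|``, then negative before positive.  Returns
    ``(None, None)`` when no lag achieves the minimum overlap.
    """
    m_years = master.indices.index.to_numpy()
    m_vals = master.indices.to_numpy()
    s_years = series.indices.index.to_numpy()
    s_vals = series.indices.to_numpy()
    lag_order = sorted(
        range(-max_lag, max_lag + 1), key=lambda l: (abs(l), 0 if l < 0 else 1)
    )
    best: tuple[Optional[int], Optional[float]] = (None, None)
    for lag in lag_order:
        shifted = s_years + lag
        # master years are sorted; map shifted years onto master positions
        pos = np.searchsorted(m_years, shifted)
        ok = (pos < m_years.size) & (m_years[np.minimum(pos, m_years.size - 1)] == shifted)
        mv = m_vals[pos[ok]]
        sv = s_vals[ok]
        keep = np.isfinite(mv)
        if keep.sum() < min_overlap:
            continue
        r = _pearson(sv[keep], mv[keep])
        if np.isnan(r):
            continue
        if best[1] is None or r > best[1]:
            best = (lag, r)
    return best


def flag_low_correlation(report: pd.DataFrame, critical_r: float = DEFAULT_CRITICAL_R) -> pd.Series:
    """Boolean flags: r strictly below the critical level.

    A series exactly at the critical value is not flagged; series with
    no computable r (insufficient overlap) are flagged for inspection.
    """
    r = report["r"]
    return (r < critical_r) | r.isna()


def crossdate(
    series_list: Sequence[StandardizedSeries],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    critical_r: float = DEFAULT_CRITICAL_R,
    max_lag: int = DEFAULT_MAX_LAG,
    robust: bool = False,
) -> pd.DataFrame:
    """Leave-one-out crossdating report for a set of standardized series.

    Returns a DataFrame indexed by series label with columns ``r``,
    ``n_overlap``, ``flagged``, ``best_lag`` and ``best_lag_r``.
    """
    rows = {}
    for s in series_list:
        master = leave_one_out_master(series_list, s.label, robust=robust)
        r, n = series_master_correlation(s, master, min_overlap)
        lag, lag_r = best_lag(s, master, max_lag, min_overlap)
        rows[s.label] = {
            "r": np.nan if r is None else r,
            "n_overlap": n,
            "best_lag": np.nan if lag is None else lag,
            "best_lag_r": np.nan if lag_r is None else lag_r,
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "series"
    report["flagged"] = flag_low_correlation(report, critical_r)
    return report


@dataclass(frozen=True)
class LocatedError:
    """Best change-point explanation of a suspected dating error.

    ``year`` is the estimated calendar year of the mis-placed increment
    boundary; ``lag`` the correction the mis-dated side needs; ``side``
    which side of the change point is shifted.  ``r_corrected`` is the
    series-master correlation after applying the correction,
    ``r_uncorrected`` before.
    """

    year: int
    lag: int
    side: str
    r_corrected: float
    r_uncorrected: float


def segment_lags(
    series: StandardizedSeries,
    master: StandardizedSeries,
    segment: int = 10,
    lap: int = 5,
    max_lag: int = DEFAULT_MAX_LAG,
    min_overlap: int = 8,
) -> pd.DataFrame:
    """Best lag per fixed-length segment of the series (diagnostic view).

    Segments of ``segment`` years advance by ``segment - lap`` years; a
    run of non-zero lags marks the mis-dated portion of a series.
    """
    if segment < 3 or not 0 <= lap < segment:
        raise ValidationError("need segment >= 3 and 0 <= lap < segment")
    years = series.indices.index.to_numpy()
    rows = []
    step = segment - lap
    for start in range(0, max(1, years.size - segment + 1), step):
        sub = series.indices.iloc[start : start + segment]
        sub_series = _master_series(sub)
        object.__setattr__(sub_series, "fish_id", series.label)
        lag, r = best_lag(sub_series, master, max_lag, min(min_overlap, len(sub)))
        rows.append(
            {
                "start_year": int(years[start]),
                "end_year": int(sub.index[-1]),
                "lag": np.nan if lag is None else lag,
                "r": np.nan if r is None else r,
            }
        )
    return pd.DataFrame(rows)


def locate_dating_error(
    series: StandardizedSeries,
    master: StandardizedSeries,
    max_lag: int = 1,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    sides: Sequence[str] = ("early",),
    smooth_halfwin: int = 2,
) -> Optional[LocatedError]:
    """Change-point scan localizing a single +-lag dating error.

    Series and master are standardized to zero mean and unit variance;
    for every candidate (lag, side, change-point year) the total squared
    deviation between the re-dated series and the master is computed,
    and the combination minimizing it wins (a least-squares change-point
    estimator).  Because adjacent candidate cuts differ by a single
    year's evidence, the objective is averaged over a window of
    ``2 * smooth_halfwin + 1`` neighbouring cuts before the minimum is
    taken, damping single-year noise flips at the change point.  The
    reported ``year`` is the estimated year of the mis-placed boundary:
    the change point, minus one for a negative-lag (missed-increment)
    correction, since a deletion's ideal change point sits one year
    above the missing increment.

    Because calendar years are assigned backwards from the capture year,
    a boundary error always mis-dates the early portion of a series;
    ``sides`` therefore defaults to scanning early-side corrections
    only.  Pass ``("early", "late")`` to scan both.  Returns ``None``
    when no shifted variant beats the unshifted alignment.
    """
    bad_sides = set(sides) - {"early", "late"}
    if bad_sides or not sides:
        raise ValidationError(f"sides must be drawn from 'early'/'late', got {sides!r}")
    m_years = master.indices.index.to_numpy()
    m_vals = master.indices.to_numpy()
    s_years = series.indices.index.to_numpy()
    s_vals = series.indices.to_numpy()
    if s_years.size < max(3, min_overlap):
        return None

    s_z = (s_vals - s_vals.mean()) / s_vals.std()
    m_z = (m_vals - np.nanmean(m_vals)) / np.nanstd(m_vals)

    def master_at(years: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(m_years, years)
        ok = (pos < m_years.size) & (
            m_years[np.minimum(pos, m_years.size - 1)] == years
        )
        out = np.full(years.size, np.nan)
        out[ok] = m_z[pos[ok]]
        return out

    def r_for(years: np.ndarray) -> float:
        mv = master_at(years)
        keep = np.isfinite(mv)
        if keep.sum() < min_overlap:
            return np.nan
        return _pearson(s_vals[keep], mv[keep])

    e_aligned = np.nan_to_num((s_z - master_at(s_years)) ** 2)
    sse0 = float(e_aligned.sum())
    n = s_years.size
    halfwin = min(smooth_halfwin, max(0, (n - 2) // 2 - 1))
    kernel = np.ones(2 * halfwin + 1) / (2 * halfwin + 1)
    best: Optional[tuple[float, int, int, str]] = None  # (sse, cut, lag, side)
    for lag in [l for l in range(-max_lag, max_lag + 1) if l != 0]:
        e_shifted = np.nan_to_num((s_z - master_at(s_years + lag)) ** 2)
        cum_al = np.concatenate([[0.0], np.cumsum(e_aligned)])
        cum_sh = np.concatenate([[0.0], np.cumsum(e_shifted)])
        for side in sides:
            cuts = np.arange(1, n)
            if side == "early":
                sse = cum_sh[cuts] + (cum_al[-1] - cum_al[cuts])
            else:
                sse = cum_al[cuts] + (cum_sh[-1] - cum_sh[cuts])
            smoothed = np.convolve(sse, kernel, mode="same")
            if halfwin:
                smoothed[:halfwin] = np.inf
                smoothed[-halfwin:] = np.inf
            i = int(np.argmin(smoothed))
            if smoothed[i] < sse0 and (best is None or smoothed[i] < best[0]):
                best = (float(smoothed[i]), int(s_years[cuts[i]]), lag, side)
    if best is None:
        return None
    _, cut, lag, side = best
    if side == "early":
        corrected = np.where(s_years < cut, s_years + lag, s_years)
    else:
        corrected = np.where(s_years >= cut, s_years + lag, s_years)
    return LocatedError(
        year=cut - 1 if lag < 0 else cut,
        lag=lag,
        side=side,
        r_corrected=float(r_for(corrected)),
        r_uncorrected=float(r_for(s_years)),
    )
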