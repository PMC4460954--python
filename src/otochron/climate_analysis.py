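"""Climate-growth screening: correlations, collinearity, PCA, regression.

The screen correlates a growth chronology with growing-season
(January-March) monthly values of five environmental factors — fifteen
variables in all — using Pearson correlations at a fixed significance
threshold tightened to alpha = 0.03 to account for the multiple
comparisons.  Collinear predictors are grouped by absolute pairwise
correlation and combined by principal components analysis on the
correlation matrix; chronologies are then related to component scores
(or single predictors, transformed where needed) by ordinary least
squares with residual diagnostics: Durbin-Watson for autocorrelation,
Shapiro-Wilk for normality and Breusch-Pagan for homoscedasticity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.stattools import durbin_watson

from .types import Chronology, ValidationError

MONTH_ABBREV = {1: "jan", 2: "feb", 3: "mar"}


@dataclass(frozen=True)
class ScreenConfig:
    """Screen settings.

    ``alpha`` is the fixed significance threshold (0.03, the tightened
    level standing in for a formal multiplicity correction);
    ``adjustment`` may instead be ``"bonferroni"`` or ``"fdr_bh"`` for
    sensitivity analyses.  ``collinearity_r`` is the absolute pairwise
    correlation at which significant predictors are grouped before PCA.
    ``transforms`` maps factor names to variance-stabilizing transforms
    applied before regression (rainfall totals are fourth-root
    transformed because of their range).
    """

    alpha: float = 0.03
    months: tuple[int, ...] = (1, 2, 3)
    collinearity_r: float = 0.5
    adjustment: str = "fixed"
    transforms: dict = field(default_factory=lambda: {"rain": "fourth_root"})

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.adjustment not in ("fixed", "bonferroni", "fdr_bh"):
            raise ValidationError(f"unknown adjustment {self.adjustment!r}")
        bad = [m for m in self.months if m not in MONTH_ABBREV]
        if bad:
            raise ValidationError(f"unsupported months {bad}; screen covers Jan-Mar")


@dataclass(frozen=True)
class PCAResult:
    """PCA of standardized predictors (correlation-matrix convention)."""

    loadings: pd.DataFrame  # variable x component, unit-norm eigenvectors
    explained_fraction: np.ndarray
    scores: pd.DataFrame  # year x component


@dataclass(frozen=True)
class ModelFit:
    """OLS fit summary with residual diagnostics."""

    params: pd.Series
    bse: pd.Series
    model_p: float
    r2: float
    adj_r2: float
    durbin_watson: float
    normality_p: float
    homoscedasticity_p: float
    nobs: int
    predictors: tuple[str, ...]


@dataclass(frozen=True)
class ScreenResult:
    """Full output of the environmental screen."""

    records: pd.DataFrame
    groups: list[list[str]]
    pca: dict[str, PCAResult]
    models: dict[str, ModelFit]


def is_significant(p: float, alpha: float = 0.03) -> bool:
    """Fixed-threshold rule: significant iff p < alpha (strict)."""
    return bool(p < alpha)


def variable_name(factor: str, month: int) -> str:
    return f"{factor}_{MONTH_ABBREV[month]}"


def build_screen_table(
    climate: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
    years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Pivot the monthly climate table into year x (factor, month) columns.

    One column per factor and configured month (15 for five factors and
    January-March).  With ``years`` given, rows are restricted to the
    intersection with those years (a span mismatch is logged, not
    fatal); missing factor-months are an error listing the gaps.
    """
    if "year" not in climate.columns or "month" not in climate.columns:
        raise ValidationError("climate table needs year and month columns")
    factors = [c for c in climate.columns if c not in ("year", "month")]
    sub = climate[climate["month"].isin(config.months)]
    table = sub.pivot(index="year", columns="month", values=factors)
    table.columns = [variable_name(f, m) for f, m in table.columns]
    expected = [variable_name(f, m) for f in factors for m in config.months]
    gaps = sorted(
        set(expected) - set(c for c in table.columns if table[c].notna().all())
    )
    if gaps:
        raise ValidationError(f"missing factor-month values: {gaps}")
    table = table[expected]
    if years is not None:
        keep = table.index.intersection(pd.Index(years))
        if len(keep) < len(years):
            warnings.warn(
                f"climate table covers {len(keep)} of {len(np.unique(years))} "
                "requested years; truncating to the intersection",
                stacklevel=2,
            )
        table = table.loc[keep]
    return table


def correlation_screen(
    chron: Chronology | pd.Series,
    table: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Pearson r, two-sided p and significance per screen variable.

    p-values come from the t distribution with n - 2 degrees of
    freedom.  A variable constant over the overlap yields an undefined
    correlation and is flagged ``degenerate``.
    """
    values = chron.index if isinstance(chron, Chronology) else chron
    joined = table.join(values.rename("_chron"), how="inner").dropna(subset=["_chron"])
    n = len(joined)
    if n < 10:
        raise ValidationError(f"only {n} overlapping years; need at least 10")
    y = joined["_chron"].to_numpy()
    rows = []
    for col in table.columns:
        x = joined[col].to_numpy()
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            rows.append(
                {"variable": col, "r": np.nan, "p": np.nan, "n_years": n,
                 "significant": False, "degenerate": True}
            )
            continue
        r, p = scipy.stats.pearsonr(x, y)
        rows.append(
            {"variable": col, "r": float(r), "p": float(p), "n_years": n,
             "significant": False, "degenerate": False}
        )
    records = pd.DataFrame(rows).set_index("variable")
    ok = ~records["degenerate"]
    if config.adjustment == "fixed":
        records.loc[ok, "significant"] = records.loc[ok, "p"] < config.alpha
    elif config.adjustment == "bonferroni":
        records.loc[ok, "significant"] = records.loc[ok, "p"] < config.alpha / ok.sum()
    else:  # fdr_bh
        rej, *_ = multipletests(records.loc[ok, "p"], alpha=config.alpha, method="fdr_bh")
        records.loc[ok, "significant"] = rej
    return records


def collinearity_groups(
    table: pd.DataFrame,
    threshold: float = 0.5,
    variables: Optional[Sequence[str]] = None,
) -> list[list[str]]:
    """Connected components of the |pairwise r| >= threshold graph.

    ``variables`` restricts the graph (typically to screen-significant
    columns); the >= convention includes edges exactly at the threshold.
    """
    cols = list(variables) if variables is not None else list(table.columns)
    if len(cols) < 2:
        return [[c] for c in cols]
    corr = table[cols].corr().abs().to_numpy()
    adj = corr >= threshold
    seen: set[int] = set()
    groups: list[list[str]] = []
    for i in range(len(cols)):
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in range(len(cols)):
                if j not in seen and adj[k, j]:
                    seen.add(j)
                    stack.append(j)
        groups.append(sorted(cols[k] for k in comp))
    return sorted(groups, key=lambda g: (-len(g), g))


def pca_combine(table: pd.DataFrame) -> PCAResult:
    """PCA of the given columns on the correlation matrix.

    Columns are centred and scaled to unit variance before the
    eigendecomposition, so scales (index units, psu, mm) do not weight
    the components.  Signs are fixed so each component's
    largest-magnitude loading is positive; explained fractions sum to 1.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValidationError("PCA needs at least 2 columns and 3 rows")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        dead = [c for c, s in zip(table.columns, sd) if s == 0.0]
        raise ValidationError(f"zero-variance columns in PCA input: {dead}")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    comps = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(evecs, index=table.columns, columns=comps),
        explained_fraction=evals / evals.sum(),
        scores=pd.DataFrame(Z @ evecs, index=table.index, columns=comps),
    )


def fourth_root(values) -> np.ndarray:
    """Elementwise fourth root; rejects negative input."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValidationError("fourth-root transform requires non-negative values")
    return x**0.25


_TRANSFORMS: dict[str, Callable] = {"fourth_root": fourth_root}


def fit_linear_model(
    chron: Chronology | pd.Series,
    predictors: pd.DataFrame,
    transforms: Optional[dict] = None,
) -> ModelFit:
    """OLS of the chronology on the given predictors with diagnostics.

    ``transforms`` maps predictor column names to a transform name
    (``"fourth_root"``) or callable applied before fitting.  Reports the
    overall model (F-test) p-value, adjusted R-squared
    ``1 - (1 - R2)(n - 1)/(n - k - 1)``, the Durbin-Watson statistic
    (2 by convention when residuals are exactly zero), Shapiro-Wilk
    residual-normality p and Breusch-Pagan homoscedasticity p.
    """
    y = chron.index if isinstance(chron, Chronology) else chron
    X = predictors.copy()
    for col, tr in (transforms or {}).items():
        if col in X.columns:
            fn = _TRANSFORMS[tr] if isinstance(tr, str) else tr
            X[col] = fn(X[col].to_numpy())
    joined = X.join(y.rename("_y"), how="inner").dropna()
    n, k = len(joined), X.shape[1]
    if n <= k + 2:
        raise ValidationError(f"need more than {k + 2} years for {k} predictors; have {n}")
    design = joined[list(X.columns)].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), design])) < k + 1:
        corr = joined[list(X.columns)].corr().abs()
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1 :]
            if corr.loc[a, b] > 0.999
        ]
        raise ValidationError(
            f"rank-deficient design; collinear predictors: {pairs or list(X.columns)}"
        )
    model = sm.OLS(joined["_y"].to_numpy(), sm.add_constant(design)).fit()
    resid = model.resid
    if np.allclose(resid, 0.0, atol=1e-12):
        dw, norm_p, het_p = 2.0, np.nan, np.nan
    else:
        dw = float(durbin_watson(resid))
        norm_p = float(scipy.stats.shapiro(resid).pvalue)
        het_p = float(het_breuschpagan(resid, sm.add_constant(design))[1])
    names = ["const", *X.columns]
    return ModelFit(
        params=pd.Series(model.params, index=names),
        bse=pd.Series(model.bse, index=names),
        model_p=float(model.f_pvalue),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        durbin_watson=dw,
        normality_p=norm_p,
        homoscedasticity_p=het_p,
        nobs=n,
        predictors=tuple(X.columns),
    )


def two_predictor_gain(
    chron: Chronology | pd.Series,
    p1: pd.Series,
    p2: pd.Series,
    collinearity_r: float = 0.5,
    transforms: Optional[dict] = None,
) -> tuple[float, float, ModelFit, ModelFit]:
    """Adjusted R-squared of the one- and two-predictor models.

    Used for the juvenile-style comparison: does adding a marginal
    second predictor (e.g. rainfall) strengthen the model?  Collinear
    predictors trigger a warning but both fits are still returned.
    """
    overlap = pd.concat([p1, p2], axis=1, join="inner").dropna()
    r12 = np.corrcoef(overlap.iloc[:, 0], overlap.iloc[:, 1])[0, 1]
    if abs(r12) >= collinearity_r:
        warnings.warn(
            f"predictors are collinear (r = {r12:.3f}); interpret the joint "
            "model with caution",
            stacklevel=2,
        )
    name1 = p1.name or "p1"
    name2 = p2.name or "p2"
    single = fit_linear_model(chron, p1.to_frame(name1), transforms)
    both = fit_linear_model(
        chron, pd.concat([p1.rename(name1), p2.rename(name2)], axis=1), transforms
    )
    return single.adj_r2, both.adj_r2, single, both


def run_screen(
    chron: Chronology,
    climate: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Full screen: correlations, collinearity grouping, PCA, models.

    Significant variables are grouped by absolute correlation; a group
    spanning several factors is expanded to all configured months of
    those factors and combined by PCA, and the chronology is regressed
    on PC1.  Singleton variables are regressed directly, with any
    configured factor transform applied.
    """
    table = build_screen_table(climate, config, years=chron.years)
    records = correlation_screen(chron, table, config)
    sig = list(records.index[records["significant"]])
    groups = collinearity_groups(table, config.collinearity_r, variables=sig)
    pca: dict[str, PCAResult] = {}
    models: dict[str, ModelFit] = {}
    for group in groups:
        factors = sorted({v.rsplit("_", 1)[0] for v in group})
        if len(group) >= 2:
            cols = [variable_name(f, m) for f in factors for m in config.months]
            key = "+".join(factors)
            res = pca_combine(table[cols])
            pca[key] = res
            models[f"{key}:PC1"] = fit_linear_model(chron, res.scores[["PC1"]])
        else:
            var = group[0]
            factor = var.rsplit("_", 1)[0]
            tr = {var: config.transforms[factor]} if factor in config.transforms else None
            models[var] = fit_linear_model(chron, table[[var]], tr)
    return ScreenResult(records=records, groups=groups, pca=pca, models=models)
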