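"""The statistical battery: two-factor ANOVA, Pearson with Bonferroni,
2x2 chi-square, and multiple linear regression with standardized betas.

The two-factor ANOVA and chi-square statistics are computed from their
closed-form sums of squares so the algebraic contracts hold exactly
(SS_total = SS_A + SS_B + SS_residual; the 2x2 shortcut formula equals the
observed-vs-expected summation identically); distributions come from scipy
and the regression is ordinary least squares via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = ["StatsConfig", "AnovaResult", "two_factor_anova",
           "one_way_anova_p", "pearson_with_bonferroni", "chisq_2x2",
           "RegressionResult", "lv_rv_regression"]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    bonferroni_m: int = 16
    residual_bound: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.bonferroni_m


# ---------------------------------------------------------------------------
# two-factor ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Fixed-effects two-factor decomposition without interaction."""

    ss_a: float
    ss_b: float
    ss_error: float
    ss_total: float
    df_a: int
    df_b: int
    df_error: int
    f_a: float
    f_b: float
    p_a: float
    p_b: float
    factor_names: tuple[str, str] = ("sample", "resolution")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": list(self.factor_names) + ["residual"],
            "ss": [self.ss_a, self.ss_b, self.ss_error],
            "df": [self.df_a, self.df_b, self.df_error],
            "F": [self.f_a, self.f_b, np.nan],
            "p": [self.p_a, self.p_b, np.nan],
        })


def _f_p(ss: float, df: int, ss_e: float, df_e: int) -> tuple[float, float]:
    if df <= 0 or df_e <= 0:
        return float("nan"), float("nan")
    ms, ms_e = ss / df, ss_e / df_e
    if ms_e == 0.0:
        return (0.0, 1.0) if ms == 0.0 else (float("inf"), 0.0)
    f = ms / ms_e
    return f, float(sps.f.sf(f, df, df_e))


def two_factor_anova(table: np.ndarray | pd.DataFrame,
                     value: str = "value",
                     factor_a: str = "sample",
                     factor_b: str = "resolution",
                     average_replicates: bool = True) -> AnovaResult:
    """Two-factor fixed-effects ANOVA without interaction.

    ``table`` is either a complete (a x b) array of one observation per cell
    or a long-form DataFrame with columns ``value``, ``factor_a`` and
    ``factor_b``.  Replicated cells (e.g. multiple trajectories per sample
    and resolution) are averaged per cell by default; with
    ``average_replicates=False`` they enter as replicates of a balanced
    no-interaction model (the interaction is pooled into the residual).
    Missing cells are rejected.
    """
    if isinstance(table, pd.DataFrame):
        counts = table.groupby([factor_a, factor_b])[value].count().unstack()
        if counts.isna().any().any() or (counts == 0).any().any():
            raise ValueError("missing cells: the design must be complete")
        if average_replicates:
            arr = table.groupby([factor_a, factor_b])[value].mean() \
                       .unstack().to_numpy(dtype=float)[:, :, None]
        else:
            r = int(counts.iloc[0, 0])
            if not (counts == r).all().all():
                raise ValueError("unbalanced replication")
            wide = table.sort_values([factor_a, factor_b]) \
                        .groupby([factor_a, factor_b])[value] \
                        .apply(lambda s: s.to_numpy(dtype=float))
            arr = np.stack([np.stack(wide.loc[a].to_numpy())
                            for a in counts.index])
        names = (factor_a, factor_b)
    else:
        arr = np.asarray(table, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("array input must be (a, b) or (a, b, r)")
        if np.isnan(arr).any():
            raise ValueError("missing cells: the design must be complete")
        names = (factor_a, factor_b)

    a, b, r = arr.shape
    grand = arr.mean()
    ss_total = float(((arr - grand) ** 2).sum())
    ss_a = float(b * r * ((arr.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_b = float(a * r * ((arr.mean(axis=(0, 2)) - grand) ** 2).sum())
    ss_e = ss_total - ss_a - ss_b
    df_a, df_b = a - 1, b - 1
    df_e = a * b * r - 1 - df_a - df_b
    f_a, p_a = _f_p(ss_a, df_a, ss_e, df_e)
    f_b, p_b = _f_p(ss_b, df_b, ss_e, df_e)
    return AnovaResult(ss_a=ss_a, ss_b=ss_b, ss_error=max(ss_e, 0.0),
                       ss_total=ss_total, df_a=df_a, df_b=df_b, df_error=df_e,
                       f_a=f_a, f_b=f_b, p_a=p_a, p_b=p_b, factor_names=names)


def one_way_anova_p(groups: list[np.ndarray]) -> float:
    """One-way ANOVA p across groups (used for the cohort group table)."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return 1.0
    stat, p = sps.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


# ---------------------------------------------------------------------------
# Pearson with Bonferroni
# ---------------------------------------------------------------------------

def pearson_with_bonferroni(pairs: dict[int, tuple[np.ndarray, np.ndarray]],
                            config: StatsConfig = StatsConfig()
                            ) -> pd.DataFrame:
    """Per-segment Pearson correlations with a Bonferroni-corrected
    significance flag (p < alpha / m).

    ``pairs`` maps a segment id to its paired (x, y) vectors (>= 3 pairs
    each).  Zero-variance inputs are rejected.
    """
    rows = []
    thr = config.bonferroni_threshold
    for seg, (x, y) in sorted(pairs.items()):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3 or len(x) != len(y):
            raise ValueError(f"segment {seg}: need >= 3 paired observations")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"segment {seg}: zero-variance input")
        r, p = sps.pearsonr(x, y)
        rows.append({"segment": seg, "r": float(r), "p": float(p),
                     "significant": bool(p < thr)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2x2 chi-square
# ---------------------------------------------------------------------------

def chisq_2x2(a: int, b: int, c: int, d: int,
              correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]].

    Computed by the shortcut formula N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),
    which equals the observed-vs-expected summation identically.  The Yates
    continuity-corrected variant is available by flag; it is not the default
    because the correction changes the statistic substantially for sparse
    tables.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined with an empty margin")
    det = a * d - b * c
    if correction:
        det = max(abs(det) - n / 2.0, 0.0)
    stat = n * float(det) ** 2 / float(np.prod([float(m) for m in margins]))
    return stat, float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# LV-RV regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    adjusted_R2: float
    R2: float
    overall_p: float
    betas: dict[str, float]
    standardized_betas: dict[str, float]
    p_values: dict[str, float]
    residual_range: tuple[float, float]
    residuals_within_bound: bool
    normality_p: float                 # Shapiro-Wilk on the dependent variable
    collinear: bool
    n: int

    def summary(self) -> pd.DataFrame:
        rows = [{"predictor": k, "beta": self.betas[k],
                 "st_beta": self.standardized_betas[k],
                 "p": self.p_values[k]} for k in self.betas]
        return pd.DataFrame(rows)


def lv_rv_regression(volumes: pd.DataFrame,
                     dependent: str = "lv_trab",
                     predictors: tuple[str, ...] = ("lv_compact", "rv_trab",
                                                    "rv_compact"),
                     config: StatsConfig = StatsConfig()) -> RegressionResult:
    """OLS of LV trabecular volume on LV compact, RV trabecular and RV
    compact volumes, with standardized betas and a residual screen.

    The Shapiro-Wilk normality p of the dependent variable is always
    reported; the regression proceeds regardless (the normality check is a
    reported gate, not a hard stop).  Standardized betas are
    beta * sd(x) / sd(y); standardized residuals are checked against the
    configured bound (default +/-3).
    """
    df = volumes
    n = len(df)
    if n < len(predictors) + 2:
        raise ValueError("need at least predictors + 2 observations")
    y = df[dependent].to_numpy(dtype=float)
    X = df[list(predictors)].to_numpy(dtype=float)

    shapiro_p = float(sps.shapiro(y).pvalue)
    model = sm.OLS(y, sm.add_constant(X))
    res = model.fit()

    sd_y = y.std(ddof=1)
    betas = dict(zip(predictors, res.params[1:]))
    st_betas = {k: float(b * X[:, i].std(ddof=1) / sd_y)
                for i, (k, b) in enumerate(betas.items())}
    pvals = dict(zip(predictors, (float(p) for p in res.pvalues[1:])))

    mse = float(res.mse_resid)
    std_resid = res.resid / np.sqrt(mse) if mse > 0 else res.resid * 0.0
    rng = (float(std_resid.min()), float(std_resid.max()))
    within = bool(max(abs(rng[0]), abs(rng[1])) <= config.residual_bound)
    collinear = bool(np.linalg.cond(sm.add_constant(X)) > 1e10)

    return RegressionResult(
        adjusted_R2=float(res.rsquared_adj), R2=float(res.rsquared),
        overall_p=float(res.f_pvalue),
        betas={k: float(v) for k, v in betas.items()},
        standardized_betas=st_betas, p_values=pvals,
        residual_range=rng, residuals_within_bound=within,
        normality_p=shapiro_p, collinear=collinear, n=n)
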