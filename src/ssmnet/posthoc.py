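"""Follow-up statistics: per-tract univariate regressions with FDR control
and block-wise hierarchical regressions of pattern expression on covariates.

Univariate models regress each tract's (log) metric on VO2max; p-values are
Benjamini-Hochberg adjusted across the tested tract family (by default the
tracts found reliable in the pattern, not all tracts). The block-wise models
follow the hierarchical scheme TIV | +age, sex | +vascular risk, APOE e4 |
+log WMH, reporting standardized and unstandardized coefficients, adjusted
R^2 and the model F per block. Standardized coefficients z-score binary
predictors exactly like continuous ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CovariateTable, MetricMatrix

DEFAULT_BLOCKS: tuple[tuple[str, ...], ...] = (
    ("tiv",),
    ("age", "sex"),
    ("vascular_risk_level", "apoe_e4"),
    ("wmh_log",),
)


@dataclass
class UnivariateResult:
    """Per-tract simple regressions of the metric on VO2max."""

    table: pd.DataFrame  # tract, beta_std, slope, slope_se, ci_lower, ci_upper, p_raw, p_fdr
    metric_name: str
    fdr_q: float = 0.05
    log_scale: bool = True

    @property
    def significant(self) -> pd.Series:
        return self.table["p_fdr"] < self.fdr_q


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def univariate_tract_regressions(matrix: MetricMatrix, vo2max: np.ndarray,
                                 tracts: list[str] | None = None,
                                 log_scale: bool = True,
                                 fdr_q: float = 0.05,
                                 ci_level: float = 0.95) -> UnivariateResult:
    """OLS of each tract's (log) metric value on VO2max, with BH correction
    across the tested subset.

    The FDR family is the ``tracts`` argument (default: every tract in the
    matrix); restrict it to the pattern's reliable tracts to mirror the
    follow-up analysis of a bootstrap-significant pattern.
    """
    if tracts is None:
        tracts = list(matrix.tract_labels)
    if len(tracts) == 0:
        raise ValueError("empty tract subset")
    missing = [t for t in tracts if t not in matrix.tract_labels]
    if missing:
        raise ValueError(f"unknown tracts: {missing}")
    cols = [matrix.tract_labels.index(t) for t in tracts]
    Y = matrix.values[:, cols]
    if log_scale:
        Y = np.log(Y)
    x = np.asarray(vo2max, dtype=float)
    n = len(x)

    # closed-form simple OLS per tract (outcome = tract value, predictor = VO2max)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = Y - Y.mean(axis=0)
    sxy = xc @ yc
    slope = sxy / sxx
    syy = (yc * yc).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
        rss = syy - slope * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = slope / se
    p_raw = 2 * stats.t.sf(np.abs(tstat), n - 2)
    tcrit = stats.t.ppf(1 - (1 - ci_level) / 2, n - 2)
    p_fdr = benjamini_hochberg(p_raw)

    table = pd.DataFrame({
        "tract": tracts,
        "beta_std": r,
        "slope": slope,
        "slope_se": se,
        "ci_lower": slope - tcrit * se,
        "ci_upper": slope + tcrit * se,
        "p_raw": p_raw,
        "p_fdr": p_fdr,
    }).set_index("tract")
    return UnivariateResult(table=table, metric_name=matrix.metric_name,
                            fdr_q=fdr_q, log_scale=log_scale)


@dataclass
class BlockFit:
    predictors: tuple[str, ...]
    coef_table: pd.DataFrame  # beta_std, B, SE, p per predictor
    r2: float
    adjusted_r2: float
    f_value: float
    f_pvalue: float
    nobs: int
    perfect_fit: bool = False


@dataclass
class BlockwiseResult:
    blocks: list[BlockFit]
    outcome_name: str = "pattern_expression"

    def block_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.blocks, start=1):
            for name, row in b.coef_table.iterrows():
                rows.append({"block": i, "predictor": name, **row.to_dict()})
            rows.append({"block": i, "predictor": "(adjusted R2)",
                         "B": b.adjusted_r2})
            rows.append({"block": i, "predictor": "(model F)",
                         "B": b.f_value, "p": b.f_pvalue})
        return pd.DataFrame(rows)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def blockwise_regression(expression: np.ndarray, covariates: CovariateTable,
                         blocks: tuple[tuple[str, ...], ...] = DEFAULT_BLOCKS,
                         outcome_name: str = "pattern_expression") -> BlockwiseResult:
    """Hierarchical OLS of pattern expression on accumulating covariate blocks.

    Complete-case analysis: rows missing any covariate used in the final
    block are dropped from every block so adjusted-R^2 comparisons share one
    sample.
    """
    y = np.asarray(expression, dtype=float)
    all_predictors: list[str] = []
    for b in blocks:
        all_predictors.extend(b)
    df = covariates.table[list(all_predictors)].astype(float)
    mask = ~(df.isna().any(axis=1) | ~np.isfinite(y))
    df = df.loc[mask.to_numpy()]
    y = y[mask.to_numpy()]
    n = len(y)
    if n < len(all_predictors) + 2:
        raise ValueError("too few complete cases for the largest block")

    def _z(a: np.ndarray) -> np.ndarray:
        sd = a.std(ddof=1)
        return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)

    results: list[BlockFit] = []
    cumulative: list[str] = []
    for block in blocks:
        cumulative = cumulative + list(block)
        X = df[cumulative].to_numpy()
        _check_full_rank(np.column_stack([np.ones(n), X]), ["const", *cumulative])
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        Xz = np.column_stack([_z(X[:, j]) for j in range(X.shape[1])])
        fitz = sm.OLS(_z(y), sm.add_constant(Xz)).fit()
        perfect = bool(fit.rsquared > 1 - 1e-12)
        coef = pd.DataFrame({
            "beta_std": fitz.params[1:],
            "B": fit.params[1:],
            "SE": fit.bse[1:],
            "p": fit.pvalues[1:],
        }, index=pd.Index(cumulative, name="predictor"))
        results.append(BlockFit(
            predictors=tuple(cumulative),
            coef_table=coef,
            r2=float(fit.rsquared),
            adjusted_r2=float(fit.rsquared_adj),
            f_value=float("inf") if perfect else float(fit.fvalue),
            f_pvalue=0.0 if perfect else float(fit.f_pvalue),
            nobs=n,
            perfect_fit=perfect,
        ))
    return BlockwiseResult(blocks=results, outcome_name=outcome_name)
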