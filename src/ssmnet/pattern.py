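"""BIC selection of leading components and the combined fitness pattern.

Candidate models are the *nested leading* component sets 1..k (not arbitrary
subsets): for each k, VO2max is regressed on the first k SSM subject-score
columns with an intercept and scored by the Gaussian-likelihood BIC

    BIC(k) = n * ln(RSS_k / n) + (k + 1) * ln(n),

with the intercept counted in the parameter total and ties broken toward the
smaller k. The selected components are then linearly combined with their
regression coefficients into a single regional pattern w = sum_c b_c v_c
whose per-participant expression is z-scored and sign-oriented so that
higher expression corresponds to higher fitness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ssm import SSMDecomposition


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def bic_select(scores: np.ndarray, vo2max: np.ndarray,
               k_max: int | None = None) -> tuple[int, np.ndarray]:
    """Choose the number of leading components by BIC.

    Returns ``(k_star, bic_trace)`` where ``bic_trace[k-1]`` is BIC(k).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(vo2max, dtype=float)
    n, n_comp = scores.shape
    if k_max is None:
        k_max = min(15, n_comp)
    if k_max > n_comp:
        raise ValueError(f"k_max={k_max} exceeds available components ({n_comp})")
    if n <= k_max + 2:
        raise ValueError("too few participants for the requested k_max")
    if np.std(y) == 0:
        raise ValueError("VO2max is constant: no variance to model")

    bic = np.empty(k_max)
    for k in range(1, k_max + 1):
        X = np.column_stack([np.ones(n), scores[:, :k]])
        _, rss = _ols_rss(y, X)
        with np.errstate(divide="ignore"):
            bic[k - 1] = n * np.log(rss / n) + (k + 1) * np.log(n)
    k_star = int(np.argmin(bic)) + 1  # argmin takes the first (smallest k) on ties
    return k_star, bic


@dataclass
class PatternFit:
    """Fit of VO2max on the z-scored pattern expression (simple regression)."""

    standardized_beta: float
    r2: float
    adjusted_r2: float
    p_value: float
    n: int
    adjusted_r2_change_after_tiv: float | None = None


@dataclass
class CombinedPattern:
    """BIC-selected linear combination of SSM components."""

    k: int
    combination_weights: np.ndarray     # b_1..b_k (VO2max units per score unit)
    combined_loadings: np.ndarray       # w = sum b_c v_c, raw scale
    combined_loadings_unit: np.ndarray  # w / ||w||, the plotted scale
    expression_scores: np.ndarray       # z-scored, oriented with VO2max
    expression_raw: np.ndarray
    fit: PatternFit
    bic_trace: np.ndarray | None = None
    tract_labels: list[str] | None = None
    participant_ids: list[str] | None = None

    def loadings_frame(self) -> pd.DataFrame:
        idx = self.tract_labels if self.tract_labels is not None else None
        return pd.DataFrame(
            {"loading": self.combined_loadings,
             "loading_unit": self.combined_loadings_unit},
            index=pd.Index(idx, name="tract") if idx is not None else None)


def _simple_fit(expression_z: np.ndarray, vo2max: np.ndarray) -> PatternFit:
    n = len(vo2max)
    r = float(np.corrcoef(expression_z, vo2max)[0, 1])
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if 1.0 - r2 < 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return PatternFit(standardized_beta=r, r2=r2, adjusted_r2=adj, p_value=p, n=n)


def combine_pattern(decomposition: SSMDecomposition, k: int,
                    vo2max: np.ndarray,
                    bic_trace: np.ndarray | None = None) -> CombinedPattern:
    """Combine the first k components into one regional pattern.

    The combination weights are the OLS coefficients of VO2max on the first
    k score columns; loadings and expression are negated jointly if the raw
    expression correlates negatively with VO2max, so that higher expression
    always means higher fitness.
    """
    if not (1 <= k <= decomposition.n_components):
        raise ValueError(
            f"k={k} outside available components (1..{decomposition.n_components})")
    y = np.asarray(vo2max, dtype=float)
    n = len(y)
    scores = decomposition.scores[:, :k]
    X = np.column_stack([np.ones(n), scores])
    coef, _ = _ols_rss(y, X)
    b = coef[1:]
    w = decomposition.loadings[:, :k] @ b
    e = scores @ b
    sd = e.std(ddof=1)
    if sd == 0 or np.linalg.norm(w) == 0:
        raise ValueError("degenerate pattern: combined expression has no variance")
    r = float(np.corrcoef(e, y)[0, 1])
    if r < 0:
        b, w, e = -b, -w, -e
    expression_z = (e - e.mean()) / sd
    fit = _simple_fit(expression_z, y)
    return CombinedPattern(
        k=k,
        combination_weights=b,
        combined_loadings=w,
        combined_loadings_unit=w / np.linalg.norm(w),
        expression_scores=expression_z,
        expression_raw=e,
        fit=fit,
        bic_trace=bic_trace,
        tract_labels=decomposition.tract_labels,
        participant_ids=decomposition.participant_ids,
    )


@dataclass
class TivAdjustedFit:
    """Hierarchical fit: VO2max ~ TIV, then VO2max ~ TIV + pattern expression."""

    standardized_beta: float
    p_value: float
    adjusted_r2_block1: float
    adjusted_r2_block2: float
    adjusted_r2_change: float
    degenerate: bool = False


def tiv_adjusted_fit(expression_scores: np.ndarray, vo2max: np.ndarray,
                     tiv: np.ndarray) -> TivAdjustedFit:
    """Association of pattern expression with VO2max after adjusting for TIV.

    Reports the standardized beta of expression in the two-predictor model
    and the adjusted-R^2 change between the TIV-only and TIV+expression
    blocks.
    """
    import statsmodels.api as sm

    e = np.asarray(expression_scores, dtype=float)
    y = np.asarray(vo2max, dtype=float)
    t = np.asarray(tiv, dtype=float)
    if not (len(e) == len(y) == len(t)):
        raise ValueError("expression, VO2max and TIV must be aligned")

    degenerate = False
    if t.std() == 0 or abs(np.corrcoef(t, e)[0, 1]) > 0.999:
        degenerate = True
        warnings.warn("TIV is (nearly) collinear with pattern expression; "
                      "the partial coefficient is ill-determined", stacklevel=2)

    m1 = sm.OLS(y, sm.add_constant(t)).fit()
    X2 = sm.add_constant(np.column_stack([t, e]))
    m2 = sm.OLS(y, X2).fit()

    def _z(x):
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    mz = sm.OLS(_z(y), sm.add_constant(np.column_stack([_z(t), _z(e)]))).fit()
    return TivAdjustedFit(
        standardized_beta=float(mz.params[2]),
        p_value=float(m2.pvalues[2]),
        adjusted_r2_block1=float(m1.rsquared_adj),
        adjusted_r2_block2=float(m2.rsquared_adj),
        adjusted_r2_change=float(m2.rsquared_adj - m1.rsquared_adj),
        degenerate=degenerate,
    )
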