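"""Model/Results interface over the SSM fitness-pattern analysis.

:class:`SSMPatternModel` is constructed from one metric's participant x
tract matrix and the fitness covariate; ``fit()`` performs the log +
double-centering, the PCA, the BIC selection over nested leading components
and the pattern combination, returning an :class:`SSMPatternResults` that
carries the estimates and exposes the follow-up analyses (TIV adjustment,
bootstrap reliability, per-tract univariate regressions, block-wise
covariate regressions) and a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bootstrap as _bootstrap
from . import posthoc as _posthoc
from .data import CovariateTable, MetricMatrix
from .pattern import CombinedPattern, TivAdjustedFit, bic_select, combine_pattern, tiv_adjusted_fit
from .ssm import SSMDecomposition, decompose, log_double_center


class SSMPatternModel:
    """Scaled Subprofile Model pattern regression for one diffusion metric.

    Parameters
    ----------
    metric
        Participant x tract matrix of one strictly positive metric.
    vo2max
        Fitness covariate (ml/kg/min), aligned to participants; taken from
        ``covariates`` when omitted.
    covariates
        Optional covariate table (required for the TIV-adjusted and
        block-wise analyses).
    k_max
        Largest candidate number of leading components (default
        ``min(15, rank)``).
    """

    def __init__(self, metric: MetricMatrix, vo2max: np.ndarray | None = None,
                 covariates: CovariateTable | None = None,
                 k_max: int | None = None):
        if covariates is not None:
            covariates = covariates.aligned_to(metric.participant_ids)
        if vo2max is None:
            if covariates is None:
                raise ValueError("supply vo2max directly or via covariates")
            vo2max = covariates.vo2max
        vo2max = np.asarray(vo2max, dtype=float)
        if len(vo2max) != metric.n_participants:
            raise ValueError("vo2max is not aligned to the metric matrix")
        self.metric = metric
        self.vo2max = vo2max
        self.covariates = covariates
        self.k_max = k_max

    @classmethod
    def from_dataframe(cls, metric_df: pd.DataFrame, metric_name: str,
                       covariates: CovariateTable | None = None,
                       vo2max: np.ndarray | None = None,
                       **kwargs) -> "SSMPatternModel":
        metric = MetricMatrix.from_dataframe(metric_df, metric_name)
        return cls(metric, vo2max=vo2max, covariates=covariates, **kwargs)

    def fit(self, k: int | None = None) -> "SSMPatternResults":
        """Run the decomposition and (unless ``k`` is forced) BIC selection."""
        C, offsets = log_double_center(self.metric)
        dec = decompose(C, offsets=offsets,
                        tract_labels=list(self.metric.tract_labels),
                        participant_ids=list(self.metric.participant_ids))
        if dec.n_components == 0:
            raise ValueError("centered matrix is identically zero; no components")
        bic_trace = None
        if k is None:
            k_max = self.k_max if self.k_max is not None else min(15, dec.n_components)
            k_max = min(k_max, dec.n_components)
            k, bic_trace = bic_select(dec.scores, self.vo2max, k_max=k_max)
        pattern = combine_pattern(dec, k, self.vo2max, bic_trace=bic_trace)
        return SSMPatternResults(self, dec, pattern)


class SSMPatternResults:
    """Fitted fitness-related covariance pattern for one metric."""

    def __init__(self, model: SSMPatternModel, decomposition: SSMDecomposition,
                 pattern: CombinedPattern):
        self.model = model
        self.decomposition = decomposition
        self.pattern = pattern
        self._tiv_fit: TivAdjustedFit | None = None

    # -- convenience accessors -------------------------------------------------
    @property
    def k(self) -> int:
        return self.pattern.k

    @property
    def bic_trace(self) -> np.ndarray | None:
        return self.pattern.bic_trace

    @property
    def combined_loadings(self) -> np.ndarray:
        return self.pattern.combined_loadings

    @property
    def expression_scores(self) -> np.ndarray:
        return self.pattern.expression_scores

    @property
    def standardized_beta(self) -> float:
        return self.pattern.fit.standardized_beta

    @property
    def adjusted_r2(self) -> float:
        return self.pattern.fit.adjusted_r2

    @property
    def pvalue(self) -> float:
        return self.pattern.fit.p_value

    # -- follow-up analyses ----------------------------------------------------
    def tiv_adjusted_fit(self, tiv: np.ndarray | None = None) -> TivAdjustedFit:
        if tiv is None:
            if self.model.covariates is None:
                raise ValueError("no covariate table: pass tiv explicitly")
            tiv = self.model.covariates["tiv"]
        res = tiv_adjusted_fit(self.pattern.expression_scores, self.model.vo2max, tiv)
        self._tiv_fit = res
        self.pattern.fit.adjusted_r2_change_after_tiv = res.adjusted_r2_change
        return res

    def bootstrap_loadings(self, n_iterations: int = 10_000, seed: int = 0,
                           **kwargs) -> _bootstrap.BootstrapReliability:
        return _bootstrap.bootstrap_loadings(
            self.model.metric, self.model.vo2max, self.k,
            n_iterations=n_iterations, seed=seed, **kwargs)

    def univariate_tract_regressions(self, tracts: list[str] | None = None,
                                     **kwargs) -> _posthoc.UnivariateResult:
        return _posthoc.univariate_tract_regressions(
            self.model.metric, self.model.vo2max, tracts=tracts, **kwargs)

    def blockwise_regression(self, blocks=_posthoc.DEFAULT_BLOCKS,
                             covariates: CovariateTable | None = None,
                             ) -> _posthoc.BlockwiseResult:
        cov = covariates if covariates is not None else self.model.covariates
        if cov is None:
            raise ValueError("no covariate table available")
        cov = cov.aligned_to(self.model.metric.participant_ids)
        return _posthoc.blockwise_regression(
            self.pattern.expression_scores, cov, blocks=blocks,
            outcome_name=f"{self.model.metric.metric_name} pattern expression")

    def plot_loadings(self, reliability=None, ax=None):
        from .plotting import plot_loadings
        rel = reliability
        return plot_loadings(
            tract_labels=self.model.metric.tract_labels,
            loadings=(rel.point_estimate if rel is not None
                      else self.pattern.combined_loadings_unit),
            reliability=rel, ax=ax,
            title=f"{self.model.metric.metric_name} fitness-related pattern")

    # -- reporting ---------------------------------------------------------------
    def summary(self) -> str:
        f = self.pattern.fit
        m = self.model.metric
        lines = [
            f"SSM fitness-pattern results: {m.metric_name}",
            "=" * 46,
            f"participants:            {m.n_participants}",
            f"tracts:                  {m.n_tracts}",
            f"components available:    {self.decomposition.n_components}",
            f"selected k (BIC):        {self.k}",
            f"standardized beta:       {f.standardized_beta: .3f}",
            f"R^2:                     {f.r2: .3f}",
            f"adjusted R^2:            {f.adjusted_r2: .3f}",
            f"p-value:                 {f.p_value: .3e}",
        ]
        if self._tiv_fit is not None:
            t = self._tiv_fit
            lines += [
                f"TIV-adjusted beta:       {t.standardized_beta: .3f}",
                f"adj. R^2 change (TIV):   {t.adjusted_r2_change: .3f}",
                f"TIV-adjusted p:          {t.p_value: .3e}",
            ]
        if self.bic_trace is not None:
            trace = ", ".join(f"{b:.1f}" for b in self.bic_trace)
            lines.append(f"BIC trace (k=1..{len(self.bic_trace)}): {trace}")
        return "\n".join(lines)
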