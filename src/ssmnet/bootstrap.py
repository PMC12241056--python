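"""Bootstrap reliability of combined-pattern tract loadings.

Participants are resampled with replacement; for each replicate the full
log -> double-center -> PCA -> combine chain is re-run with the number of
components k *frozen* at the full-sample selection (the bootstrap quantifies
the reliability of the observed pattern, not model-selection variance).
Because PCA loadings are sign-indeterminate, each replicate's combined
loading vector is aligned to the full-sample point estimate by negation when
their correlation is negative; per-tract percentile confidence intervals are
then read off the aligned replicates.

Loadings are compared on the unit-norm scale by default (``scale="unit"``),
the scale on which the pattern is plotted; ``scale="raw"`` keeps the
regression-weighted combination, whose overall magnitude varies with the
replicate fit.

The per-replicate recomputation uses an eigendecomposition of the small
tracts x tracts cross-product matrix plus the closed-form OLS solution on
orthogonal score columns; this is algebraically identical to the SVD route
used by :func:`ssmnet.ssm.decompose` (and is tested against it) but much
faster inside the resampling loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data import MetricMatrix
from .pattern import combine_pattern
from .ssm import decompose, log_double_center


@dataclass
class BootstrapReliability:
    n_iterations: int
    point_estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    significant: np.ndarray
    n_degenerate: int
    seed: int
    ci_level: float = 0.95
    scale: str = "unit"
    ci_method: str = "percentile"
    tract_labels: list[str] | None = None
    replicate_loadings: np.ndarray | None = None  # (n_iterations, n_tracts), NaN rows degenerate

    def to_frame(self) -> pd.DataFrame:
        idx = (pd.Index(self.tract_labels, name="tract")
               if self.tract_labels is not None else None)
        return pd.DataFrame(
            {"loading": self.point_estimate,
             "ci_lower": self.ci_lower,
             "ci_upper": self.ci_upper,
             "significant": self.significant},
            index=idx)


def _double_center(L: np.ndarray) -> np.ndarray:
    return (L - L.mean(axis=1, keepdims=True)
            - L.mean(axis=0, keepdims=True) + L.mean())


def _combined_loading_fast(C: np.ndarray, y: np.ndarray, k: int) -> np.ndarray | None:
    """Combined loading vector from a centered matrix via eigh of C'C.

    Returns None when the decomposition has rank < k. Uses the fact that PCA
    score columns are exactly orthogonal with zero mean, so the OLS
    coefficients of y on the first k scores are s_c'y / s_c's_c.
    """
    n, p = C.shape
    G = C.T @ C
    evals, evecs = linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    tol = max(n, p) * np.finfo(float).eps * max(evals[0], 0.0)
    rank = int(np.sum(evals > tol))
    rank = min(rank, n - 1, p - 1)
    if rank < k:
        return None
    V = evecs[:, order[:k]]
    scores = C @ V
    ss = (scores * scores).sum(axis=0)
    b = (scores.T @ y) / ss
    return V @ b


def _bca_bounds(reps: np.ndarray, point: np.ndarray, jack: np.ndarray,
                alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Bias-corrected and accelerated percentile bounds per tract."""
    from scipy.stats import norm

    n_ok = np.sum(~np.isnan(reps[:, 0]))
    prop = np.nanmean(reps < point[None, :], axis=0)
    z0 = norm.ppf(np.clip(prop, 1.0 / (n_ok + 1), n_ok / (n_ok + 1)))
    jm = jack.mean(axis=0)
    d = jm[None, :] - jack
    accel = (d ** 3).sum(axis=0) / (6.0 * ((d ** 2).sum(axis=0)) ** 1.5 + 1e-300)
    lo = np.empty(point.shape)
    hi = np.empty(point.shape)
    for z_alpha, out in ((norm.ppf(alpha), lo), (norm.ppf(1 - alpha), hi)):
        adj = norm.cdf(z0 + (z0 + z_alpha) / (1 - accel * (z0 + z_alpha)))
        for j in range(len(point)):
            out[j] = np.nanpercentile(reps[:, j], 100 * adj[j])
    return lo, hi


def bootstrap_loadings(matrix: MetricMatrix, vo2max: np.ndarray, k: int,
                       n_iterations: int = 10_000, seed: int = 0,
                       ci_level: float = 0.95, scale: str = "unit",
                       ci_method: str = "percentile",
                       orient_reference: np.ndarray | None = None,
                       keep_replicates: bool = False) -> BootstrapReliability:
    """Bootstrap CIs for each tract's combined-pattern loading.

    Parameters
    ----------
    matrix, vo2max
        Full-sample inputs; participants are the resampling unit.
    k
        Number of leading components, frozen at the full-sample selection.
    ci_method
        ``"percentile"`` (default) or ``"bca"`` (bias-corrected and
        accelerated, with jackknife-estimated acceleration).
    orient_reference
        Loading vector used for sign alignment (default: the full-sample
        point estimate).
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be at least 100")
    if scale not in ("unit", "raw"):
        raise ValueError("scale must be 'unit' or 'raw'")
    if ci_method not in ("percentile", "bca"):
        raise ValueError("ci_method must be 'percentile' or 'bca'")
    y = np.asarray(vo2max, dtype=float)
    n, p = matrix.values.shape
    if len(y) != n:
        raise ValueError("vo2max not aligned to participants")
    if n < k + 3:
        raise ValueError(f"n={n} too small for k={k} components")

    # full-sample point estimate via the reference (SVD) route
    C_full, _ = log_double_center(matrix)
    dec = decompose(C_full, tract_labels=list(matrix.tract_labels))
    pattern = combine_pattern(dec, k, y)
    point = (pattern.combined_loadings_unit if scale == "unit"
             else pattern.combined_loadings)
    reference = point if orient_reference is None else np.asarray(orient_reference, float)

    L = np.log(matrix.values)
    rng = np.random.default_rng(seed)
    reps = np.full((n_iterations, p), np.nan)
    n_degenerate = 0
    ref_c = reference - reference.mean()
    for it in range(n_iterations):
        idx = rng.integers(0, n, n)
        C = _double_center(L[idx])
        yb = y[idx]
        if yb.std() == 0:
            n_degenerate += 1
            continue
        w = _combined_loading_fast(C, yb, k)
        if w is None:
            n_degenerate += 1
            continue
        norm = np.linalg.norm(w)
        if norm == 0:
            n_degenerate += 1
            continue
        # sign alignment against the reference pattern
        wc = w - w.mean()
        if wc @ ref_c < 0:
            w = -w
        if scale == "unit":
            w = w / norm
        reps[it] = w

    if n_degenerate == n_iterations:
        raise RuntimeError("all bootstrap replicates were degenerate")
    frac = n_degenerate / n_iterations
    if frac > 0.01:
        warnings.warn(f"{frac:.1%} of bootstrap replicates were degenerate "
                      "(rank below k); CIs may be unreliable", stacklevel=2)

    alpha = (1.0 - ci_level) / 2.0
    if ci_method == "bca":
        # jackknife leave-one-out loadings for the acceleration term
        jack = np.empty((n, p))
        keep = np.arange(n)
        for i in range(n):
            rows = np.delete(keep, i)
            w = _combined_loading_fast(_double_center(L[rows]), y[rows], k)
            if w is None:
                w = point.copy()
            else:
                if (w - w.mean()) @ ref_c < 0:
                    w = -w
                if scale == "unit":
                    w = w / np.linalg.norm(w)
            jack[i] = w
        lo, hi = _bca_bounds(reps, point, jack, alpha)
    else:
        lo = np.nanpercentile(reps, 100 * alpha, axis=0)
        hi = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
    significant = (lo > 0) | (hi < 0)
    return BootstrapReliability(
        n_iterations=n_iterations,
        point_estimate=point,
        ci_lower=lo,
        ci_upper=hi,
        significant=significant,
        n_degenerate=n_degenerate,
        seed=seed,
        ci_level=ci_level,
        scale=scale,
        ci_method=ci_method,
        tract_labels=list(matrix.tract_labels),
        replicate_loadings=reps if keep_replicates else None,
    )
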