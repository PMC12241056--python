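"""End-to-end orchestration: QC -> SSM -> selection -> bootstrap -> post-hoc
for each metric, with delimited-text reports and a reproducibility manifest.

All randomness flows from a single root seed, split deterministically per
metric and stage, so a re-run with the same configuration and inputs
produces byte-identical report files (the manifest additionally records a
timestamp and file checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data import CovariateTable, MetricMatrix, check_alignment
from .model import SSMPatternModel
from .posthoc import DEFAULT_BLOCKS
from .qc import apply_exclusions, qc_flag_extremes

logger = logging.getLogger("ssmnet")


@dataclass
class RunConfig:
    metric_paths: dict  # metric name -> delimited-text path
    covariate_path: str
    output_dir: str
    k_max: int | None = None
    n_iterations: int = 10_000
    ci_level: float = 0.95
    fdr_q: float = 0.05
    seed: int = 0
    blocks: tuple = DEFAULT_BLOCKS
    qc_multiplier: float = 3.0
    qc_axis: str = "participants"
    univariate_log_scale: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be at least 100")
        self.blocks = tuple(tuple(b) for b in self.blocks)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = [list(b) for b in self.blocks]
        return d


def _stage_seed(root: int, metric_index: int) -> int:
    ss = np.random.SeedSequence(entropy=root, spawn_key=(metric_index,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class MetricRunResult:
    metric_name: str
    results: object                      # SSMPatternResults
    tiv_fit: object
    reliability: object
    univariate: object | None
    blockwise: object


@dataclass
class PipelineResult:
    qc_report: object
    per_metric: dict
    output_dir: Path | None = None


def run_study(matrices: dict[str, MetricMatrix], covariates: CovariateTable,
              config: RunConfig, output_dir: Path | None = None) -> PipelineResult:
    """Run the full analysis on in-memory inputs; write reports if asked."""
    check_alignment(matrices)
    ref = next(iter(matrices.values()))
    covariates = covariates.aligned_to(ref.participant_ids)

    logger.info("QC: %d participants, %d tracts, %d metrics",
                ref.n_participants, ref.n_tracts, len(matrices))
    qc_report = qc_flag_extremes(matrices, multiplier=config.qc_multiplier,
                                 axis=config.qc_axis)
    logger.info("QC: %d flagged cells, %d excluded, %d retained",
                len(qc_report.flagged_cells),
                len(qc_report.excluded_participants), qc_report.retained_n)
    matrices = apply_exclusions(matrices, qc_report)
    ref = next(iter(matrices.values()))
    covariates = covariates.aligned_to(ref.participant_ids)

    per_metric: dict[str, MetricRunResult] = {}
    for i, (name, matrix) in enumerate(matrices.items()):
        logger.info("[%s] decomposition + BIC selection", name)
        model = SSMPatternModel(matrix, covariates=covariates, k_max=config.k_max)
        res = model.fit()
        logger.info("[%s] k=%d beta=%.3f adjR2=%.3f", name, res.k,
                    res.standardized_beta, res.adjusted_r2)
        tiv_fit = res.tiv_adjusted_fit()
        seed = _stage_seed(config.seed, i)
        rel = res.bootstrap_loadings(n_iterations=config.n_iterations,
                                     seed=seed, ci_level=config.ci_level)
        sig_tracts = [t for t, s in zip(matrix.tract_labels, rel.significant) if s]
        logger.info("[%s] bootstrap: %d/%d significant tracts, %d degenerate",
                    name, len(sig_tracts), matrix.n_tracts, rel.n_degenerate)
        # follow-up univariate models on the pattern's reliable tracts; fall
        # back to the full tract family when no tract is reliable
        uni = res.univariate_tract_regressions(
            tracts=sig_tracts or None,
            log_scale=config.univariate_log_scale, fdr_q=config.fdr_q)
        blockwise = res.blockwise_regression(blocks=config.blocks)
        per_metric[name] = MetricRunResult(
            metric_name=name, results=res, tiv_fit=tiv_fit,
            reliability=rel, univariate=uni, blockwise=blockwise)

    result = PipelineResult(qc_report=qc_report, per_metric=per_metric,
                            output_dir=output_dir)
    if output_dir is not None:
        _write_reports(result, covariates, config, Path(output_dir))
    return result


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read inputs from the configured paths and run :func:`run_study`."""
    matrices = {name: MetricMatrix.read_csv(path, metric_name=name)
                for name, path in config.metric_paths.items()}
    covariates = CovariateTable.read_csv(config.covariate_path)
    check_alignment(matrices, covariates.aligned_to(
        next(iter(matrices.values())).participant_ids))
    return run_study(matrices, covariates, config, output_dir=Path(config.output_dir))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_reports(result: PipelineResult, covariates: CovariateTable,
                   config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    qc = result.qc_report
    qc.flags_frame().to_csv(out / "qc_flags.csv", index=False)
    qc.exclusions_frame().to_csv(out / "qc_exclusions.csv", index=False)
    written += [out / "qc_flags.csv", out / "qc_exclusions.csv"]

    for name, mr in result.per_metric.items():
        d = out / name
        d.mkdir(exist_ok=True)
        res = mr.results
        rel = mr.reliability

        loadings = res.pattern.loadings_frame()
        rel_frame = rel.to_frame()
        loadings["ci_lower"] = rel_frame["ci_lower"].to_numpy()
        loadings["ci_upper"] = rel_frame["ci_upper"].to_numpy()
        loadings["significant"] = rel_frame["significant"].to_numpy()
        loadings.to_csv(d / "pattern_loadings.csv")

        import pandas as pd
        pd.DataFrame({
            "participant_id": res.model.metric.participant_ids,
            "expression": res.expression_scores,
            "vo2max": res.model.vo2max,
        }).to_csv(d / "pattern_expression.csv", index=False)

        pd.DataFrame({
            "component": np.arange(1, res.decomposition.n_components + 1),
            "eigenvalue": res.decomposition.eigenvalues,
            "explained_variance_ratio": res.decomposition.explained_variance_ratio,
        }).to_csv(d / "eigenvalues.csv", index=False)

        fit = res.pattern.fit
        tiv = mr.tiv_fit
        fit_summary = {
            "metric": name,
            "n": int(fit.n),
            "k": int(res.k),
            "bic_trace": [float(b) for b in (res.bic_trace if res.bic_trace is not None else [])],
            "standardized_beta": float(fit.standardized_beta),
            "r2": float(fit.r2),
            "adjusted_r2": float(fit.adjusted_r2),
            "p_value": float(fit.p_value),
            "tiv_adjusted_beta": float(tiv.standardized_beta),
            "tiv_adjusted_p": float(tiv.p_value),
            "adjusted_r2_change_after_tiv": float(tiv.adjusted_r2_change),
            "bootstrap": {
                "n_iterations": int(rel.n_iterations),
                "seed": int(rel.seed),
                "ci_level": float(rel.ci_level),
                "scale": rel.scale,
                "resampling_unit": "participants",
                "ci_flavor": rel.ci_method,
                "n_degenerate": int(rel.n_degenerate),
                "n_significant_tracts": int(np.sum(rel.significant)),
            },
        }
        with open(d / "fit_summary.yaml", "w") as fh:
            yaml.safe_dump(fit_summary, fh, sort_keys=False)

        if mr.univariate is not None:
            mr.univariate.table.to_csv(d / "univariate.csv")
        mr.blockwise.block_frame().to_csv(d / "blockwise.csv", index=False)
        (d / "summary.txt").write_text(res.summary() + "\n")
        written += [d / "pattern_loadings.csv", d / "pattern_expression.csv",
                    d / "eigenvalues.csv", d / "fit_summary.yaml",
                    d / "blockwise.csv", d / "summary.txt"]
        if mr.univariate is not None:
            written.append(d / "univariate.csv")

        if config.make_plots:
            import matplotlib.pyplot as plt
            from .plotting import plot_expression_scatter, plot_loadings
            ax = plot_loadings(res.model.metric.tract_labels, rel.point_estimate,
                               reliability=rel,
                               title=f"{name} fitness-related pattern")
            ax.figure.savefig(d / "loadings.png", dpi=150)
            plt.close(ax.figure)
            ax = plot_expression_scatter(res.expression_scores, res.model.vo2max,
                                         adjusted_r2=fit.adjusted_r2,
                                         p_value=fit.p_value,
                                         title=f"{name} pattern expression vs VO2max")
            ax.figure.savefig(d / "expression_scatter.png", dpi=150)
            plt.close(ax.figure)

    import pandas
    import scipy
    import statsmodels
    manifest = {
        "config": config.to_dict(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "ssmnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "qc": {
            "input_n": int(qc.input_n),
            "retained_n": int(qc.retained_n),
            "excluded": {p: rules for p, rules in qc.excluded_participants.items()},
        },
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
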