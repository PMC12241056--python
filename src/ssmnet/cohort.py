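"""Synthetic cohort generator with planted covariance patterns.

The generator emulates the statistical structure the SSM analysis assumes in
a cohort of healthy older adults: on the natural-log scale each metric value
is a per-tract baseline profile, plus a per-subject global scaling factor
(the nuisance the log + double-centering step exists to remove), plus one or
more planted regional covariance patterns with per-subject expression
scores, plus independent tract-level noise,

    ln(M[i, j]) = ln(baseline[j]) + g_i
                  + a * (sum_c s_ic * v_c[j] + noise_sd * eps_ij) .

Expression scores s_ic are standard normal (the planted signal SD is 1, so
``noise_sd`` is expressed in units of the expression SD); the amplitude
``a`` (``signal_amplitude``) converts that dimensionless block into
fractional metric variation and is statistically invisible downstream
(loadings, correlations, BIC and standardized coefficients are
scale-invariant) — it only controls how large the planted structure is
relative to the tract baselines, keeping raw values realistic for the
IQR-based quality control. VO2max is mixed
against the standardized combination of the planted expressions so that its
correlation with the signal equals ``signal_strength`` in expectation, then
rescaled to the target cohort mean/SD (defaults 24.43 and 5.40 ml/kg/min).
Demographic and health covariates are drawn with configurable prevalences
and can feed the first expression score through standardized effects, so
that downstream covariate regressions have a known ground truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .data import RISK_FACTORS, CovariateTable, MetricMatrix
from .tracts import METRIC_NAMES, default_baseline_profile, make_tract_labels

#: cohort targets: VO2max moments and covariate prevalences for a healthy
#: older-adult sample (n = 167 reference cohort).
DEFAULT_COVARIATE_MODEL: dict = {
    "vo2max_mean": 24.43,
    "vo2max_sd": 5.40,
    "age_min": 50.0,
    "age_max": 88.0,
    "p_male": 89 / 167,
    "tiv_mean": 1.4e6,   # mm^3
    "tiv_sd": 1.3e5,
    "risk_prevalence": {
        "cardiac_arrest": 5 / 167,
        "hypertension": 55 / 167,
        "hyperlipidemia": 73 / 167,
        "diabetes": 8 / 167,
        "smoking": 66 / 167,
    },
    "p_apoe_e4": 49 / 167,
    "wmh_log_mean": 0.9,  # ln(ml); median ~2.5 ml
    "wmh_log_sd": 1.0,
}

#: standardized effects of covariates on the first expression score:
#: age and lesion load erode pattern expression, vascular risk adds a
#: smaller penalty, APOE e4 carriage has no effect.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age": -0.5,
    "wmh_log": -0.25,
    "vascular_risk_level": -0.15,
    "apoe_e4": 0.0,
}


def _vascular_risk_moments(prevalence: dict[str, float]) -> tuple[float, float]:
    """Exact population mean/SD of the derived high-risk indicator under
    independent risk factors (Poisson-binomial P(count >= 2))."""
    ps = list(prevalence.values())
    p_high = 0.0
    for combo in product((0, 1), repeat=len(ps)):
        if sum(combo) >= 2:
            prob = 1.0
            for c, p in zip(combo, ps):
                prob *= p if c else (1 - p)
            p_high += prob
    return p_high, float(np.sqrt(p_high * (1 - p_high)))


def random_planted_loadings(n_tracts: int, rng: np.random.Generator) -> np.ndarray:
    """Random unit-norm loading vector with zero tract mean.

    Double-centering annihilates the tract-mean component of any pattern, so
    a zero-sum planted vector is the identifiable default.
    """
    v = rng.standard_normal(n_tracts)
    v -= v.mean()
    return v / np.linalg.norm(v)


@dataclass
class GroundTruth:
    """Full generative specification of a synthetic cohort."""

    planted_loadings: np.ndarray
    baseline_profile: np.ndarray
    true_k: int = 1
    signal_strength: float = 0.7
    noise_sd: float = 0.5
    signal_amplitude: float = 0.05
    subject_scale_sd: float = 0.1
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    component_weights: np.ndarray | None = None  # default: equal over true_k
    component_sd_decay: float = 0.85
    residual_corr: float = 0.0
    covariate_model: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COVARIATE_MODEL))
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_loadings = np.asarray(self.planted_loadings, dtype=float)
        self.baseline_profile = np.asarray(self.baseline_profile, dtype=float)
        if self.component_weights is not None:
            self.component_weights = np.asarray(self.component_weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        norm = np.linalg.norm(self.planted_loadings)
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"planted_loadings must be unit norm (got {norm})")
        if not (0.0 <= abs(self.signal_strength) <= 1.0):
            raise ValueError("signal_strength must lie in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.signal_amplitude <= 0:
            raise ValueError("signal_amplitude must be positive")
        if self.subject_scale_sd < 0:
            raise ValueError("subject_scale_sd must be non-negative")
        if not (0.0 < self.component_sd_decay <= 1.0):
            raise ValueError("component_sd_decay must lie in (0, 1]")
        if not (0.0 <= self.residual_corr < 1.0):
            raise ValueError("residual_corr must lie in [0, 1)")
        if self.true_k < 1:
            raise ValueError("true_k must be at least 1")
        if np.any(self.baseline_profile <= 0):
            raise ValueError("baseline_profile must be strictly positive "
                             "(log transform must be defined)")
        if len(self.baseline_profile) != len(self.planted_loadings):
            raise ValueError("baseline_profile and planted_loadings lengths differ")
        if self.component_weights is not None and len(self.component_weights) != self.true_k:
            raise ValueError("component_weights must have length true_k")
        cm = self.covariate_model
        probs = [cm["p_male"], cm["p_apoe_e4"], *cm["risk_prevalence"].values()]
        if any(not (0.0 <= q <= 1.0) for q in probs):
            raise ValueError("covariate prevalence outside [0, 1]")
        effect_var = sum(b * b for b in self.covariate_effects.values())
        if effect_var > 1.0 + 1e-12:
            raise ValueError("sum of squared covariate effects exceeds 1")

    @classmethod
    def default(cls, n_tracts: int = 42, metric_name: str = "FA",
                seed: int = 0, **kwargs) -> "GroundTruth":
        rng = np.random.default_rng([seed, 101])
        return cls(
            planted_loadings=random_planted_loadings(n_tracts, rng),
            baseline_profile=default_baseline_profile(metric_name, n_tracts, seed=7),
            seed=seed,
            **kwargs,
        )

    def to_dict(self) -> dict:
        d = {
            "planted_loadings": self.planted_loadings.tolist(),
            "baseline_profile": self.baseline_profile.tolist(),
            "true_k": int(self.true_k),
            "signal_strength": float(self.signal_strength),
            "noise_sd": float(self.noise_sd),
            "signal_amplitude": float(self.signal_amplitude),
            "subject_scale_sd": float(self.subject_scale_sd),
            "covariate_effects": {k: float(v) for k, v in self.covariate_effects.items()},
            "component_weights": (None if self.component_weights is None
                                  else self.component_weights.tolist()),
            "component_sd_decay": float(self.component_sd_decay),
            "residual_corr": float(self.residual_corr),
            "covariate_model": copy.deepcopy(self.covariate_model),
            "seed": int(self.seed),
        }
        return d

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticCohort:
    """Generated metric matrices plus covariates plus the generating truth."""

    metric_matrices: dict[str, MetricMatrix]
    covariates: CovariateTable
    truth: GroundTruth
    expressions: np.ndarray          # (n, true_k) realized expression scores
    signal_components: np.ndarray    # (true_k, n_tracts) planted + nuisance loadings

    @property
    def metric_matrix(self) -> MetricMatrix:
        return next(iter(self.metric_matrices.values()))

    @property
    def participant_ids(self) -> list[str]:
        return self.metric_matrix.participant_ids

    def write(self, directory, sep: str = ",") -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, m in self.metric_matrices.items():
            m.write_csv(d / f"metric_{name}.csv", sep=sep)
        self.covariates.write_csv(d / "covariates.csv", sep=sep)
        self.truth.write_yaml(d / "ground_truth.yaml")


def _signal_basis(v1: np.ndarray, true_k: int, rng: np.random.Generator) -> np.ndarray:
    """Planted loading plus (true_k - 1) nuisance components, orthonormalised
    by Gram-Schmidt against the all-ones vector and each other."""
    p = len(v1)
    if true_k > p - 1:
        raise ValueError("true_k too large for the number of tracts")
    ones = np.ones(p) / np.sqrt(p)
    basis = [ones, v1 / np.linalg.norm(v1)]
    while len(basis) - 1 < true_k:
        w = rng.standard_normal(p)
        for b in basis:
            w -= (w @ b) * b
        norm = np.linalg.norm(w)
        if norm > 1e-8:
            basis.append(w / norm)
    return np.stack(basis[1:1 + true_k])


def _draw_covariates(n: int, cm: dict, rng: np.random.Generator) -> pd.DataFrame:
    df = pd.DataFrame(index=pd.Index([f"sub-{i + 1:04d}" for i in range(n)],
                                     name="participant_id"))
    df["age"] = rng.uniform(cm["age_min"], cm["age_max"], n)
    df["sex"] = (rng.random(n) < cm["p_male"]).astype(int)
    df["tiv"] = rng.normal(cm["tiv_mean"], cm["tiv_sd"], n)
    for factor in RISK_FACTORS:
        df[factor] = (rng.random(n) < cm["risk_prevalence"][factor]).astype(int)
    df["apoe_e4"] = (rng.random(n) < cm["p_apoe_e4"]).astype(int)
    df["wmh_ml"] = np.exp(rng.normal(cm["wmh_log_mean"], cm["wmh_log_sd"], n))
    return df


def _population_z(df: pd.DataFrame, column: str, cm: dict) -> np.ndarray:
    """Standardize a covariate by its *population* moments so configured
    standardized effects are exact rather than sample-dependent."""
    x = df[column].to_numpy(dtype=float)
    if column == "age":
        mu = (cm["age_min"] + cm["age_max"]) / 2
        sd = (cm["age_max"] - cm["age_min"]) / np.sqrt(12.0)
    elif column == "sex":
        p = cm["p_male"]
        mu, sd = p, np.sqrt(p * (1 - p))
    elif column == "tiv":
        mu, sd = cm["tiv_mean"], cm["tiv_sd"]
    elif column == "apoe_e4":
        p = cm["p_apoe_e4"]
        mu, sd = p, np.sqrt(p * (1 - p))
    elif column == "wmh_log":
        mu, sd = cm["wmh_log_mean"], cm["wmh_log_sd"]
    elif column == "vascular_risk_level":
        mu, sd = _vascular_risk_moments(cm["risk_prevalence"])
    elif column in RISK_FACTORS:
        p = cm["risk_prevalence"][column]
        mu, sd = p, np.sqrt(p * (1 - p))
    else:
        raise ValueError(f"no population moments for covariate {column!r}")
    if sd == 0:
        raise ValueError(f"covariate {column!r} is degenerate (zero variance)")
    return (x - mu) / sd


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(n_participants: int, n_tracts: int,
                    truth: GroundTruth | None = None,
                    metric_name: str = "FA") -> SyntheticCohort:
    """Generate a single-metric cohort; see the module docstring for the model."""
    return generate_study(n_participants, n_tracts, truth,
                          metrics=(metric_name,))


def generate_study(n_participants: int, n_tracts: int,
                   truth: GroundTruth | None = None,
                   metrics: tuple[str, ...] = METRIC_NAMES) -> SyntheticCohort:
    """Generate a cohort with one metric matrix per requested metric.

    All metrics share the participants, covariates, VO2max and expression
    scores (so each metric carries the same planted pattern), with
    metric-specific baseline profiles, subject scaling factors and noise.
    """
    if n_participants < 10:
        raise ValueError("n_participants must be at least 10")
    if n_tracts < 3:
        raise ValueError("n_tracts must be at least 3")
    if truth is None:
        truth = GroundTruth.default(n_tracts=n_tracts, metric_name=metrics[0])
    truth.validate()
    if len(truth.planted_loadings) != n_tracts:
        raise ValueError("truth.planted_loadings length does not match n_tracts")

    rng = np.random.default_rng(truth.seed)
    cm = truth.covariate_model
    n, k = n_participants, truth.true_k

    cov_df = _draw_covariates(n, cm, rng)
    cov_df["wmh_log"] = np.log(cov_df["wmh_ml"].to_numpy())
    from .data import derive_vascular_risk_level
    cov_df["vascular_risk_level"] = derive_vascular_risk_level(cov_df)

    # expression scores: s_1 carries the covariate effects and has SD 1 (the
    # planted signal SD); later components get geometrically smaller SDs so
    # the covariance spectrum decays and the leading components stay
    # individually identifiable (exactly degenerate eigenvalues would leave
    # only the signal subspace, not its basis, defined)
    component_sds = truth.component_sd_decay ** np.arange(k)
    S = rng.standard_normal((n, k)) * component_sds
    effects = truth.covariate_effects
    if effects:
        drive = np.zeros(n)
        effect_var = 0.0
        for name, beta in effects.items():
            if beta == 0.0:
                continue
            drive += beta * _population_z(cov_df, name, cm)
            effect_var += beta * beta
        resid_sd = np.sqrt(max(0.0, 1.0 - effect_var))
        S[:, 0] = drive + resid_sd * S[:, 0]

    # VO2max correlated with the weighted combination of planted expressions;
    # weights apply to the *standardized* expressions, so equal weights mean
    # every signal component contributes equally to the fitness signal
    w = (truth.component_weights if truth.component_weights is not None
         else np.ones(k))
    w = w / np.linalg.norm(w)
    u = _zscore((S / component_sds) @ w)
    r = truth.signal_strength
    vo2_noise = rng.standard_normal(n)
    vo2_std = r * u + np.sqrt(max(0.0, 1.0 - r * r)) * vo2_noise
    cov_df["vo2max"] = cm["vo2max_mean"] + cm["vo2max_sd"] * vo2_std

    V = _signal_basis(truth.planted_loadings, k, rng)
    signal = S @ V

    matrices: dict[str, MetricMatrix] = {}
    labels = make_tract_labels(n_tracts)
    ids = list(cov_df.index)
    for metric in metrics:
        baseline = (truth.baseline_profile if metric == metrics[0]
                    else default_baseline_profile(metric, n_tracts, seed=7))
        g = rng.normal(0.0, truth.subject_scale_sd, n)
        eps = rng.standard_normal((n, n_tracts))
        if truth.residual_corr > 0:
            shared = rng.standard_normal((n, 1))
            eps = (np.sqrt(truth.residual_corr) * shared
                   + np.sqrt(1 - truth.residual_corr) * eps)
        # signal_amplitude converts the dimensionless signal + noise block
        # (expression SD 1, noise in expression-SD units) into log-metric
        # units, i.e. fractional metric variation per expression SD
        logm = (np.log(baseline)[None, :] + g[:, None]
                + truth.signal_amplitude * (signal + truth.noise_sd * eps))
        matrices[metric] = MetricMatrix(
            values=np.exp(logm), participant_ids=ids,
            tract_labels=labels, metric_name=metric)

    return SyntheticCohort(
        metric_matrices=matrices,
        covariates=CovariateTable(cov_df),
        truth=truth,
        expressions=S,
        signal_components=V,
    )


def inject_outliers(cohort: SyntheticCohort,
                    spec: list[tuple]) -> SyntheticCohort:
    """Return a copy of the cohort with cells displaced by given offsets.

    ``spec`` is a list of ``(participant, tract, metric, offset)`` where
    participant and tract may be identifiers or integer positions. Ground
    truth is unchanged; out-of-range indices are rejected.
    """
    new_matrices = {name: replace(m, values=m.values.copy())
                    for name, m in cohort.metric_matrices.items()}
    for participant, tract, metric, offset in spec:
        if metric not in new_matrices:
            raise ValueError(f"unknown metric {metric!r}")
        m = new_matrices[metric]
        i = (m.participant_ids.index(participant) if isinstance(participant, str)
             else int(participant))
        j = (m.tract_labels.index(tract) if isinstance(tract, str)
             else int(tract))
        if not (0 <= i < m.n_participants and 0 <= j < m.n_tracts):
            raise IndexError(f"cell ({participant}, {tract}) out of range")
        m.values[i, j] += offset
        m.validate()
    return SyntheticCohort(
        metric_matrices=new_matrices,
        covariates=cohort.covariates,
        truth=cohort.truth,
        expressions=cohort.expressions,
        signal_components=cohort.signal_components,
    )
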