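"""Tabular containers: participant x tract metric matrices and covariates.

Both containers are thin, validated wrappers around numpy/pandas objects and
round-trip losslessly through delimited text (header row, first column the
participant identifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: binary clinical vascular risk indicators; "high" vascular risk level is
#: defined as carrying two or more of these.
RISK_FACTORS = (
    "cardiac_arrest",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "smoking",
)

COVARIATE_COLUMNS = (
    "vo2max", "age", "sex", "tiv",
    *RISK_FACTORS,
    "apoe_e4", "wmh_ml",
)


@dataclass
class MetricMatrix:
    """One diffusion metric (AD, RD, MD or FA) for all participants and tracts.

    values
        ``(n_participants, n_tracts)`` array, strictly positive (the analysis
        starts with a natural log transform). Diffusivities are in native
        units (mm^2/s); FA is dimensionless.
    """

    values: np.ndarray
    participant_ids: list[str]
    tract_labels: list[str]
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.participant_ids = [str(p) for p in self.participant_ids]
        self.tract_labels = [str(t) for t in self.tract_labels]
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.participant_ids) != n:
            raise ValueError(
                f"{len(self.participant_ids)} participant ids for {n} rows")
        if len(self.tract_labels) != p:
            raise ValueError(f"{len(self.tract_labels)} tract labels for {p} columns")
        if len(set(self.participant_ids)) != n:
            raise ValueError("participant ids are not unique")
        if len(set(self.tract_labels)) != p:
            raise ValueError("tract labels are not unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at participant {self.participant_ids[bad[0]]}, "
                f"tract {self.tract_labels[bad[1]]}")
        if np.any(self.values <= 0):
            bad = np.argwhere(self.values <= 0)[0]
            raise ValueError(
                f"non-positive {self.metric_name} value at participant "
                f"{self.participant_ids[bad[0]]}, tract {self.tract_labels[bad[1]]}: "
                "log transform undefined")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracts(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.participant_ids, name="participant_id"),
            columns=self.tract_labels,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric_name: str) -> "MetricMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            participant_ids=[str(i) for i in df.index],
            tract_labels=[str(c) for c in df.columns],
            metric_name=metric_name,
        )

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep)

    @classmethod
    def read_csv(cls, path, metric_name: str, sep: str | None = None) -> "MetricMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
        return cls.from_dataframe(df, metric_name)

    def subset_participants(self, keep_ids) -> "MetricMatrix":
        keep = set(keep_ids)
        mask = np.array([p in keep for p in self.participant_ids])
        return replace(
            self,
            values=self.values[mask],
            participant_ids=[p for p in self.participant_ids if p in keep],
        )


def derive_vascular_risk_level(df: pd.DataFrame) -> pd.Series:
    """High (1) iff two or more of the five clinical risk factors are present."""
    counts = df[list(RISK_FACTORS)].sum(axis=1)
    return (counts >= 2).astype(int)


@dataclass
class CovariateTable:
    """Per-participant covariates for the fitness-pattern analyses.

    Required columns: vo2max (ml/kg/min), age (years), sex (male=1),
    tiv (mm^3), the five binary risk factors, apoe_e4 (carrier=1) and
    wmh_ml (white matter hyperintensity volume, ml). ``vascular_risk_level``
    and ``wmh_log`` are derived on construction and recomputed if absent.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.name != "participant_id":
            if "participant_id" in df.columns:
                df = df.set_index("participant_id")
            else:
                df.index.name = "participant_id"
        df.index = df.index.astype(str)
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"covariate table is missing columns: {missing}")
        if not df.index.is_unique:
            raise ValueError("participant ids are not unique")
        if "vascular_risk_level" not in df.columns:
            df["vascular_risk_level"] = derive_vascular_risk_level(df)
        if "wmh_log" not in df.columns:
            if np.any(df["wmh_ml"].to_numpy() <= 0):
                raise ValueError("wmh_ml must be strictly positive to take logs")
            df["wmh_log"] = np.log(df["wmh_ml"].to_numpy())
        expected = derive_vascular_risk_level(df)
        if not (df["vascular_risk_level"].astype(int) == expected).all():
            raise ValueError(
                "vascular_risk_level is inconsistent with the risk factor columns "
                "(high=1 iff >=2 positive indicators)")
        self.table = df

    @property
    def participant_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    def __len__(self) -> int:
        return len(self.table)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy(dtype=float)

    @property
    def vo2max(self) -> np.ndarray:
        return self["vo2max"]

    def aligned_to(self, participant_ids) -> "CovariateTable":
        """Reindex to the given participant order; error on any orphan."""
        ids = [str(p) for p in participant_ids]
        have = set(self.participant_ids)
        orphans = [p for p in ids if p not in have]
        if orphans:
            raise ValueError(f"participants missing from covariate table: {orphans}")
        return CovariateTable(self.table.loc[ids])

    def write_csv(self, path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep)

    @classmethod
    def read_csv(cls, path, sep: str | None = None) -> "CovariateTable":
        return cls(pd.read_csv(path, sep=sep, index_col=0, engine="python"))


def check_alignment(matrices: dict[str, MetricMatrix],
                    covariates: CovariateTable | None = None) -> None:
    """All metric matrices (and optionally covariates) must share one ordered
    participant list and one tract list."""
    items = list(matrices.items())
    ref_name, ref = items[0]
    for name, m in items[1:]:
        if m.participant_ids != ref.participant_ids:
            raise ValueError(f"participant ids of {name} do not match {ref_name}")
        if m.tract_labels != ref.tract_labels:
            raise ValueError(f"tract labels of {name} do not match {ref_name}")
    if covariates is not None and covariates.participant_ids != ref.participant_ids:
        missing = set(ref.participant_ids) - set(covariates.participant_ids)
        extra = set(covariates.participant_ids) - set(ref.participant_ids)
        raise ValueError(
            "covariate table misaligned with metric matrices"
            + (f"; missing: {sorted(missing)}" if missing else "")
            + (f"; extra: {sorted(extra)}" if extra else ""))
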