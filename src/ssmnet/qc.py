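"""Interquartile-range quality control across the four diffusion metrics.

A cell (participant, tract, metric) is an extreme value when it lies beyond
3 interquartile ranges of that tract's cross-participant distribution for
that metric (below Q1 - 3*IQR or above Q3 + 3*IQR). A participant is then
excluded when

* rule 3 — more than one of the four metrics is extreme for the same tract, or
* rule 4 — any single metric is extreme on more than one tract.

Quartiles use the linear-interpolation definition (numpy's default); IQR
flags can differ at the margin under other quantile definitions. Quartiles
are computed per tract and per metric across participants (a per-tract
default; see the ``axis`` argument).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MetricMatrix, check_alignment


@dataclass
class QCReport:
    flagged_cells: set = field(default_factory=set)   # (participant_id, tract_label, metric)
    excluded_participants: dict = field(default_factory=dict)  # id -> sorted rule list
    retained_n: int = 0
    input_n: int = 0

    @property
    def excluded_ids(self) -> list[str]:
        return sorted(self.excluded_participants)

    def flags_frame(self) -> pd.DataFrame:
        rows = sorted(self.flagged_cells)
        return pd.DataFrame(rows, columns=["participant_id", "tract", "metric"])

    def exclusions_frame(self) -> pd.DataFrame:
        rows = [(p, ",".join(str(r) for r in rules))
                for p, rules in sorted(self.excluded_participants.items())]
        return pd.DataFrame(rows, columns=["participant_id", "rules"])


def _extreme_mask(values: np.ndarray, multiplier: float, axis: int) -> np.ndarray:
    q1 = np.quantile(values, 0.25, axis=axis, keepdims=True)
    q3 = np.quantile(values, 0.75, axis=axis, keepdims=True)
    iqr = q3 - q1
    return (values < q1 - multiplier * iqr) | (values > q3 + multiplier * iqr)


def qc_flag_extremes(matrices: dict[str, MetricMatrix],
                     multiplier: float = 3.0,
                     axis: str = "participants") -> QCReport:
    """Flag extreme cells and derive participant exclusions.

    Parameters
    ----------
    matrices
        Mapping metric name -> MetricMatrix; all must share participant and
        tract indices.
    multiplier
        IQR multiple defining "extreme" (default 3).
    axis
        ``"participants"`` (default): quartiles per tract per metric across
        participants. ``"tracts"``: across tracts within participant.
    """
    if not matrices:
        raise ValueError("no metric matrices supplied")
    check_alignment(matrices)
    ref = next(iter(matrices.values()))
    ids, tracts = ref.participant_ids, ref.tract_labels
    n, p = len(ids), len(tracts)
    np_axis = 0 if axis == "participants" else 1

    report = QCReport(input_n=n)
    # per-participant tallies: metrics flagged per tract, tracts flagged per metric
    flags_per_tract = np.zeros((n, p), dtype=int)
    tracts_per_metric: dict[str, np.ndarray] = {}
    for metric, m in matrices.items():
        mask = _extreme_mask(m.values, multiplier, np_axis)
        flags_per_tract += mask.astype(int)
        tracts_per_metric[metric] = mask.sum(axis=1)
        for i, j in np.argwhere(mask):
            report.flagged_cells.add((ids[i], tracts[j], metric))

    for i, pid in enumerate(ids):
        rules = []
        if np.any(flags_per_tract[i] >= 2):
            rules.append(3)
        if any(counts[i] >= 2 for counts in tracts_per_metric.values()):
            rules.append(4)
        if rules:
            report.excluded_participants[pid] = rules
    report.retained_n = n - len(report.excluded_participants)
    return report


def apply_exclusions(matrices: dict[str, MetricMatrix],
                     report: QCReport) -> dict[str, MetricMatrix]:
    """Drop excluded participants from every metric matrix."""
    keep = [p for p in next(iter(matrices.values())).participant_ids
            if p not in report.excluded_participants]
    return {name: m.subset_participants(keep) for name, m in matrices.items()}
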