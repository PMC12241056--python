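"""Canonical white matter bundle labels and plausible per-metric baselines.

The default tract set mirrors the 42 bundles of a global probabilistic
tractography atlas: 16 bilateral pairs plus 8 corpus callosum subdivisions,
the anterior commissure and the middle cerebellar peduncle. Labels are
cosmetic — every routine accepts arbitrary label lists — but reports read
more naturally with real bundle names.
"""

from __future__ import annotations

import numpy as np

_BILATERAL = [
    "Arc Fas",      # arcuate fasciculus
    "Fron Asl",     # frontal aslant
    "SLF 1",        # superior longitudinal fasciculus, dorsal
    "SLF 2",
    "SLF 3",
    "Ant Thal",     # anterior thalamic radiation
    "Acou Rad",     # acoustic radiation
    "Opt Rad",      # optic radiation
    "Unc Fas",      # uncinate fasciculus
    "Ext Cap",      # external capsule
    "CST",          # corticospinal tract
    "MLF",          # middle longitudinal fasciculus
    "ILF",          # inferior longitudinal fasciculus
    "Cing Bun D",   # cingulum bundle, dorsal
    "Cing Bun V",   # cingulum bundle, ventral
    "Fornix",
]

_COMMISSURAL = [
    "CC Genu",
    "CC Rostrum",
    "CC Splenium",
    "CC Body C",    # central
    "CC Body PF",   # prefrontal
    "CC Body PM",   # premotor
    "CC Body P",    # parietal
    "CC Body T",    # temporal
    "Ant Comm",     # anterior commissure
    "Mid Cer Ped",  # middle cerebellar peduncle
]

DEFAULT_TRACT_LABELS: list[str] = [
    f"{name} {side}" for name in _BILATERAL for side in ("L", "R")
] + list(_COMMISSURAL)

N_DEFAULT_TRACTS = len(DEFAULT_TRACT_LABELS)  # 42

# Typical tract-average values in healthy older adults; diffusivities in
# mm^2/s, FA dimensionless. Used as the centre of generated baseline profiles.
METRIC_BASELINE_RANGES: dict[str, tuple[float, float]] = {
    "AD": (1.05e-3, 1.50e-3),
    "RD": (4.0e-4, 7.0e-4),
    "MD": (6.5e-4, 9.5e-4),
    "FA": (0.30, 0.60),
}

METRIC_NAMES = ("AD", "RD", "MD", "FA")


def default_baseline_profile(metric_name: str, n_tracts: int, seed: int = 0) -> np.ndarray:
    """Per-tract mean metric values spread across the metric's typical range.

    Deterministic in ``seed``; strictly positive so the log transform is
    always defined.
    """
    lo, hi = METRIC_BASELINE_RANGES.get(metric_name, (0.5, 1.5))
    rng = np.random.default_rng(seed)
    # smooth spread over the range with mild jitter, then shuffled so
    # neighbouring tracts are not artificially ordered
    base = np.linspace(lo, hi, n_tracts)
    jitter = rng.uniform(-0.02, 0.02, n_tracts) * (hi - lo)
    profile = np.clip(base + jitter, lo * 0.9, hi * 1.1)
    rng.shuffle(profile)
    return profile


def make_tract_labels(n_tracts: int) -> list[str]:
    if n_tracts <= N_DEFAULT_TRACTS:
        return DEFAULT_TRACT_LABELS[:n_tracts]
    extra = [f"Tract {i + 1}" for i in range(N_DEFAULT_TRACTS, n_tracts)]
    return DEFAULT_TRACT_LABELS + extra
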