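"""Synthetic two-group LC-MS-like feature tables with metadata confounders.

The generator emulates the design of a small amniotic-fluid untargeted
metabolomics study: two clinical groups of roughly 10–13 subjects, 1400–1800
RT_mass features with log-normal intensities, a handful of genuinely
class-discriminant marker features, and features driven instead by a
metadata covariate that may itself correlate with the class (a confounder).
Ground truth (which features carry which effect) is returned alongside the
tables so every downstream stage — constrained modelling, validation,
stability selection — can be tested without access to real data.

Intensity model: per-feature baseline log-intensity ~ N(9, 1.5²) (peak areas
around e⁹ ≈ 8000 counts), i.i.d. Gaussian residual noise of SD ``noise_sd``
on the log scale, exponentiated.  Marker features shift the case group's
log-mean by ``marker_effect · noise_sd``; confounded features regress on the
standardized covariate with slope ``confounder_effect``.  Covariates mirror
a typical obstetric metadata sheet: maternal age and BMI (continuous),
previous-miscarriage count, gestational age at amniocentesis (21–28 weeks),
four binary therapy flags, and newborn sex — all independent except the
designated confounder (maternal age), which correlates with class membership
at ``confounder_class_assoc``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationDesign",
    "SyntheticTruth",
    "simulate_dataset",
    "inject_binary_factor",
    "write_dataset",
]

CONTROL_CLASS = "TD"
CASE_CLASS = "PTD"
CONFOUNDER_COVARIATE = "maternal_age"


@dataclass(frozen=True)
class SimulationDesign:
    """Knobs of the synthetic study.

    ``n_per_group`` is an int (balanced) or a (control, case) pair.
    ``marker_effect`` is the standardized between-class mean shift in units
    of ``noise_sd`` (log scale); ``confounder_effect`` the slope of the
    log-intensity on the standardized covariate; ``confounder_class_assoc``
    the target correlation in [0, 1) between covariate and class membership.
    """

    n_per_group: int | tuple = 12
    n_features: int = 1400
    n_markers: int = 20
    n_confounded: int = 30
    n_both: int = 0
    marker_effect: float = 1.0
    confounder_effect: float = 1.0
    noise_sd: float = 0.5
    confounder_class_assoc: float = 0.0
    seed: int = 0
    left_censor_quantile: float = 0.0   # optional left-censoring, off by default

    def group_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_group, (tuple, list)):
            return int(self.n_per_group[0]), int(self.n_per_group[1])
        return int(self.n_per_group), int(self.n_per_group)

    def validate(self) -> None:
        n0, n1 = self.group_sizes()
        for name, v in (("n_per_group", min(n0, n1)), ("n_features", self.n_features),
                        ("n_markers", self.n_markers), ("n_confounded", self.n_confounded),
                        ("n_both", self.n_both)):
            if v < 0 or (name in ("n_per_group", "n_features") and v < 1):
                raise ValueError(f"invalid design: {name} = {v}")
        if self.n_markers + self.n_confounded + self.n_both > self.n_features:
            raise ValueError(
                "invalid design: n_markers + n_confounded + n_both "
                f"({self.n_markers}+{self.n_confounded}+{self.n_both}) exceeds "
                f"n_features ({self.n_features})")
        if not self.noise_sd > 0:
            raise ValueError(f"invalid design: noise_sd = {self.noise_sd} (must be > 0)")
        if not 0 <= self.confounder_class_assoc < 1:
            raise ValueError(
                f"invalid design: confounder_class_assoc = {self.confounder_class_assoc} "
                "(must lie in [0, 1))")
        if not 0 <= self.left_censor_quantile < 1:
            raise ValueError(
                f"invalid design: left_censor_quantile = {self.left_censor_quantile}")


@dataclass
class SyntheticTruth:
    """Which features carry which effect, plus the simulated covariates."""

    marker_ids: list
    confounded_ids: list
    both_ids: list
    covariate_values: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"marker_ids": self.marker_ids,
                       "confounded_ids": self.confounded_ids,
                       "both_ids": self.both_ids,
                       "covariate_values": {k: list(map(float, v))
                                            for k, v in self.covariate_values.items()}},
                      fh, sort_keys=True)


def _feature_ids(rng, p: int) -> list[str]:
    """Unique 'RT_mz' identifiers, e.g. '5.06_197.0808'."""
    ids: list[str] = []
    seen = set()
    while len(ids) < p:
        rt = rng.uniform(0.5, 7.5)
        mz = rng.uniform(80.0, 800.0)
        fid = f"{rt:.2f}_{mz:.4f}"
        if fid not in seen:
            seen.add(fid)
            ids.append(fid)
    return ids


def simulate_dataset(design: SimulationDesign):
    """Generate (FeatureTable, MetadataTable, SyntheticTruth).

    Reproducible given ``design.seed``; intensities are strictly positive.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n0, n1 = design.group_sizes()
    n = n0 + n1
    p = design.n_features
    group = np.array([CONTROL_CLASS] * n0 + [CASE_CLASS] * n1)
    case = (group == CASE_CLASS).astype(float)

    # covariates (Table-1-like obstetric metadata)
    rho = design.confounder_class_assoc
    zc = (case - case.mean()) / case.std() if case.std() > 0 else np.zeros(n)
    cov_std = rho * zc + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    meta = pd.DataFrame({
        "group": group,
        "maternal_age": np.round(30.0 + 4.0 * cov_std, 1),
        "maternal_bmi": np.round(rng.normal(22.5, 2.5, n), 1),
        "previous_miscarriages": rng.poisson(0.35, n),
        "ga_amniocentesis": rng.integers(21, 29, n),
        "betamethasone": rng.random(n) < 0.65,
        "atosiban": rng.random(n) < 0.45,
        "progesterone": rng.random(n) < 0.15,
        "nifedipine": rng.random(n) < 0.08,
        "male": rng.random(n) < 0.60,
    }, index=[f"S{i + 1:02d}" for i in range(n)])
    meta[["betamethasone", "atosiban", "progesterone", "nifedipine", "male"]] = \
        meta[["betamethasone", "atosiban", "progesterone", "nifedipine", "male"]].astype(int)

    ids = _feature_ids(rng, p)
    special = rng.choice(p, size=design.n_markers + design.n_confounded + design.n_both,
                         replace=False)
    m_idx = special[:design.n_markers]
    c_idx = special[design.n_markers:design.n_markers + design.n_confounded]
    b_idx = special[design.n_markers + design.n_confounded:]

    baseline = rng.normal(9.0, 1.5, p)
    logx = baseline + design.noise_sd * rng.standard_normal((n, p))
    shift = design.marker_effect * design.noise_sd
    for idx in (m_idx, b_idx):
        logx[:, idx] += shift * case[:, None]
    for idx in (c_idx, b_idx):
        logx[:, idx] += design.confounder_effect * cov_std[:, None]
    X = np.exp(logx)
    if design.left_censor_quantile > 0:
        floor = np.quantile(X, design.left_censor_quantile)
        X = np.maximum(X, floor)
    table = pd.DataFrame(X, index=meta.index, columns=ids)
    truth = SyntheticTruth(
        [ids[i] for i in np.sort(m_idx)],
        [ids[i] for i in np.sort(c_idx)],
        [ids[i] for i in np.sort(b_idx)],
        {CONFOUNDER_COVARIATE: cov_std.tolist()},
    )
    return table, meta, truth


def inject_binary_factor(meta: pd.DataFrame, prevalence: float, seed: int,
                         name: str = "chorioamnionitis") -> pd.DataFrame:
    """Add a binary external factor drawn independently of class.

    Returns a copy of the metadata with one extra 0/1 column at the given
    prevalence; reproducible given ``seed``.
    """
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence}")
    rng = np.random.default_rng(seed)
    out = meta.copy()
    out[name] = (rng.random(len(meta)) < prevalence).astype(int)
    return out


def write_dataset(table: pd.DataFrame, meta: pd.DataFrame, truth: SyntheticTruth,
                  prefix) -> None:
    """Write features/metadata as CSV (samples in rows) and truth as JSON."""
    table.rename_axis("sample_id").to_csv(f"{prefix}_features.csv")
    meta.rename_axis("sample_id").to_csv(f"{prefix}_metadata.csv")
    truth.to_json(f"{prefix}_truth.json")
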