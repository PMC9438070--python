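"""Physiological-dysregulation scoring.

Biomarkers are normalized (log/sqrt where flagged), standardized against a
first-visit reference population ("UV scaled": centred at the reference
mean, divided by the reference SD), and integrated into Mahalanobis-distance
dysregulation scores: a global score over all 30 markers and one score per
physiological system using that system's covariance sub-block.  Higher
scores indicate a more aberrant profile, i.e. greater loss of homeostasis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .panel import BiomarkerPanel
from .simulate import BM_PREFIX

__all__ = [
    "ReferenceStats",
    "build_reference_stats",
    "mahalanobis_distance",
    "score_dysregulation",
    "log_z_scores",
    "SCORE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: dysregulation score columns in a ScoreTable, in output order
SCORE_COLUMNS = (
    "dm_global",
    "dm_oxygen_transport",
    "dm_liver_kidney",
    "dm_leukopoiesis",
    "dm_micronutrients",
    "dm_lipids",
)


def _transform(values: np.ndarray, how: str) -> np.ndarray:
    if how == "log":
        return np.log(values)
    if how == "sqrt":
        return np.sqrt(values)
    return values


@dataclass
class ReferenceStats:
    """First-visit reference moments and correlation structure.

    Means/SDs are on the transformed scale; ``cov`` is the covariance of
    the standardized markers (so its diagonal is ~1), with marker order
    matching ``names``.
    """

    names: list[str]
    transforms: dict[str, str]
    means: np.ndarray
    sds: np.ndarray
    cov: np.ndarray
    n_reference: int

    def standardize(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Transform and UV-scale the panel columns of ``cohort``."""
        z = {}
        for j, name in enumerate(self.names):
            x = _transform(cohort[BM_PREFIX + name].to_numpy(float), self.transforms[name])
            z[name] = (x - self.means[j]) / self.sds[j]
        return pd.DataFrame(z, index=cohort.index)

    def sub_cov(self, names: list[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.cov[np.ix_(idx, idx)]


def build_reference_stats(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    reference_visit: int = 1,
) -> ReferenceStats:
    """Compute reference means/SDs/covariance from first-visit rows.

    The entry visit represents a population in general good health (the
    cohort's inclusion criteria screen at recruitment), making it the
    natural reference against which later deviation is measured.
    """
    ref = cohort[cohort["visit"] == reference_visit]
    cols = [BM_PREFIX + n for n in panel.names]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks biomarker columns: {missing}")
    ref = ref.dropna(subset=cols)
    if len(ref) < len(panel):
        raise ValueError(
            f"only {len(ref)} complete reference rows for {len(panel)} markers; "
            "covariance would be singular"
        )
    transforms = {m.name: m.transform for m in panel.markers}
    X = np.column_stack(
        [_transform(ref[BM_PREFIX + n].to_numpy(float), transforms[n]) for n in panel.names]
    )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [panel.names[j] for j in np.flatnonzero(sds == 0)]
    if zero:
        raise ValueError(f"zero reference SD for marker(s): {zero}")
    Z = (X - means) / sds
    cov = np.cov(Z, rowvar=False, ddof=1)
    cov = (cov + cov.T) / 2
    return ReferenceStats(
        names=list(panel.names),
        transforms=transforms,
        means=means,
        sds=sds,
        cov=cov,
        n_reference=len(ref),
    )


def _regularize(cov: np.ndarray, max_condition: float = 1e8, weight: float = 1e-3) -> np.ndarray:
    """Shrink toward the identity when the covariance is near-singular.

    Stable at the scale of ~30 markers on ~1500 reference rows; the guard
    exists for small synthetic reference samples.
    """
    eigvals = linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > max_condition:
        cov = (1.0 - weight) * cov + weight * np.eye(cov.shape[0])
        eigvals = linalg.eigvalsh(cov)
        if eigvals[0] <= 0:
            raise ValueError("covariance singular beyond regularization tolerance")
    return cov


def mahalanobis_distance(z: np.ndarray, cov: np.ndarray) -> float | np.ndarray:
    """sqrt(z' cov^-1 z) for one profile or a stack of profiles (rows)."""
    z = np.asarray(z, float)
    cov = _regularize(np.asarray(cov, float))
    if z.ndim == 1:
        if z.size != cov.shape[0]:
            raise ValueError("profile length does not match covariance dimension")
        sol = linalg.solve(cov, z, assume_a="pos")
        return float(np.sqrt(z @ sol))
    if z.shape[1] != cov.shape[0]:
        raise ValueError("profile length does not match covariance dimension")
    sol = linalg.solve(cov, z.T, assume_a="pos")
    return np.sqrt(np.einsum("ij,ji->i", z, sol))


def score_dysregulation(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    ref: ReferenceStats,
) -> pd.DataFrame:
    """Per-observation dysregulation ScoreTable.

    The global score uses all panel markers and the full reference
    covariance; each system score uses only that system's markers and the
    corresponding covariance sub-block.  An observation missing any marker
    required by a score gets a missing value for that score (no
    imputation); the count of such rows is logged.
    """
    z = ref.standardize(cohort)
    out = cohort[["subject_id", "visit"]].copy()

    def _score(names: list[str], col: str) -> None:
        block = z[names].to_numpy(float)
        complete = ~np.isnan(block).any(axis=1)
        vals = np.full(len(z), np.nan)
        if complete.any():
            vals[complete] = mahalanobis_distance(block[complete], ref.sub_cov(names))
        if (~complete).any():
            logger.info("%s: %d observation(s) missing markers, score set missing",
                        col, int((~complete).sum()))
        out[col] = vals

    _score(list(panel.names), "dm_global")
    for system in panel.systems:
        _score(panel.system_members(system), f"dm_{system}")
    return out


def log_z_scores(
    scores: pd.DataFrame,
    columns: tuple[str, ...] = SCORE_COLUMNS,
    epsilon: float = 1e-8,
    ddof: int = 0,
) -> pd.DataFrame:
    """Log-transform then Z-transform score columns over the given sample.

    Appends ``log_<col>`` and ``z_<col>`` columns; the Z columns have mean 0
    and SD 1 (population-SD convention) over the non-missing rows.  Raw
    scores of 0 are floored at ``epsilon`` with a warning (the log would be
    infinite); rank order is preserved.
    """
    out = scores.copy()
    for col in columns:
        if col not in out.columns:
            continue
        raw = out[col].to_numpy(float)
        n_zero = int(np.sum(raw == 0))
        if n_zero:
            warnings.warn(f"{col}: {n_zero} zero score(s) floored at {epsilon} before log")
        logged = np.log(np.maximum(raw, epsilon))
        mu = np.nanmean(logged)
        sd = np.nanstd(logged, ddof=ddof)
        if sd == 0:
            raise ValueError(f"{col}: zero variance, cannot Z-transform")
        out["log_" + col] = logged
        out["z_" + col] = (logged - mu) / sd
    return out
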