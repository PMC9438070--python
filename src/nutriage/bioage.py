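"""Biological-age outcomes: phenotypic age and Klemera-Doubal age.

Phenotypic age (PhenoAge) maps a 9-biomarker + chronological-age linear
predictor through a Gompertz 10-year mortality risk M and back onto the age
scale; the coefficients were calibrated against NHANES mortality follow-up
and are shipped here as a documented configuration (units declared per
input) rather than hard-coded in the computation.  Because C-reactive
protein is not assayed in the target cohort, the default policy substitutes
a fixed population-mean CRP for every individual.

Klemera-Doubal (KDM) biological age combines per-marker regressions of
marker on chronological age (intercept q_j, slope k_j, residual SD s_j)
into a precision-weighted age estimate, optionally age-corrected through a
variance term s_BA^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenoAgeCoefficients",
    "compute_phenoage",
    "phenoage_inputs",
    "KdmCalibration",
    "calibrate_kdm",
    "compute_kdm_age",
]


# Default PhenoAge configuration, transcribed from the published NHANES-IV
# calibration (Levine et al. 2018).  Units matter: a value supplied on the
# wrong scale produces a mortality score outside (0, 1), which is treated
# as an error rather than silently propagated.
_PHENOAGE_DEFAULT_COEFS = {
    "albumin": (-0.0336, "g/L"),
    "creatinine": (0.0095, "umol/L"),
    "glucose": (0.1953, "mmol/L"),
    "log_crp": (0.0954, "log(mg/dL)"),
    "lymphocyte_percent": (-0.0120, "%"),
    "mcv": (0.0268, "fL"),
    "rdw_percent": (0.3306, "%"),
    "alkaline_phosphatase": (0.00188, "U/L"),
    "leukocytes": (0.0554, "10^9 cells/L"),
}


@dataclass
class PhenoAgeCoefficients:
    """PhenoAge formula constants with unit declarations.

    ``crp_policy`` is ``"constant"`` (every individual gets ``crp_constant``
    mg/dL, the cohort-independent population-mean policy) or
    ``"individual"`` (the supplied CRP value is used).
    """

    coefficients: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(_PHENOAGE_DEFAULT_COEFS)
    )
    intercept: float = -19.9067
    age_coefficient: float = 0.0804  # per year
    gompertz_gamma: float = 0.0076927  # Gompertz shape, per month
    horizon_months: float = 120.0  # 10-year mortality horizon
    age_map_a: float = 141.50225  # final age-mapping constants
    age_map_b: float = -0.00553
    age_map_c: float = 0.090165
    crp_policy: str = "constant"
    crp_constant: float = 0.42  # mg/dL; configurable population-mean CRP

    @property
    def marker_names(self) -> list[str]:
        return list(self.coefficients)

    def __post_init__(self) -> None:
        if len(self.coefficients) != 9:
            raise ValueError("PhenoAge takes exactly 9 biomarker inputs plus age")
        if self.crp_policy not in ("constant", "individual"):
            raise ValueError("crp_policy must be 'constant' or 'individual'")


def compute_phenoage(
    markers: dict[str, float] | pd.DataFrame,
    age: float | np.ndarray,
    coeffs: PhenoAgeCoefficients | None = None,
) -> float | np.ndarray:
    """Phenotypic age in years for one profile or a table of profiles.

    ``markers`` must supply every coefficient input in its declared units;
    under the constant-CRP policy the ``log_crp`` entry is replaced by
    log(crp_constant) regardless of what is supplied (the key may then be
    omitted entirely).
    """
    coeffs = coeffs or PhenoAgeCoefficients()
    scalar = not isinstance(markers, pd.DataFrame)
    table = pd.DataFrame([markers]) if scalar else markers
    age_arr = np.atleast_1d(np.asarray(age, float))

    xb = np.full(len(table), coeffs.intercept + 0.0)
    for name, (beta, _units) in coeffs.coefficients.items():
        if name == "log_crp" and coeffs.crp_policy == "constant":
            value = math.log(coeffs.crp_constant)
        else:
            if name not in table.columns:
                raise ValueError(f"PhenoAge input {name!r} missing")
            value = table[name].to_numpy(float)
            if np.isnan(value).any():
                raise ValueError(f"PhenoAge input {name!r} contains missing values")
        xb = xb + beta * value
    xb = xb + coeffs.age_coefficient * age_arr

    g = coeffs.gompertz_gamma
    mort = 1.0 - np.exp(-np.exp(xb) * (np.exp(g * coeffs.horizon_months) - 1.0) / g)
    if np.any((mort <= 0.0) | (mort >= 1.0)):
        raise ValueError(
            "mortality score outside (0, 1); check marker units against the "
            "declared units in PhenoAgeCoefficients"
        )
    pheno = coeffs.age_map_a + np.log(coeffs.age_map_b * np.log1p(-mort)) / coeffs.age_map_c
    return float(pheno[0]) if scalar and pheno.size == 1 else pheno


def phenoage_inputs(cohort: pd.DataFrame, bm_prefix: str = "bm_") -> pd.DataFrame:
    """Map cohort biomarker columns onto the PhenoAge input names/units.

    Lymphocyte and red-cell-distribution-width differentials are stored as
    proportions in the cohort and converted to the percent scale the
    coefficients expect.
    """
    def col(name):
        return cohort[bm_prefix + name].to_numpy(float)

    return pd.DataFrame(
        {
            "albumin": col("albumin"),
            "creatinine": col("creatinine"),
            "glucose": col("glucose"),
            "lymphocyte_percent": col("lymphocytes") * 100.0,
            "mcv": col("mcv"),
            "rdw_percent": col("rdw") * 100.0,
            "alkaline_phosphatase": col("alkaline_phosphatase"),
            "leukocytes": col("leukocytes"),
        },
        index=cohort.index,
    )


# ---------------------------------------------------------------------------
# Klemera-Doubal biological age
# ---------------------------------------------------------------------------

@dataclass
class KdmCalibration:
    """Per-marker age regressions and the age-correction variance.

    For each selected marker j: x_j = q_j + k_j * age + e_j with residual
    SD s_j.  ``s_ba_sq`` weights chronological age in the corrected
    estimator; ``r`` records each marker's Pearson correlation with age.
    """

    markers: list[str]
    q: np.ndarray
    k: np.ndarray
    s: np.ndarray
    r: dict[str, float]
    s_ba_sq: float
    r_min: float
    age_range: tuple[float, float]

    def __len__(self) -> int:
        return len(self.markers)


def calibrate_kdm(
    reference: pd.DataFrame,
    candidates: list[str],
    r_min: float = 0.1,
    age_col: str = "age",
    exclude: tuple[str, ...] = (),
    s_ba: float | None = None,
    min_s: float = 1e-12,
) -> KdmCalibration:
    """Select age-correlated markers and fit per-marker age regressions.

    Candidates with |Pearson r| < ``r_min`` against age, or named in
    ``exclude`` (the missingness-based exclusion list), are dropped.  A
    residual SD of ~0 flags a marker that is a deterministic function of
    age; it is floored at ``min_s`` so the estimator (which weights by
    1/s^2) effectively pins to that marker.

    ``s_ba`` fixes the age-correction SD directly; when None it is
    estimated from the calibration sample following the original
    procedure: the variance of (uncorrected BA - age) minus the sampling
    contribution implied by the characteristic marker-age correlation.
    """
    age = reference[age_col].to_numpy(float)
    kept, qs, ks, ss, rs = [], [], [], [], {}
    for name in candidates:
        if name in exclude or name not in reference.columns:
            continue
        x = reference[name].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(age))
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            continue
        r = float(stats.pearsonr(age[ok], x[ok])[0])
        rs[name] = r
        if abs(r) < r_min:
            continue
        slope, intercept, _r, _p, _se = stats.linregress(age[ok], x[ok])
        resid = x[ok] - (intercept + slope * age[ok])
        s_j = float(np.sqrt(np.sum(resid**2) / max(ok.sum() - 2, 1)))
        kept.append(name)
        qs.append(float(intercept))
        ks.append(float(slope))
        ss.append(max(s_j, min_s))
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} marker(s) pass |r| >= {r_min}; need >= 2")

    cal = KdmCalibration(
        markers=kept,
        q=np.asarray(qs),
        k=np.asarray(ks),
        s=np.asarray(ss),
        r={n: rs[n] for n in kept},
        s_ba_sq=float(s_ba**2) if s_ba is not None else np.nan,
        r_min=r_min,
        age_range=(float(np.nanmin(age)), float(np.nanmax(age))),
    )
    if s_ba is None:
        cal.s_ba_sq = _estimate_s_ba_sq(reference, cal, age_col)
    return cal


def _estimate_s_ba_sq(reference: pd.DataFrame, cal: KdmCalibration, age_col: str) -> float:
    """s_BA^2 per the original derivation: spread of the uncorrected
    estimate around age, less the noise-driven part."""
    sub = reference.dropna(subset=cal.markers + [age_col])
    age = sub[age_col].to_numpy(float)
    ba_e = compute_kdm_age(sub, age, cal, corrected=False)
    diff = ba_e - age
    m = len(cal)
    r_char_sq = float(np.mean([cal.r[n] ** 2 for n in cal.markers]))
    r_char_sq = min(max(r_char_sq, 1e-6), 1 - 1e-6)
    span = cal.age_range[1] - cal.age_range[0]
    correction = ((1.0 - r_char_sq) / r_char_sq) * span**2 / (12.0 * m)
    est = float(np.var(diff)) - correction
    # floor: a non-positive estimate means markers explain age nearly fully
    return max(est, 1.0)


def compute_kdm_age(
    markers: dict[str, float] | pd.DataFrame,
    age: float | np.ndarray,
    cal: KdmCalibration,
    corrected: bool = True,
) -> float | np.ndarray:
    """Weighted KDM estimator.

    BA = [sum_j (x_j - q_j) k_j / s_j^2  (+ age / s_BA^2)] /
         [sum_j (k_j / s_j)^2            (+ 1 / s_BA^2)]

    with the age terms present only for the corrected variant (default).
    Noiseless markers x_j = q_j + k_j*age return chronological age exactly.
    """
    if len(cal) == 0:
        raise ValueError("empty KDM calibration")
    scalar = not isinstance(markers, pd.DataFrame)
    table = pd.DataFrame([markers]) if scalar else markers
    missing = [n for n in cal.markers if n not in table.columns]
    if missing:
        raise ValueError(f"calibrated marker(s) missing: {missing}")
    X = table[cal.markers].to_numpy(float)
    age_arr = np.atleast_1d(np.asarray(age, float))

    num = ((X - cal.q) * (cal.k / cal.s**2)).sum(axis=1)
    den = float(np.sum((cal.k / cal.s) ** 2))
    if corrected:
        if not np.isfinite(cal.s_ba_sq) or cal.s_ba_sq <= 0:
            raise ValueError("corrected estimator needs a positive s_BA^2")
        num = num + age_arr / cal.s_ba_sq
        den = den + 1.0 / cal.s_ba_sq
    ba = num / den
    return float(ba[0]) if scalar and ba.size == 1 else ba
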