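"""Synthetic longitudinal cohort generation.

Emulates a community-dwelling cohort of older adults (ages 67-84 at entry,
up to four annual visits) with demographics, daily macronutrient intakes
(kJ/day), ~30 raw micronutrient/subclass intakes organised in
high-correlation clusters, and the 30-biomarker panel with system-structured
covariance.  Ground-truth nutrient effects can be planted on biomarkers (or
whole-system latents) so that downstream surface and screen stages are
testable for parameter recovery.

The module also implements the dataset-construction steps used on real
data: the exclusive-dataset filters (diabetes, prescribed diet, BMI range,
weight fluctuation) and participant-mean income imputation.

Biomarker columns are stored with a ``bm_`` prefix to keep serum
concentrations (e.g. serum alpha-tocopherol, umol/L) distinct from dietary
intakes of the same compound (mg/day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import BiomarkerPanel, default_panel

__all__ = [
    "SimulationConfig",
    "EffectSpec",
    "BM_PREFIX",
    "MICRONUTRIENTS",
    "MACRONUTRIENTS",
    "default_cluster_members",
    "generate_cohort",
    "simulate_biomarkers",
    "simulate",
    "apply_exclusive_filters",
    "impute_income",
]

BM_PREFIX = "bm_"

MACRONUTRIENTS = ("protein_kj", "carbohydrate_kj", "lipid_kj")

# Canonical raw micronutrient/subclass intake variables: (name, mean, CV).
# Ordered so that the default cluster spec consumes the first 18 names; the
# remaining 12 are singletons, giving 7 + 12 = 19 reduced screen variables.
_MICRO_DEFS = [
    # cluster 1: B vitamins (4)
    ("thiamin", 1.4, 0.40),
    ("riboflavin", 1.8, 0.40),
    ("niacin", 20.0, 0.40),
    ("vitamin_b6", 1.7, 0.40),
    # cluster 2: bone minerals (3)
    ("calcium", 900.0, 0.40),
    ("phosphorus", 1200.0, 0.35),
    ("magnesium", 300.0, 0.35),
    # cluster 3: trace minerals (3)
    ("zinc", 10.0, 0.40),
    ("iron", 13.0, 0.40),
    ("copper", 1.3, 0.40),
    # cluster 4: major fatty-acid subclasses (2)
    ("saturated_fat", 25.0, 0.40),
    ("monounsaturated_fat", 27.0, 0.40),
    # cluster 5: carotenes (2)
    ("alpha_carotene", 0.6, 0.60),
    ("beta_carotene", 3.5, 0.60),
    # cluster 6: long-chain omega-3 (2)
    ("epa", 0.10, 0.60),
    ("dha", 0.20, 0.60),
    # cluster 7: vegetable-linked (2)
    ("potassium", 2900.0, 0.35),
    ("dietary_folate", 350.0, 0.40),
    # singletons (12)
    ("alpha_tocopherol", 4.75, 0.575),
    ("vitamin_c", 120.0, 0.50),
    ("trans_fatty_acids", 2.5, 0.50),
    ("vitamin_d", 6.0, 0.50),
    ("vitamin_k", 90.0, 0.50),
    ("vitamin_b12", 4.0, 0.50),
    ("selenium", 100.0, 0.40),
    ("sodium", 2800.0, 0.35),
    ("manganese", 3.5, 0.40),
    ("dietary_cholesterol", 250.0, 0.45),
    ("polyunsaturated_fat", 13.0, 0.40),
    ("caffeine", 200.0, 0.60),
]

MICRONUTRIENTS = tuple(name for name, _, _ in _MICRO_DEFS)

# Macronutrient requirement functions (kJ/day): intercept + coefficients on
# weight (kg), height (cm), age - 75 (years), male indicator, PASE score.
_MACRO_REQ = {
    "protein_kj": (500.0, 14.0, 2.0, -5.0, 150.0, 1.0),
    "carbohydrate_kj": (1500.0, 20.0, 6.0, -10.0, 300.0, 3.0),
    "lipid_kj": (800.0, 18.0, 3.0, -8.0, 200.0, 1.5),
}

# Default per-year age slopes (in transformed-scale SD units, centred at 75)
# planted on a subset of markers so that biological-age calibration has
# age-correlated markers to select.
_DEFAULT_AGE_SLOPES = {
    "hemoglobin": -0.05,
    "rbc": -0.04,
    "mcv": 0.03,
    "rdw": 0.05,
    "albumin": -0.06,
    "creatinine": 0.05,
    "folate": 0.04,
    "monocytes": 0.04,
    "lymphocytes": -0.04,
    "uric_acid": 0.03,
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted ground-truth nutrient effect on a biomarker.

    ``target`` is a panel marker name or ``"system:<label>"`` for a whole
    system latent.  ``nutrient`` names one intake variable (two for saddle /
    interaction shapes).  Coefficients act on standardized scales: the
    nutrient is standardized over the generated sample; the response is
    added in transformed-scale SD units of the marker.
    """

    target: str
    nutrient: str | tuple[str, str]
    shape: str  # {"linear", "quadratic", "saddle", "interaction"}
    coefficients: tuple[float, ...]
    optimum: float | None = None

    _ARITY = {"linear": 1, "quadratic": 1, "saddle": 2, "interaction": 1}

    def __post_init__(self) -> None:
        if self.shape not in self._ARITY:
            raise ValueError(f"EffectSpec.shape: unknown shape {self.shape!r}")
        if len(self.coefficients) != self._ARITY[self.shape]:
            raise ValueError(
                f"EffectSpec.coefficients: shape {self.shape!r} takes "
                f"{self._ARITY[self.shape]} coefficient(s)"
            )
        n_nutrients = 2 if self.shape in ("saddle", "interaction") else 1
        nutrients = self.nutrient if isinstance(self.nutrient, tuple) else (self.nutrient,)
        if len(nutrients) != n_nutrients:
            raise ValueError(
                f"EffectSpec.nutrient: shape {self.shape!r} takes {n_nutrients} nutrient(s)"
            )
        if self.optimum is not None and self.shape != "quadratic":
            raise ValueError("EffectSpec.optimum: only defined for quadratic shapes")

    def response(self, z: np.ndarray, z2: np.ndarray | None = None) -> np.ndarray:
        if self.shape == "linear":
            return self.coefficients[0] * z
        if self.shape == "quadratic":
            opt = self.optimum if self.optimum is not None else 0.0
            return self.coefficients[0] * (z - opt) ** 2
        if self.shape == "saddle":
            return self.coefficients[0] * z**2 - self.coefficients[1] * z2**2
        # interaction
        return self.coefficients[0] * z * z2


def default_cluster_spec() -> list[tuple[int, float]]:
    """Seven planted high-correlation clusters: sizes 4,3,3,2,2,2,2."""
    return [(4, 0.8), (3, 0.8), (3, 0.8), (2, 0.8), (2, 0.8), (2, 0.8), (2, 0.8)]


def default_cluster_members(
    spec: Sequence[tuple[int, float]] | None = None,
) -> list[tuple[str, ...]]:
    """Assign canonical nutrient names to the cluster spec, in order."""
    spec = default_cluster_spec() if spec is None else spec
    members, i = [], 0
    for size, _r in spec:
        members.append(tuple(MICRONUTRIENTS[i : i + size]))
        i += size
    if i > len(MICRONUTRIENTS):
        raise ValueError("micronutrient_clusters: cluster sizes exceed available nutrients")
    return members


@dataclass
class SimulationConfig:
    n_subjects: int = 1560
    n_visits: int = 4
    seed: int = 0
    age_range: tuple[float, float] = (67.0, 84.0)
    income_missing_rate: float = 0.31
    micronutrient_clusters: list[tuple[int, float]] = field(default_factory=default_cluster_spec)
    between_cluster_r: float = 0.1
    planted_effects: list[EffectSpec] = field(default_factory=list)
    biomarker_system_correlation: float = 0.3
    biomarker_noise_sd: float = 1.0
    age_slopes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AGE_SLOPES))
    dropout_rate: float = 0.10
    macro_noise_sd: float = 0.25  # log-scale visit noise on macronutrients
    macro_subject_sd: float = 0.15  # log-scale subject-level persistence
    prop_men: float = 0.48

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        for name in ("income_missing_rate", "dropout_rate", "prop_men",
                     "biomarker_system_correlation", "between_cluster_r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.age_range
        if not (67.0 <= lo < hi <= 84.0):
            raise ValueError("age_range must lie within [67, 84]")
        for size, r in self.micronutrient_clusters:
            if size < 2:
                raise ValueError("micronutrient_clusters: cluster size must be >= 2")
            if not -1.0 < r < 1.0:
                raise ValueError("micronutrient_clusters: correlation must be in (-1, 1)")
        if self.biomarker_noise_sd < 0:
            raise ValueError("biomarker_noise_sd must be >= 0")
        default_cluster_members(self.micronutrient_clusters)  # size check


def _rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate demographics and nutrient intakes (biomarkers left empty).

    One row per subject-visit.  Macronutrient intake is log-normal around a
    requirement function linear in weight, height, age, sex and PASE, so
    relative-intake estimation has recoverable signal.  Micronutrients are
    drawn from the configured block-correlation structure.  Income is
    missing completely at random at the configured per-row rate.
    """
    config.validate()
    rng = _rng(config)
    n, v = config.n_subjects, config.n_visits
    lo, hi = config.age_range

    # subject-level draws
    age0 = rng.uniform(lo, hi, n)
    men = rng.random(n) < config.prop_men
    height = np.where(men, rng.normal(1.72, 0.07, n), rng.normal(1.58, 0.06, n))
    bmi0 = np.clip(rng.normal(27.0, 3.5, n), 17.0, 42.0)
    weight0 = bmi0 * height**2
    pase = np.clip(rng.normal(90.0, 40.0, n), 0.0, None)
    education = np.clip(np.round(rng.normal(11.0, 4.0, n)), 4, 22)
    income = np.round(np.exp(rng.normal(np.log(30000.0), 0.45, n)), -2)
    smoking = rng.random(n) < 0.08
    alcohol = np.round(rng.gamma(1.2, 7.0, n), 1)
    comorbid = rng.poisson(3.0, n)
    diabetes = rng.random(n) < 0.12
    rx_diet = rng.random(n) < 0.10
    macro_subject = rng.normal(0.0, config.macro_subject_sd, (n, 3))

    # monotone dropout: subject attends visits 1..k
    attend = np.ones((n, v), dtype=bool)
    for t in range(1, v):
        attend[:, t] = attend[:, t - 1] & (rng.random(n) >= config.dropout_rate)

    rows = []
    for t in range(v):
        keep = attend[:, t]
        idx = np.flatnonzero(keep)
        m = idx.size
        if m == 0:
            continue
        age_t = age0[idx] + t
        weight_t = weight0[idx] * (1.0 + rng.normal(0.0, 0.015, m))
        height_t = height[idx]
        df = pd.DataFrame(
            {
                "subject_id": idx,
                "visit": t + 1,
                "age": age_t,
                "sex": np.where(men[idx], "men", "women"),
                "height_m": height_t,
                "weight_kg": weight_t,
                "bmi": weight_t / height_t**2,
                "pase": pase[idx],
                "income": income[idx],
                "education_years": education[idx],
                "smoking": np.where(smoking[idx], "current", "not_current"),
                "alcohol_g_day": alcohol[idx],
                "comorbidity_count": comorbid[idx],
                "diabetes": diabetes[idx],
                "prescribed_diet": rx_diet[idx],
            }
        )
        # macronutrients: requirement * lognormal noise
        male = (df["sex"] == "men").to_numpy(float)
        for j, macro in enumerate(MACRONUTRIENTS):
            b0, bw, bh, ba, bs, bp = _MACRO_REQ[macro]
            req = (
                b0
                + bw * weight_t
                + bh * height_t * 100.0
                + ba * (age_t - 75.0)
                + bs * male
                + bp * pase[idx]
            )
            noise = macro_subject[idx, j] + rng.normal(0.0, config.macro_noise_sd, m)
            df[macro] = req * np.exp(noise - config.macro_noise_sd**2 / 2)
        # micronutrients: block-correlated Gaussian copula -> lognormal
        df = pd.concat([df, _draw_micronutrients(config, rng, m)], axis=1)
        rows.append(df)

    cohort = pd.concat(rows, ignore_index=True)
    cohort = cohort.sort_values(["subject_id", "visit"], ignore_index=True)
    # MCAR income missingness
    miss = rng.random(len(cohort)) < config.income_missing_rate
    cohort.loc[miss, "income"] = np.nan
    return cohort


def _draw_micronutrients(
    config: SimulationConfig, rng: np.random.Generator, m: int
) -> pd.DataFrame:
    """Correlated lognormal intakes: a global factor links all nutrients at
    ``between_cluster_r``; each cluster adds a shared factor to reach its
    within-cluster correlation."""
    members = default_cluster_members(config.micronutrient_clusters)
    clustered = {name: (ci, r) for ci, ((_, r), names) in
                 enumerate(zip(config.micronutrient_clusters, members)) for name in names}
    rb = config.between_cluster_r
    g = rng.normal(0.0, 1.0, m)
    factors = {ci: rng.normal(0.0, 1.0, m) for ci in range(len(members))}
    defs = {name: (mean, cv) for name, mean, cv in _MICRO_DEFS}
    out = {}
    for name in MICRONUTRIENTS:
        mean, cv = defs[name]
        if name in clustered:
            ci, rw = clustered[name]
            z = (
                np.sqrt(rb) * g
                + np.sqrt(max(rw - rb, 0.0)) * factors[ci]
                + np.sqrt(max(1.0 - max(rw, rb), 0.0)) * rng.normal(0.0, 1.0, m)
            )
        else:
            z = np.sqrt(rb) * g + np.sqrt(1.0 - rb) * rng.normal(0.0, 1.0, m)
        sigma = np.sqrt(np.log1p(cv**2))
        out[name] = mean * np.exp(sigma * z - sigma**2 / 2)
    return pd.DataFrame(out)


# auxiliary (non-panel) serum markers needed by the biological-age stage
_AUX_MARKERS = [("glucose", "mmol/L", "none", "none", 5.4, 0.8)]


def simulate_biomarkers(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    panel: BiomarkerPanel | None = None,
) -> pd.DataFrame:
    """Fill ``bm_`` biomarker columns on a generated cohort.

    Each system's markers load on a shared latent factor at the configured
    correlation; planted :class:`EffectSpec` entries perturb the targeted
    marker (or system latent) as a function of standardized intakes; age
    slopes add a linear trend on the transformed scale.  With
    ``biomarker_noise_sd = 0`` and no effects, every marker equals its
    configured baseline mean exactly.
    """
    config.validate()
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed + 1)
    out = cohort.copy()
    m = len(out)
    rho = config.biomarker_system_correlation
    noise_sd = config.biomarker_noise_sd

    # validate effect targets / nutrients up front
    valid_targets = set(panel.names) | {f"system:{s}" for s in panel.systems}
    nutrient_cols = set(MICRONUTRIENTS) | set(MACRONUTRIENTS)
    for eff in config.planted_effects:
        if eff.target not in valid_targets:
            raise ValueError(f"EffectSpec target {eff.target!r} is not a marker or system")
        for nut in (eff.nutrient if isinstance(eff.nutrient, tuple) else (eff.nutrient,)):
            if nut not in nutrient_cols or nut not in out.columns:
                raise ValueError(f"EffectSpec nutrient {nut!r} is not an intake variable")

    def z_of(col: str) -> np.ndarray:
        x = out[col].to_numpy(float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    def effect_sum(target: str) -> np.ndarray:
        total = np.zeros(m)
        for eff in config.planted_effects:
            if eff.target != target:
                continue
            nuts = eff.nutrient if isinstance(eff.nutrient, tuple) else (eff.nutrient,)
            z1 = z_of(nuts[0])
            z2 = z_of(nuts[1]) if len(nuts) > 1 else None
            total += eff.response(z1, z2)
        return total

    latents = {s: rng.normal(0.0, 1.0, m) + effect_sum(f"system:{s}") for s in panel.systems}
    age_dev = out["age"].to_numpy(float) - 75.0

    for marker in panel.markers:
        if marker.system != "none":
            shared = latents[marker.system]
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, m)
        else:
            z = rng.normal(0.0, 1.0, m)
        z = noise_sd * z
        z = z + config.age_slopes.get(marker.name, 0.0) * age_dev
        z = z + effect_sum(marker.name)
        out[BM_PREFIX + marker.name] = _from_standardized(marker, z)

    for name, _units, _system, transform, mean, sd in _AUX_MARKERS:
        z = noise_sd * rng.normal(0.0, 1.0, m) + 0.02 * age_dev
        out[BM_PREFIX + name] = mean + sd * z if transform == "none" else np.exp(
            np.log(mean) + np.sqrt(np.log1p((sd / mean) ** 2)) * z
        )
    return out


def _from_standardized(marker, z: np.ndarray) -> np.ndarray:
    """Map transformed-scale standardized deviations back to the
    measurement scale, anchored so z = 0 gives the configured mean."""
    if marker.transform == "log":
        sigma = np.sqrt(np.log1p((marker.sd / marker.mean) ** 2))
        return np.exp(np.log(marker.mean) + sigma * z)
    if marker.transform == "sqrt":
        return (np.sqrt(marker.mean) + 0.5 * marker.sd / np.sqrt(marker.mean) * z) ** 2
    return marker.mean + marker.sd * z


def simulate(config: SimulationConfig, panel: BiomarkerPanel | None = None) -> pd.DataFrame:
    """Convenience: generate demographics/intakes and fill biomarkers."""
    return simulate_biomarkers(generate_cohort(config), config, panel)


# ---------------------------------------------------------------------------
# dataset-construction steps (used for real and synthetic data alike)
# ---------------------------------------------------------------------------

def apply_exclusive_filters(
    cohort: pd.DataFrame,
    bmi_range: tuple[float, float] = (22.0, 29.9),
    weight_cv_max: float = 0.04,
) -> pd.DataFrame:
    """Exclusive-dataset filters.

    Removes observations where the subject is diabetic, on a medically
    prescribed diet, or has BMI strictly outside ``bmi_range`` (bounds
    inclusive: 22.0 and 29.9 are retained); then removes every observation
    of subjects whose weight coefficient of variation (population SD / mean
    over their surviving observations) exceeds ``weight_cv_max``.  Subjects
    with any missing weight are excluded.  Applying the filter twice yields
    the same table.
    """
    df = cohort.copy()
    missing_weight = df.groupby("subject_id")["weight_kg"].transform(lambda s: s.isna().any())
    df = df[~missing_weight]

    lo, hi = bmi_range
    bmi = df["bmi"] if "bmi" in df else df["weight_kg"] / df["height_m"] ** 2
    row_ok = (~df["diabetes"].astype(bool)) & (~df["prescribed_diet"].astype(bool))
    row_ok &= (bmi >= lo) & (bmi <= hi)
    df = df[row_ok]

    def _cv(s: pd.Series) -> float:
        mu = s.mean()
        return float(s.std(ddof=0) / mu) if mu > 0 else np.inf

    cv = df.groupby("subject_id")["weight_kg"].transform(_cv)
    return df[cv <= weight_cv_max].copy()


def impute_income(cohort: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing income with the participant's mean observed
    income; participants with no observed income stay missing (and fall out
    of complete-case assembly)."""
    df = cohort.copy()
    subject_mean = df.groupby("subject_id")["income"].transform("mean")
    df["income"] = df["income"].fillna(subject_mean)
    return df
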