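"""The standard model battery for nutrient-ageing response surfaces.

Eight numbered specifications plus the screen model, all sharing the same
chassis — outcome = log+Z score, subject random intercept, and one or two
isotropic three-dimensional nutrient smooths:

========  ===========================================  ====================
model id  nutrient smooth(s)                           covariates
========  ===========================================  ====================
1         absolute macronutrients (kJ/day)             none
2         relative macronutrient intake (%)            none
3         relative macronutrients                      confounders
4         relative macronutrients                      confounders + comorb.
5         micronutrient triple                         confounders
6         micronutrient triple                         confounders + comorb.
7         micronutrients + relative macronutrients     confounders
8         micronutrients + relative macronutrients     confounders + comorb.
screen    micronutrient triple                         none
========  ===========================================  ====================

Confounders: income, education years, alcohol intake, PASE and age as
one-dimensional smooths (numeric, Z-scaled internally); sex and smoking
status as parametric terms.  Comorbidity count joins the numeric set in
the even-numbered variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import GAM, Categorical, GAMResults, RandomIntercept, Smooth

__all__ = [
    "ModelSpec",
    "build_model_spec",
    "fit_gam",
    "predict_at",
    "compare_models_aic",
    "CONFOUNDERS_NUMERIC",
    "CONFOUNDERS_CATEGORICAL",
    "DEFAULT_MICRO_TRIPLE",
    "RELATIVE_MACROS",
]

from .simulate import MACRONUTRIENTS

RELATIVE_MACROS = tuple("rel_" + m for m in MACRONUTRIENTS)
CONFOUNDERS_NUMERIC = ("income", "education_years", "alcohol_g_day", "pase", "age")
CONFOUNDERS_CATEGORICAL = ("sex", "smoking")
COMORBIDITY = "comorbidity_count"
#: focal micronutrient combination examined in depth by models 5-8
DEFAULT_MICRO_TRIPLE = ("alpha_tocopherol", "vitamin_c", "trans_fatty_acids")

#: default covariate profile for population-level predictions
DEFAULT_PROFILE = {"sex": "men", "smoking": "not_current"}

_VALID_IDS = (1, 2, 3, 4, 5, 6, 7, 8, "screen")


@dataclass
class ModelSpec:
    model_id: int | str
    outcome: str
    smooth_triples: list[tuple[str, str, str]]
    covariates_numeric: tuple[str, ...] = ()
    covariates_categorical: tuple[str, ...] = ()
    random_intercept: str = "subject_id"
    k: int = 30  # basis dimension of each 3-D nutrient smooth
    k_covariate: int = 10

    @property
    def variables(self) -> list[str]:
        out = [self.outcome]
        for triple in self.smooth_triples:
            out += list(triple)
        out += list(self.covariates_numeric) + list(self.covariates_categorical)
        out.append(self.random_intercept)
        return out

    def terms(self):
        terms = [Smooth(t, k=self.k) for t in self.smooth_triples]
        terms += [Smooth(c, k=self.k_covariate) for c in self.covariates_numeric]
        terms += [Categorical(c) for c in self.covariates_categorical]
        terms.append(RandomIntercept(self.random_intercept))
        return terms


def build_model_spec(
    model_id: int | str,
    outcome: str,
    macro_vars: tuple[str, str, str] = MACRONUTRIENTS,
    relative_vars: tuple[str, str, str] = RELATIVE_MACROS,
    micro_triple: tuple[str, str, str] = DEFAULT_MICRO_TRIPLE,
    **overrides,
) -> ModelSpec:
    """Assemble the ModelSpec for one of the numbered variants."""
    if model_id not in _VALID_IDS:
        raise ValueError(f"unknown model id {model_id!r}; valid: {_VALID_IDS}")
    smooths: list[tuple[str, str, str]]
    if model_id == 1:
        smooths, confounded = [tuple(macro_vars)], False
    elif model_id == 2:
        smooths, confounded = [tuple(relative_vars)], False
    elif model_id in (3, 4):
        smooths, confounded = [tuple(relative_vars)], True
    elif model_id in (5, 6):
        smooths, confounded = [tuple(micro_triple)], True
    elif model_id in (7, 8):
        smooths, confounded = [tuple(micro_triple), tuple(relative_vars)], True
    else:  # screen
        smooths, confounded = [tuple(micro_triple)], False
    numeric: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    if confounded:
        numeric = CONFOUNDERS_NUMERIC
        categorical = CONFOUNDERS_CATEGORICAL
        if model_id in (4, 6, 8):
            numeric = numeric + (COMORBIDITY,)
    return ModelSpec(
        model_id=model_id,
        outcome=outcome,
        smooth_triples=smooths,
        covariates_numeric=numeric,
        covariates_categorical=categorical,
        **overrides,
    )


@dataclass
class FitSummary:
    """A fitted specification: the GAMResults plus its provenance."""

    spec: ModelSpec
    results: GAMResults

    @property
    def aic(self) -> float:
        return self.results.aic

    @property
    def deviance_explained(self) -> float:
        return self.results.deviance_explained

    @property
    def nobs(self) -> int:
        return self.results.nobs

    @property
    def converged(self) -> bool:
        return self.results.converged

    def smooth_terms(self) -> pd.DataFrame:
        return self.results.smooth_terms()

    def summary(self) -> str:
        head = f"Model {self.spec.model_id}  (outcome: {self.spec.outcome})\n"
        return head + self.results.summary()


def fit_gam(spec: ModelSpec, data: pd.DataFrame, min_n: int = 30) -> FitSummary:
    """Fit a specification on the complete cases of its variables."""
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks column(s): {missing}")
    complete = data.dropna(subset=spec.variables)
    if len(complete) < min_n:
        raise ValueError(f"only {len(complete)} complete rows; minimum is {min_n}")
    model = GAM(complete, spec.outcome, spec.terms())
    return FitSummary(spec=spec, results=model.fit())


def predict_at(
    fit: FitSummary | GAMResults,
    nutrient_values: dict[str, float],
    covariate_profile: dict[str, object] | None = None,
) -> tuple[float, float]:
    """Population-level prediction (and SE) at stated nutrient values.

    Unspecified numeric inputs default to their training-sample mean;
    unspecified categorical inputs default to men / non-smoker.  The
    random intercept is set to zero (population level).
    """
    results = fit.results if isinstance(fit, FitSummary) else fit
    model = results.model
    profile = dict(DEFAULT_PROFILE)
    profile.update(covariate_profile or {})
    row: dict[str, object] = {}
    for t in model.terms:
        if isinstance(t, RandomIntercept):
            continue
        cols = list(t.variables) if isinstance(t, Smooth) else [t.variable]
        for c in cols:
            if c in nutrient_values:
                row[c] = float(nutrient_values[c])
            elif c in profile:
                row[c] = profile[c]
            elif np.issubdtype(model.data[c].dtype, np.number):
                row[c] = float(model.data[c].mean())
            else:
                raise ValueError(f"profile missing required covariate {c!r}")
    newdata = pd.DataFrame([row])
    pred, se = results.predict(newdata, se=True, include_random=False)
    return float(pred[0]), float(se[0])


def compare_models_aic(fits: list[FitSummary], margin: float = 2.0) -> pd.DataFrame:
    """Rank fits of the same outcome by AIC.

    A model is flagged ``favoured`` only when its AIC advantage over every
    other model exceeds ``margin`` points; smaller differences are treated
    as equivalent fits.  Fits on differing estimation samples are not
    comparable and raise.
    """
    if not fits:
        raise ValueError("no fits to compare")
    outcomes = {f.spec.outcome for f in fits}
    if len(outcomes) > 1:
        raise ValueError(f"fits have differing outcomes: {sorted(outcomes)}")
    sizes = {f.nobs for f in fits}
    if len(sizes) > 1:
        raise ValueError(f"fits have differing sample sizes: {sorted(sizes)} (AIC not comparable)")
    table = pd.DataFrame(
        {
            "model": [f.spec.model_id for f in fits],
            "aic": [f.aic for f in fits],
            "deviance_explained": [f.deviance_explained for f in fits],
            "n": [f.nobs for f in fits],
        }
    )
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best = table["aic"].idxmin()
    others = table.drop(index=best)
    table["favoured"] = False
    if len(others) == 0 or (others["aic"] - table.loc[best, "aic"] > margin).all():
        if len(fits) > 1:
            table.loc[best, "favoured"] = True
    return table.sort_values("aic", ignore_index=True)
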