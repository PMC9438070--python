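"""Nutrient predictor construction.

Two predictor sets feed the response-surface models:

* **Relative macronutrient intake** — percent above/below the intake that
  is typical for a person of given age, sex, weight, height and physical
  activity, estimated from a per-macronutrient regression of intake on
  those variables.  A value of 100 means eating 100% more (in kJ/day) than
  is typical; 0 means eating the typical amount.

* **Reduced micronutrient set** — raw micronutrient intakes are often very
  highly correlated because they co-occur in foods.  Intakes are clustered
  hierarchically on the correlation distance 1 - r; clusters whose members
  all correlate above a threshold (default r > 0.65) are summarized by the
  first principal component of their standardized intakes (sign-oriented to
  correlate positively with members), yielding a minimally correlated set
  of screen variables, each Z-scaled with stored parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TypicalIntakeModel",
    "fit_typical_intake",
    "relative_intake",
    "add_relative_intakes",
    "ClusterSolution",
    "cluster_micronutrients",
    "ReducedNutrientSet",
    "reduce_to_pc1",
]

from .simulate import MACRONUTRIENTS, MICRONUTRIENTS


@dataclass
class TypicalIntakeModel:
    """Fitted predictors of typical daily intake (kJ/day), one per
    macronutrient, from age, sex, weight, height and PASE."""

    models: dict[str, object]  # macronutrient -> statsmodels results
    predictors: tuple[str, ...] = ("age", "sex", "weight_kg", "height_m", "pase")

    def predict(self, cohort: pd.DataFrame, macronutrient: str) -> np.ndarray:
        pred = np.asarray(self.models[macronutrient].predict(cohort), float)
        if np.any(pred <= 0):
            # keep predictions usable as a divisor: floor at 1% of the
            # fitted mean (only reachable far outside the training domain)
            floor = 0.01 * float(np.mean(self.models[macronutrient].fittedvalues))
            pred = np.maximum(pred, floor)
        return pred

    def diagnostics(self) -> pd.DataFrame:
        rows = [
            {
                "macronutrient": m,
                "r_squared": res.rsquared,
                "n": int(res.nobs),
                "resid_sd": float(np.sqrt(res.mse_resid)),
            }
            for m, res in self.models.items()
        ]
        return pd.DataFrame(rows)


def fit_typical_intake(
    cohort: pd.DataFrame,
    macronutrients: tuple[str, ...] = MACRONUTRIENTS,
) -> TypicalIntakeModel:
    """Linear regression of intake on age, sex, weight, height and PASE."""
    needed = ["age", "sex", "weight_kg", "height_m", "pase", *macronutrients]
    data = cohort.dropna(subset=needed)
    for col in ("age", "weight_kg", "height_m", "pase"):
        if data[col].nunique() < 2:
            raise ValueError(f"degenerate design: predictor {col!r} is constant")
    models = {}
    for m in macronutrients:
        models[m] = smf.ols(
            f"{m} ~ age + C(sex) + weight_kg + height_m + pase", data=data
        ).fit()
    return TypicalIntakeModel(models=models)


def relative_intake(observed, predicted):
    """Percent deviation from typical: 100 * (observed - predicted) / predicted."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if np.any(predicted <= 0):
        raise ValueError("predicted intake must be > 0")
    return 100.0 * (observed - predicted) / predicted


def add_relative_intakes(
    cohort: pd.DataFrame,
    model: TypicalIntakeModel,
    macronutrients: tuple[str, ...] = MACRONUTRIENTS,
) -> pd.DataFrame:
    """Append ``rel_<macronutrient>`` percent columns."""
    out = cohort.copy()
    for m in macronutrients:
        out["rel_" + m] = relative_intake(out[m].to_numpy(float), model.predict(out, m))
    return out


# ---------------------------------------------------------------------------
# correlation clustering and PC1 reduction
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Hierarchical clustering of nutrient intakes on distance 1 - r."""

    nutrients: list[str]
    correlation: pd.DataFrame
    linkage_matrix: np.ndarray
    linkage_method: str
    r_threshold: float
    clusters: list[tuple[str, ...]]  # multi-member clusters only
    singletons: list[str]

    @property
    def n_reduced(self) -> int:
        return len(self.clusters) + len(self.singletons)


def cluster_micronutrients(
    intakes: pd.DataFrame,
    nutrients: list[str] | None = None,
    r_threshold: float = 0.65,
    method: str = "complete",
) -> ClusterSolution:
    """Agglomerative clustering of intakes on 1 - Pearson r.

    With complete linkage, cutting the tree at height 1 - r_threshold
    yields exactly the groups in which every within-cluster pairwise
    correlation is >= the threshold; everything else stays a singleton.
    """
    nutrients = list(nutrients) if nutrients is not None else [
        c for c in MICRONUTRIENTS if c in intakes.columns
    ]
    if len(nutrients) < 2:
        raise ValueError("need at least 2 nutrients to cluster")
    if len(intakes) < 3:
        raise ValueError("need at least 3 observations to estimate correlations")
    if len(set(nutrients)) != len(nutrients):
        raise ValueError("duplicate nutrient names")
    X = intakes[nutrients]
    constant = [n for n in nutrients if X[n].std() == 0]
    if constant:
        raise ValueError(f"constant nutrient column(s), correlation undefined: {constant}")
    corr = X.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    labels = hierarchy.fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for name, lab in zip(nutrients, labels):
        groups.setdefault(lab, []).append(name)
    clusters = [tuple(g) for g in groups.values() if len(g) > 1]
    singles = [g[0] for g in groups.values() if len(g) == 1]
    # deterministic ordering by first-member position in the input list
    order = {n: i for i, n in enumerate(nutrients)}
    clusters.sort(key=lambda c: order[c[0]])
    singles.sort(key=lambda n: order[n])
    return ClusterSolution(
        nutrients=nutrients,
        correlation=corr,
        linkage_matrix=Z,
        linkage_method=method,
        r_threshold=r_threshold,
        clusters=clusters,
        singletons=singles,
    )


@dataclass
class ReducedNutrientSet:
    """The reduced screen variables: singleton nutrients plus cluster PC1s.

    Per cluster: loadings on standardized member intakes, the proportion of
    member variance PC1 explains, and the orientation sign; per output
    variable: the Z-scaling mean/SD fitted on the derivation sample so the
    reduction can be re-applied to new data without refitting.
    """

    variables: list[str]
    clusters: dict[str, tuple[str, ...]] = field(default_factory=dict)
    loadings: dict[str, np.ndarray] = field(default_factory=dict)
    variance_explained: dict[str, float] = field(default_factory=dict)
    member_scaling: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    z_mean: dict[str, float] = field(default_factory=dict)
    z_sd: dict[str, float] = field(default_factory=dict)

    def transform(self, intakes: pd.DataFrame) -> pd.DataFrame:
        """Apply stored loadings and scalings to (possibly new) data."""
        out = {}
        for var in self.variables:
            if var in self.clusters:
                members = list(self.clusters[var])
                mu, sd = self.member_scaling[var]
                Z = (intakes[members].to_numpy(float) - mu) / sd
                raw = Z @ self.loadings[var]
            else:
                raw = intakes[var].to_numpy(float)
            out[var] = (raw - self.z_mean[var]) / self.z_sd[var]
        return pd.DataFrame(out, index=intakes.index)


def reduce_to_pc1(
    intakes: pd.DataFrame,
    clusters: ClusterSolution,
    cluster_names: dict[tuple[str, ...], str] | None = None,
) -> ReducedNutrientSet:
    """Summarize each multi-member cluster by the PC1 of its standardized
    member intakes (correlation-scale PCA), oriented to correlate
    non-negatively with members; Z-scale every output variable."""
    rs = ReducedNutrientSet(variables=[])
    for members in clusters.clusters:
        name = (cluster_names or {}).get(members) or "pc1_" + "_".join(m[:4] for m in members)
        X = intakes[list(members)].to_numpy(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        Z = (X - mu) / sd
        corr = np.corrcoef(Z, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        v1 = eigvecs[:, -1]
        scores = Z @ v1
        # orient so correlations with member intakes are non-negative
        member_corr = np.array([np.corrcoef(scores, Z[:, j])[0, 1] for j in range(Z.shape[1])])
        if member_corr.sum() < 0:
            v1, scores, member_corr = -v1, -scores, -member_corr
        rs.variables.append(name)
        rs.clusters[name] = members
        rs.loadings[name] = v1
        rs.variance_explained[name] = float(eigvals[-1] / eigvals.sum())
        rs.member_scaling[name] = (mu, sd)
        rs.z_mean[name] = float(scores.mean())
        rs.z_sd[name] = float(scores.std(ddof=0))
    for name in clusters.singletons:
        x = intakes[name].to_numpy(float)
        rs.variables.append(name)
        rs.z_mean[name] = float(x.mean())
        rs.z_sd[name] = float(x.std(ddof=0))
    return rs
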