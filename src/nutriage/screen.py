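"""Combinatorial micronutrient screening.

Every unordered triple of the reduced micronutrient variables is fitted as
a three-dimensional smooth (plus subject random intercept, no confounders)
against each outcome score; smooth-term p-values are corrected for the
false discovery rate by Benjamini-Hochberg step-up and tallied.  With 19
reduced variables there are C(19,3) = 969 triples per outcome.

The screen is resumable: an append-only checkpoint file keyed by
(triple, outcome) lets an interrupted run pick up where it stopped, and
fits are independent so the work parallelizes trivially.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .models import ModelSpec, build_model_spec, fit_gam, predict_at

__all__ = [
    "enumerate_triples",
    "run_screen",
    "bh_fdr",
    "flag_screen",
    "tally_screen",
    "predict_sd_shift",
]

logger = logging.getLogger(__name__)

TRIPLE_SEP = "+"


def enumerate_triples(variables: list[str]) -> list[tuple[str, str, str]]:
    """All C(n, 3) unordered triples in deterministic lexicographic order."""
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variable names")
    if len(variables) < 3:
        raise ValueError("need at least 3 variables")
    return list(itertools.combinations(sorted(variables), 3))


def _triple_key(triple: tuple[str, str, str]) -> str:
    return TRIPLE_SEP.join(triple)


def run_screen(
    triples: list[tuple[str, str, str]],
    outcomes: list[str],
    data: pd.DataFrame,
    k: int = 30,
    min_n: int = 30,
    checkpoint: str | Path | None = None,
    max_failure_rate: float = 0.2,
) -> pd.DataFrame:
    """Fit the screen GAM for every triple x outcome.

    Returns one row per fit with the smooth-term p-value, edf, deviance
    explained and sample size.  Individual fit failures are recorded (p
    missing) rather than fatal; the run aborts only if the failure rate
    exceeds ``max_failure_rate``.  With ``checkpoint`` set, completed fits
    are appended to a CSV and skipped on re-runs.
    """
    done: dict[tuple[str, str], dict] = {}
    ckpt_path = Path(checkpoint) if checkpoint else None
    if ckpt_path and ckpt_path.exists():
        prior = pd.read_csv(ckpt_path)
        for _, row in prior.iterrows():
            done[(row["triple"], row["outcome"])] = row.to_dict()
        logger.info("screen checkpoint: %d fit(s) already done", len(done))

    rows, failures, total = [], 0, 0
    for triple in triples:
        key = _triple_key(triple)
        for outcome in outcomes:
            total += 1
            if (key, outcome) in done:
                rows.append(done[(key, outcome)])
                continue
            record = {
                "triple": key,
                "var1": triple[0],
                "var2": triple[1],
                "var3": triple[2],
                "outcome": outcome,
                "p": np.nan,
                "edf": np.nan,
                "deviance_explained": np.nan,
                "n": 0,
                "converged": False,
            }
            try:
                spec = build_model_spec("screen", outcome, micro_triple=triple, k=k)
                fit = fit_gam(spec, data, min_n=min_n)
                tab = fit.smooth_terms()
                record.update(
                    p=float(tab["p"].iloc[0]),
                    edf=float(tab["edf"].iloc[0]),
                    deviance_explained=fit.deviance_explained,
                    n=fit.nobs,
                    converged=fit.converged,
                )
            except Exception as exc:  # fit failures are data, not crashes
                failures += 1
                logger.warning("screen fit failed for %s / %s: %s", key, outcome, exc)
            rows.append(record)
            if ckpt_path:
                pd.DataFrame([record]).to_csv(
                    ckpt_path, mode="a", header=not ckpt_path.exists(), index=False
                )
            if failures > max_failure_rate * total and total >= 10:
                raise RuntimeError(
                    f"screen aborted: {failures}/{total} fits failed "
                    f"(> {max_failure_rate:.0%})"
                )
    return pd.DataFrame(rows)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and flags at level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    q_adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    if ok.any():
        rej, q_ok, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        q_adj[ok] = q_ok
        flags[ok] = rej
    return q_adj, flags


def flag_screen(
    table: pd.DataFrame, q: float = 0.05, pooling: str = "within_outcome"
) -> pd.DataFrame:
    """Append BH-adjusted q-values and significance flags.

    ``pooling`` controls the family over which the correction runs:
    ``"within_outcome"`` (default) corrects across triples separately per
    outcome; ``"pooled"`` corrects across all triple x outcome fits at
    once.
    """
    if pooling not in ("within_outcome", "pooled"):
        raise ValueError("pooling must be 'within_outcome' or 'pooled'")
    out = table.copy()
    if pooling == "pooled":
        out["q"], out["significant"] = bh_fdr(out["p"].to_numpy(), q)
        return out
    out["q"] = np.nan
    out["significant"] = False
    for _outcome, idx in out.groupby("outcome").groups.items():
        q_adj, flags = bh_fdr(out.loc[idx, "p"].to_numpy(), q)
        out.loc[idx, "q"] = q_adj
        out.loc[idx, "significant"] = flags
    return out


def tally_screen(
    table: pd.DataFrame,
    ageing_outcomes: tuple[str, ...] = (),
    exclude_outcomes: tuple[str, ...] = (),
    containing: str | None = None,
) -> dict[str, int]:
    """Summary counts over a flagged screen table.

    * ``n_triples_significant_any`` — triples significant for >= 1 outcome;
    * ``n_triples_ageing_only`` — of those, triples whose significant
      outcomes are all in ``ageing_outcomes``;
    * ``n_triples_significant_all`` — triples significant for every
      outcome not in ``exclude_outcomes``;
    * ``n_containing_<var>`` — significant triples containing a variable.
    """
    if "significant" not in table.columns:
        raise ValueError("table has no 'significant' column; run flag_screen first")
    if containing is not None:
        known = set(table["var1"]) | set(table["var2"]) | set(table["var3"])
        if containing not in known:
            raise ValueError(f"unknown variable {containing!r} in containing-filter")
    sig = table[table["significant"].fillna(False)]
    by_triple = sig.groupby("triple")["outcome"].agg(set)
    counts = {"n_triples_significant_any": int(len(by_triple))}
    ageing = set(ageing_outcomes)
    counts["n_triples_ageing_only"] = int(
        sum(1 for outs in by_triple if outs and outs <= ageing)
    ) if ageing else 0
    required = set(table["outcome"].unique()) - set(exclude_outcomes)
    counts["n_triples_significant_all"] = int(
        sum(1 for outs in by_triple if required <= outs)
    )
    if containing is not None:
        members = table.drop_duplicates("triple").set_index("triple")[["var1", "var2", "var3"]]
        counts[f"n_containing_{containing}"] = int(
            sum(containing in members.loc[t].tolist() for t in by_triple.index)
        )
    return counts


def refit_with_confounders(
    table: pd.DataFrame,
    data: pd.DataFrame,
    model_id: int = 6,
    top_n: int = 1,
    min_n: int = 30,
) -> pd.DataFrame:
    """Refit the most significant screen hits with confounder adjustment.

    The screen itself is deliberately unadjusted; hits that survive FDR are
    re-examined under the fully adjusted specification (model 6 by
    default).  Takes the ``top_n`` significant triples per outcome by
    adjusted q-value; returns their adjusted smooth-term statistics.
    """
    if "significant" not in table.columns:
        raise ValueError("table has no 'significant' column; run flag_screen first")
    rows = []
    sig = table[table["significant"].fillna(False)]
    for outcome, grp in sig.groupby("outcome"):
        for _, hit in grp.nsmallest(top_n, "q").iterrows():
            triple = (hit["var1"], hit["var2"], hit["var3"])
            spec = build_model_spec(model_id, outcome, micro_triple=triple)
            try:
                fit = fit_gam(spec, data, min_n=min_n)
            except ValueError as exc:
                logger.warning("refit failed for %s / %s: %s", hit["triple"], outcome, exc)
                continue
            tab = fit.smooth_terms()
            micro = tab[tab["term"] == f"s({','.join(triple)})"].iloc[0]
            rows.append(
                {
                    "triple": hit["triple"],
                    "outcome": outcome,
                    "model": model_id,
                    "screen_p": hit["p"],
                    "screen_q": hit["q"],
                    "adjusted_p": float(micro["p"]),
                    "adjusted_edf": float(micro["edf"]),
                    "deviance_explained": fit.deviance_explained,
                    "n": fit.nobs,
                }
            )
    return pd.DataFrame(rows)


def predict_sd_shift(
    fit,
    variable: str,
    delta_sd: float,
    profile: dict | None = None,
) -> float:
    """Predicted score change when ``variable`` moves ``delta_sd`` SDs above
    its sample mean, all other intakes held at their means and covariates
    at the stated profile."""
    results = fit.results if hasattr(fit, "results") else fit
    smooth_vars = [v for t in results.model.terms if hasattr(t, "variables")
                   for v in t.variables]
    if variable not in smooth_vars:
        raise ValueError(f"variable {variable!r} is not in the fitted model")
    x = results.model.data[variable].to_numpy(float)
    mu, sd = float(x.mean()), float(x.std(ddof=0))
    base, _ = predict_at(fit, {variable: mu}, profile)
    shifted, _ = predict_at(fit, {variable: mu + delta_sd * sd}, profile)
    return shifted - base
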