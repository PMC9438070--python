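"""End-to-end pipeline orchestration.

Stages: simulate (or ingest) -> score -> prep -> fit -> screen -> surface
-> report.  Every artefact directory carries a run log with the seed and a
hash of the configuration; re-running with the same hash overwrites only
with ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioage, dysregulation, models, nutrients, screen as screen_mod, surfaces
from .panel import BiomarkerPanel, default_panel
from .simulate import SimulationConfig, simulate

__all__ = ["PipelineConfig", "run_pipeline", "assemble_scores", "OUTCOME_COLUMNS",
           "AGEING_OUTCOMES", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "prep", "fit", "screen", "surface", "report")

#: the eight outcome scores, as Z-transformed model outcomes
OUTCOME_COLUMNS = (
    "z_dm_global",
    "z_dm_oxygen_transport",
    "z_dm_liver_kidney",
    "z_dm_leukopoiesis",
    "z_dm_micronutrients",
    "z_dm_lipids",
    "z_phenoage",
    "z_kdm_age",
)
AGEING_OUTCOMES = ("z_phenoage", "z_kdm_age")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # or "ingest"
    cohort_path: str | None = None
    panel_path: str | None = None
    out_dir: str = "nutriage_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model_ids: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    outcomes: tuple = OUTCOME_COLUMNS
    screen_variables: tuple | None = None  # None = all reduced variables
    screen_q: float = 0.05
    screen_pooling: str = "within_outcome"
    surface_resolution: int = 25
    kdm_r_min: float = 0.1

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if not self.out_dir:
            raise ValueError("missing config field: output directory (out_dir)")
        if self.mode == "ingest":
            if not self.cohort_path:
                raise ValueError("missing config field: cohort_path (required in ingest mode)")
            if not Path(self.cohort_path).exists():
                raise ValueError(f"cohort_path does not exist: {self.cohort_path}")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(simulation=sim, **raw)
        for tup_field in ("model_ids", "outcomes", "screen_variables"):
            v = getattr(cfg, tup_field)
            if isinstance(v, list):
                setattr(cfg, tup_field, tuple(v))
        return cfg

    def hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def assemble_scores(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    kdm_r_min: float = 0.1,
    phenoage_coeffs: bioage.PhenoAgeCoefficients | None = None,
) -> pd.DataFrame:
    """Compute all eight outcome scores on a biomarker-bearing cohort.

    Dysregulation scores are log+Z transformed; the two age scores are
    Z-transformed (they are already on an interpretable year scale).
    Returns the cohort joined with raw, log and Z score columns.
    """
    ref = dysregulation.build_reference_stats(cohort, panel)
    scores = dysregulation.score_dysregulation(cohort, panel, ref)
    scores = dysregulation.log_z_scores(scores)

    pheno_in = bioage.phenoage_inputs(cohort)
    scores["phenoage"] = bioage.compute_phenoage(
        pheno_in, cohort["age"].to_numpy(float), phenoage_coeffs
    )

    first = cohort[cohort["visit"] == 1]
    kdm_ref = pd.DataFrame(
        {m.name: first["bm_" + m.name].to_numpy(float) for m in panel.markers}
    )
    kdm_ref["age"] = first["age"].to_numpy(float)
    cal = bioage.calibrate_kdm(kdm_ref, [m.name for m in panel.markers], r_min=kdm_r_min)
    kdm_in = pd.DataFrame(
        {m: cohort["bm_" + m].to_numpy(float) for m in cal.markers}, index=cohort.index
    )
    scores["kdm_age"] = bioage.compute_kdm_age(kdm_in, cohort["age"].to_numpy(float), cal)

    for col in ("phenoage", "kdm_age"):
        x = scores[col].to_numpy(float)
        scores["z_" + col] = (x - np.nanmean(x)) / np.nanstd(x)
    return pd.concat([cohort, scores.drop(columns=["subject_id", "visit"])], axis=1)


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] | None = None,
    force: bool = False,
) -> Path:
    """Execute the pipeline stages, writing artefacts to ``config.out_dir``."""
    config.validate()
    stages = tuple(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_hash = config.hash()
    hash_file = out / "run_hash.txt"
    if hash_file.exists() and hash_file.read_text().strip() == run_hash and not force:
        raise FileExistsError(
            f"output directory already holds a run with config hash {run_hash}; "
            "pass force=True (--force) to overwrite"
        )
    hash_file.write_text(run_hash + "\n")
    log_lines = [f"config_hash: {run_hash}", f"seed: {config.seed}"]

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    panel = (
        BiomarkerPanel.from_yaml(config.panel_path) if config.panel_path else default_panel()
    )
    last_idx = max(STAGES.index(s) for s in stages)

    def finish() -> Path:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return out

    # --- simulate / ingest ------------------------------------------------
    cohort_file = out / "cohort.csv"
    if "simulate" in stages:
        if config.mode == "simulate":
            config.simulation.seed = config.seed
            cohort = simulate(config.simulation, panel)
            log("simulate", f"{len(cohort)} observations, "
                f"{cohort['subject_id'].nunique()} subjects, seed {config.seed}")
        else:
            cohort = pd.read_csv(config.cohort_path)
            log("simulate", f"ingested {len(cohort)} rows from {config.cohort_path}")
        cohort.to_csv(cohort_file, index=False)
    else:
        cohort = pd.read_csv(cohort_file)
    if last_idx == 0:
        return finish()

    # --- score ------------------------------------------------------------
    scores_file = out / "scores.csv"
    if "score" in stages:
        cohort = assemble_scores(cohort, panel, kdm_r_min=config.kdm_r_min)
        cohort.to_csv(scores_file, index=False)
        log("score", f"scored {len(cohort)} observations")
    else:
        cohort = pd.read_csv(scores_file)
    if last_idx == 1:
        return finish()

    # --- prep: relative intakes + reduced micronutrients -------------------
    prep_file = out / "analysis_table.csv"
    reduced_file = out / "reduced_nutrients.yaml"
    if "prep" in stages:
        tim = nutrients.fit_typical_intake(cohort)
        cohort = nutrients.add_relative_intakes(cohort, tim)
        sol = nutrients.cluster_micronutrients(cohort)
        reduced = nutrients.reduce_to_pc1(cohort, sol)
        reduced_scores = reduced.transform(cohort)
        reduced_scores.columns = ["rn_" + c for c in reduced_scores.columns]
        cohort = pd.concat([cohort, reduced_scores], axis=1)
        with open(reduced_file, "w") as fh:
            yaml.safe_dump(
                {
                    "variables": list(reduced.variables),
                    "clusters": {k: list(v) for k, v in reduced.clusters.items()},
                    "variance_explained": {
                        k: float(v) for k, v in reduced.variance_explained.items()
                    },
                    "z_mean": {k: float(v) for k, v in reduced.z_mean.items()},
                    "z_sd": {k: float(v) for k, v in reduced.z_sd.items()},
                },
                fh, sort_keys=False,
            )
        cohort.to_csv(prep_file, index=False)
        log("prep", f"{len(sol.clusters)} cluster(s), {sol.n_reduced} reduced variables")
    else:
        cohort = pd.read_csv(prep_file)
    if last_idx == 2:
        return finish()

    with open(reduced_file) as fh:
        reduced_vars = tuple("rn_" + v for v in yaml.safe_load(fh)["variables"])
    screen_vars = config.screen_variables or reduced_vars
    micro_triple = tuple(screen_vars[:3])

    # --- fit models --------------------------------------------------------
    fits_file = out / "model_fits.csv"
    fitted: dict = {}
    if "fit" in stages:
        rows = []
        for outcome in config.outcomes:
            for mid in config.model_ids:
                spec = models.build_model_spec(mid, outcome, micro_triple=micro_triple)
                try:
                    fit = models.fit_gam(spec, cohort)
                except ValueError as exc:
                    log("fit", f"model {mid} / {outcome} skipped: {exc}")
                    continue
                fitted[(mid, outcome)] = fit
                for _, srow in fit.smooth_terms().iterrows():
                    rows.append(
                        {
                            "model": mid,
                            "outcome": outcome,
                            "term": srow["term"],
                            "edf": srow["edf"],
                            "ref_df": srow["ref_df"],
                            "F": srow["F"],
                            "p": srow["p"],
                            "aic": fit.aic,
                            "deviance_explained": fit.deviance_explained,
                            "n": fit.nobs,
                            "converged": fit.converged,
                        }
                    )
        pd.DataFrame(rows).to_csv(fits_file, index=False)
        log("fit", f"{len(fitted)} model(s) fitted")
    if last_idx == 3:
        return finish()

    # --- screen ------------------------------------------------------------
    screen_file = out / "screen.csv"
    if "screen" in stages:
        triples = screen_mod.enumerate_triples(list(screen_vars))
        table = screen_mod.run_screen(
            triples, list(config.outcomes), cohort,
            checkpoint=out / "screen_checkpoint.csv",
        )
        table = screen_mod.flag_screen(table, q=config.screen_q,
                                       pooling=config.screen_pooling)
        table.to_csv(screen_file, index=False)
        tally = screen_mod.tally_screen(table, ageing_outcomes=AGEING_OUTCOMES)
        with open(out / "screen_tally.yaml", "w") as fh:
            yaml.safe_dump(tally, fh)
        log("screen", f"{len(table)} fits, tally {tally}")
    if last_idx == 4:
        return finish()

    # --- surfaces ----------------------------------------------------------
    if "surface" in stages and fitted:
        sdir = out / "surfaces"
        for (mid, outcome), fit in fitted.items():
            if mid != 1:
                continue
            triple = fit.spec.smooth_triples[0]
            surf = surfaces.make_surface(
                fit, triple[0], triple[1], resolution=config.surface_resolution
            )
            surfaces.render_and_export(surf, sdir, f"model{mid}_{outcome}")
        log("surface", f"exported surfaces to {sdir}")
    if last_idx == 5:
        return finish()

    # --- report ------------------------------------------------------------
    if "report" in stages and screen_file.exists():
        flagged = pd.read_csv(screen_file)
        if flagged.get("significant") is not None and flagged["significant"].any():
            refits = screen_mod.refit_with_confounders(flagged, cohort)
            if len(refits):
                refits.to_csv(out / "screen_refits.csv", index=False)
                log("report", f"{len(refits)} significant screen hit(s) refit "
                    "with confounder adjustment")
    if "report" in stages and fitted:
        comp_rows = []
        for outcome in config.outcomes:
            group = [fitted[(mid, o)] for (mid, o) in fitted if o == outcome]
            same_n = {}
            for f in group:
                same_n.setdefault(f.nobs, []).append(f)
            for n_used, fits_n in same_n.items():
                if len(fits_n) < 2:
                    continue
                comp = models.compare_models_aic(fits_n)
                comp.insert(0, "outcome", outcome)
                comp_rows.append(comp)
        if comp_rows:
            pd.concat(comp_rows, ignore_index=True).to_csv(
                out / "aic_comparison.csv", index=False
            )
        log("report", "AIC comparison written")

    return finish()
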