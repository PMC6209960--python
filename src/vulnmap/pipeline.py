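"""End-to-end orchestration: generate/read → cluster → match → map → layer.

A single :class:`PipelineConfig` drives the full composite-vulnerability
estimation.  One integer seed feeds a seed sequence that derives independent
per-stage streams (data generation, cross-validation folds), so toggling one
stage never perturbs another's randomness.  Every stage writes its artifact
to the output directory and the run closes with a manifest recording the
configuration, seed, and a checksum per artifact; identical config + seed
reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .areas import select_vulnerable, summarize_areas
from .cart import CartParams, model_suite
from .composite import spectrum
from .data_model import (
    SurveyTable,
    candidate_indicators,
    default_schema,
    read_schema,
    read_survey,
    weighted_proportion,
    write_schema,
    write_survey,
)
from .matching import MatchConfig, compare_predictors, flag_matchers, score_matrix
from .synthetic import GeneratorConfig, generate, plant_truth_report
from .twostep import TwoStepConfig, eliminate_variables

logger = logging.getLogger(__name__)

#: the reference model suite: all predictors, then the standard exclusions
DEFAULT_EXCLUSIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("model_1_all", ()),
    ("model_2_no_bp", ("high_blood_pressure",)),
    ("model_3_no_bmi", ("bmi",)),
    ("model_4_no_bp_bmi", ("high_blood_pressure", "bmi")),
)


@dataclass
class PipelineConfig:
    survey_path: str | None = None  # read these when set …
    schema_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)  # … else generate
    candidates: tuple[str, ...] | None = None  # default: all 35 candidates
    twostep: TwoStepConfig = field(default_factory=TwoStepConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    cart: CartParams = field(default_factory=CartParams)
    exclusions: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_EXCLUSIONS
    area_quartile: float = 75.0
    area_cap: int | None = None
    seed: int = 0


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seeds(seed: int, n: int = 2) -> list[int]:
    """Independent per-stage integer seeds derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages and return the artifact manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen_seed, cv_seed = stage_seeds(config.seed, 2)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def close_stage(name: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][name] = {
            "artifacts": {p.name: _checksum(p) for p in paths},
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    # ---- stage 1: data -----------------------------------------------------
    t0 = time.time()
    if config.survey_path:
        schema = read_schema(config.schema_path) if config.schema_path else default_schema()
        table = read_survey(config.survey_path, schema)
        truth = None
        data_paths: list[Path] = []
    else:
        table, truth = generate(dataclasses.replace(config.generator, seed=gen_seed))
        schema = table.schema
        survey_csv = out / "survey.csv"
        schema_yml = out / "schema.yaml"
        truth_csv = out / "truth.csv"
        write_survey(table, survey_csv)
        write_schema(schema, schema_yml)
        truth.frame.to_csv(truth_csv, index=False)
        (out / "truth_report.json").write_text(
            json.dumps(plant_truth_report(table, truth), indent=2, sort_keys=True)
        )
        data_paths = [survey_csv, schema_yml, truth_csv, out / "truth_report.json"]
    close_stage("data", data_paths, t0)

    # ---- stage 2: cluster the diagnosed ------------------------------------
    t0 = time.time()
    candidates = list(config.candidates or candidate_indicators(schema))
    solution = eliminate_variables(table.diabetic(), schema, candidates, config.twostep)
    sol_path = out / "cluster_solution.json"
    sol_path.write_text(
        json.dumps(
            {
                "k": solution.k,
                "sizes": solution.sizes,
                "converged": solution.converged,
                "quality_band": solution.quality_band,
                "silhouette": solution.silhouette,
                "active_variables": list(solution.active_variables),
                "importance": solution.importance,
                "modal_profile": {str(c): p for c, p in solution.modal_profile.items()},
                "bic_trace": {str(k): v for k, v in solution.bic_trace.items()},
                "assignments": solution.assignments,
            },
            indent=2,
            sort_keys=True,
        )
    )
    profiles = pd.DataFrame(solution.modal_profile).rename_axis("indicator")
    profiles["importance"] = pd.Series(solution.importance)
    profiles.sort_values("importance", ascending=False).to_csv(out / "cluster_profiles.csv")
    close_stage("cluster", [sol_path, out / "cluster_profiles.csv"], t0)

    # ---- stage 3: screen the undiagnosed -----------------------------------
    t0 = time.time()
    scores = score_matrix(table, solution, config.match)
    match = flag_matchers(scores, table.undiagnosed()["weight"].to_numpy(), config.match)
    match_df = scores.copy()
    match_df.columns = [f"score_c{c}" for c in scores.columns]
    match_df["matcher"] = match.matcher
    match_df["best_cluster"] = match.best_cluster
    match_df.to_csv(out / "matches.csv")
    compare_predictors(table, match).to_csv(out / "matcher_comparison.csv")
    close_stage("match", [out / "matches.csv", out / "matcher_comparison.csv"], t0)

    # ---- stage 4: areas -----------------------------------------------------
    t0 = time.time()
    summary = summarize_areas(table, match)
    selection = select_vulnerable(summary, config.area_quartile, config.area_cap)
    summary.table.assign(
        selected=summary.table["area"].isin(selection.selected)
    ).to_csv(out / "area_summary.csv", index=False)
    close_stage("areas", [out / "area_summary.csv"], t0)

    # ---- stage 5: recursive partitioning ------------------------------------
    t0 = time.time()
    predictors = candidates + ["high_blood_pressure", "bmi", "age"]
    models = model_suite(table, predictors, list(config.exclusions), config.cart, seed=cv_seed)
    cart_report = []
    for m in models:
        imp = m.importance["rescaled"]
        top = sorted(imp.items(), key=lambda x: -x[1])[:5]
        cart_report.append(
            {
                "model": m.label,
                "excluded": list(m.excluded),
                "cv_misclassification": m.cv.selected_error,
                "accuracy": m.accuracy,
                "n_leaves_selected": m.tree.n_leaves(m.selected_pruned),
                "top_importance": {v: round(s, 1) for v, s in top},
            }
        )
    (out / "cart_models.json").write_text(json.dumps(cart_report, indent=2, sort_keys=True))
    close_stage("cart", [out / "cart_models.json"], t0)

    # ---- stage 6: composite spectrum ----------------------------------------
    t0 = time.time()
    spec = spectrum(table, selection.selected)
    spectrum_payload = {
        "selected_areas": list(selection.selected),
        "proportions": spec.proportions,
        "matcher_share_selected_areas": _matcher_share_in_areas(table, match, selection.selected),
    }
    (out / "spectrum.json").write_text(json.dumps(spectrum_payload, indent=2, sort_keys=True))
    close_stage("composite", [out / "spectrum.json"], t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _matcher_share_in_areas(table: SurveyTable, match, selected) -> float:
    """Weighted share of selected-area undiagnosed residents who are matchers."""
    undiag = table.undiagnosed().set_index("respondent_id")
    in_area = undiag["area"].isin(list(selected))
    if not in_area.any():
        return float("nan")
    w = undiag.loc[in_area, "weight"].to_numpy(dtype=float)
    flags = match.matcher.reindex(undiag.index[in_area]).to_numpy(dtype=bool)
    return weighted_proportion(w, flags)
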