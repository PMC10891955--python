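"""End-to-end orchestration of the niche-modelling analysis.

One validated YAML config and one master seed drive the full stage order:
simulate (or load) -> occurrence prep -> initial fit on all variables ->
contributions -> correlations at presences -> variable selection -> final
fit -> cross-validation -> jackknife -> response curves -> MTSPS threshold
and current-climate classification -> scenario projection and change
summaries. Per-stage seeds are derived from the master seed by labelled
hashing, so toggling one stage never shifts another's randomness; identical
config + seed gives byte-identical JSON/CSV artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import evaluate, mapping, prep, selection, simulate
from .grids import InputError, OccurrenceSet, locate_cells
from .maxent import MaxEnt, MaxEntConfig


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class WorldConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rows: int = 100
    n_cols: int = 100
    n_presences: int = 300


class PrepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    background_n: int = 10_000
    use_bias_surface: bool = False
    bandwidth: float | None = None


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rm: float = Field(1.0, gt=0)
    n_knots: int = Field(20, ge=1)
    transform: Literal["raw", "cloglog", "logistic"] = "cloglog"
    clamp: bool = True
    max_passes: int = 500
    tol: float = Field(1e-5, gt=0)


class SelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r_threshold: float = Field(0.7, ge=0, le=1)
    min_contribution: float = Field(1.0, ge=0)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = Field(10, ge=2)
    jackknife_replicates: int = Field(3, ge=1)
    response_points: int = Field(100, ge=2)


class PipelineConfig(BaseModel):
    """Strictly validated run configuration (unknown keys are errors)."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    output_dir: str = "nichecast_out"
    world: WorldConfig = WorldConfig()
    prep: PrepConfig = PrepConfig()
    model: ModelConfig = ModelConfig()
    selection: SelectionConfig = SelectionConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


def stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure aborts with :class:`StageError`; partial outputs are
    retained and the manifest marks the failed stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "stages": {}, "files": {}}
    mcfg = MaxEntConfig(rm=config.model.rm, n_knots=config.model.n_knots,
                        transform=config.model.transform, clamp=config.model.clamp,
                        max_passes=config.model.max_passes, tol=config.model.tol)

    state: dict = {}

    def _artifact(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha(path)}

    def _run(stage: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report stage and re-raise
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_json(out / "manifest.json", manifest)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "status": "ok", "wall_time_s": round(time.perf_counter() - t0, 3),
        }

    def s_simulate() -> None:
        grid, niche, suit, occ = simulate.default_world(
            stage_seed(config.seed, "simulate"),
            n_rows=config.world.n_rows, n_cols=config.world.n_cols,
            n_presences=config.world.n_presences)
        state.update(grid=grid, niche=niche, true_suit=suit, occ_raw=occ)
        occ.to_frame().to_csv(out / "occurrences_raw.csv", index=False)
        _artifact("occurrences_raw", out / "occurrences_raw.csv")

    def s_prep() -> None:
        occ = locate_cells(state["occ_raw"], state["grid"].geometry)
        occ, rep1 = prep.deduplicate(occ)
        occ, rep2 = prep.mask_filter(occ, state["grid"])
        occ, rep3 = prep.thin_one_per_cell(occ, state["grid"].geometry,
                                           seed=stage_seed(config.seed, "thin"))
        if config.prep.use_bias_surface:
            bias = prep.kernel_bias_surface(occ, state["grid"].geometry,
                                            bandwidth=config.prep.bandwidth,
                                            nodata_mask=state["grid"].nodata_mask)
            state["bias"] = bias
        else:
            state["bias"] = None
        bg = prep.sample_background(state["grid"], config.prep.background_n,
                                    bias=state["bias"],
                                    seed=stage_seed(config.seed, "background"))
        state.update(occ=occ, background_cells=bg)
        report = {"stages": [rep1.to_dict(), rep2.to_dict(), rep3.to_dict()],
                  "n_background": int(bg.shape[0])}
        _write_json(out / "prep_report.json", report)
        _artifact("prep_report", out / "prep_report.json")

    def s_initial_fit() -> None:
        model = MaxEnt.from_env_grid(state["grid"], state["occ"],
                                     background_cells=state["background_cells"],
                                     config=mcfg)
        state["initial_results"] = model.fit(seed=stage_seed(config.seed, "initial_fit"))
        state["initial_results"].to_json(out / "initial_model.json")
        _artifact("initial_model", out / "initial_model.json")

    def s_contributions() -> None:
        contrib = state["initial_results"].percent_contribution()
        contrib.rename("percent_contribution").to_csv(out / "contributions_initial.csv")
        state["contributions"] = contrib
        _artifact("contributions_initial", out / "contributions_initial.csv")

    def s_pearson() -> None:
        corr = selection.pearson_at_presences(state["grid"], state["occ"])
        corr.to_csv(out / "pearson_at_presences.csv")
        state["corr"] = corr
        _artifact("pearson_at_presences", out / "pearson_at_presences.csv")

    def s_select() -> None:
        report = selection.select_variables(
            state["corr"], state["contributions"],
            r_threshold=config.selection.r_threshold,
            min_contribution=config.selection.min_contribution)
        _write_json(out / "selection_report.json", report.to_dict())
        state["kept"] = report.kept
        if not report.kept:
            raise InputError("selection kept no variables")
        _artifact("selection_report", out / "selection_report.json")

    def s_final_fit() -> None:
        model = MaxEnt.from_env_grid(state["grid"], state["occ"], variables=state["kept"],
                                     background_cells=state["background_cells"],
                                     config=mcfg)
        state["final_results"] = model.fit(seed=stage_seed(config.seed, "final_fit"))
        state["final_results"].to_json(out / "final_model.json")
        (out / "final_model_summary.txt").write_text(
            state["final_results"].summary() + "\n", encoding="utf-8")
        _artifact("final_model", out / "final_model.json")
        _artifact("final_model_summary", out / "final_model_summary.txt")

    def s_cross_validate() -> None:
        report = evaluate.cross_validate(
            state["occ"], state["grid"], state["kept"], config=mcfg,
            k=config.evaluation.k, seed=stage_seed(config.seed, "cv"))
        _write_json(out / "cross_validation.json", report.to_dict())
        state["cv"] = report
        _artifact("cross_validation", out / "cross_validation.json")

    def s_jackknife() -> None:
        jk = evaluate.jackknife(state["occ"], state["grid"], state["kept"], config=mcfg,
                                k_replicates=config.evaluation.jackknife_replicates,
                                seed=stage_seed(config.seed, "jackknife"))
        frame = jk.to_frame()
        frame.columns = ["_".join(c) for c in frame.columns]
        frame.insert(0, "gain_full", jk.gain_full)
        frame.to_csv(out / "jackknife.csv")
        state["jackknife"] = jk
        _artifact("jackknife", out / "jackknife.csv")

    def s_response_curves() -> None:
        curves = {}
        for var in state["kept"]:
            curve = evaluate.response_curve(state["cv"].fold_results, var,
                                            n_points=config.evaluation.response_points)
            curve.to_frame().to_csv(out / f"response_{var}.csv", index=False)
            _artifact(f"response_{var}", out / f"response_{var}.csv")
            curves[var] = curve
        state["curves"] = curves

    def s_threshold_classify() -> None:
        thr = mapping.mtsps_threshold(state["cv"].pooled_presence_scores,
                                      state["cv"].background_scores)
        _write_json(out / "mtsps.json", thr.to_dict())
        _artifact("mtsps", out / "mtsps.json")
        current = state["final_results"].predict_grid(state["grid"], label="current")
        cls = mapping.classify(current, thr.threshold, label="current")
        state.update(mtsps=thr, current_map=current, current_class=cls)
        cls.counts().rename("cells").to_csv(out / "class_counts_current.csv")
        _artifact("class_counts_current", out / "class_counts_current.csv")

    def s_project_scenarios() -> None:
        rows = []
        for spec in simulate.default_scenarios():
            sgrid = simulate.apply_scenario(state["grid"], spec)
            smap = mapping.project(state["final_results"], sgrid, label=spec.label)
            scls = mapping.classify(smap, state["mtsps"].threshold, label=spec.label)
            summary = mapping.change_summary(state["current_class"], scls)
            summary.transition.to_csv(out / f"transition_{spec.label}.csv")
            _artifact(f"transition_{spec.label}", out / f"transition_{spec.label}.csv")
            counts = scls.counts()
            rows.append({"scenario": spec.label, **counts.to_dict()})
        pd.DataFrame(rows).to_csv(out / "class_counts_scenarios.csv", index=False)
        _artifact("class_counts_scenarios", out / "class_counts_scenarios.csv")

    stages = [
        ("simulate", s_simulate),
        ("prep", s_prep),
        ("initial_fit", s_initial_fit),
        ("contributions", s_contributions),
        ("pearson", s_pearson),
        ("select", s_select),
        ("final_fit", s_final_fit),
        ("cross_validate", s_cross_validate),
        ("jackknife", s_jackknife),
        ("response_curves", s_response_curves),
        ("threshold_classify", s_threshold_classify),
        ("project_scenarios", s_project_scenarios),
    ]
    for name, fn in stages:
        _run(name, fn)
    _write_json(out / "manifest.json", manifest)
    return manifest


def fixture_pipeline() -> selection.SelectionReport:
    """Run variable selection on the packaged reference tables and check the
    kept set against the published final-model variables."""
    fixture = simulate.load_reference_tables()
    report = selection.select_variables(fixture.matrix, fixture.contributions_initial)
    expected = list(fixture.contributions_final.index)
    if sorted(report.kept) != sorted(expected):
        raise RuntimeError(
            f"fixture selection mismatch: kept {report.kept}, expected {expected}; "
            f"drop ledger: {report.dropped}")
    return report
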