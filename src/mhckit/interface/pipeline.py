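"""End-to-end pipeline driver.

Stage order mirrors the analysis flow: population filter, binary recode,
factor-count criteria + EFA + CFA, per-factor 2PL IRT with thresholds, MHC
scoring and median split, nutrient screen, cut-off derivation, and N-count
stratification.  Every stage's output is persisted as CSV/JSON under the
output directory; reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .. import __version__
from .. import bjsq, factor_analysis as fa, irt, mhc as mhc_mod, nutrient_screen as ns
from ..synthetic_data import ConfigurationError
from .validate import validate_tables


@dataclass
class PipelineConfig:
    subjects_path: str = "subjects.csv"
    bjsq_path: str = "bjsq.csv"
    nutrients_path: str = "nutrients.csv"
    outdir: str = "mhc_output"
    alpha: float = 0.05
    n_factors: int | None = None          # None -> parallel-analysis count
    assignment_threshold: float = 0.29
    pa_iterations: int = 100
    pa_percentile: float = 95.0
    irt_quadrature: int = 21
    irt_tol: float = 1e-4
    irt_max_iter: int = 500
    irt_joint: bool = False               # single joint 29-item fit instead of per factor
    cutoff_overrides_path: str | None = None
    run_factors: bool = True
    run_irt: bool = True
    run_screen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path, manifest: RunManifest) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))
    manifest.checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    subjects = pd.read_csv(config.subjects_path)
    responses = pd.read_csv(config.bjsq_path)
    intakes = pd.read_csv(config.nutrients_path)

    report = validate_tables(subjects, responses, intakes)
    _write_json(report, outdir / "validation.json", manifest)
    if not report["ok"]:
        bad = report["missing_columns"] + report["range_violations"] + report["orphan_ids"]
        raise StageError("validate", f"input validation failed: {bad[:10]}")
    manifest.stages["validate"] = {"rows": int(len(subjects))}

    # -- filter ------------------------------------------------------------
    included, excl_report = bjsq.filter_population(subjects)
    _write_json(excl_report, outdir / "exclusion_report.json", manifest)
    responses = responses[responses["subject_id"].isin(included)].reset_index(drop=True)
    intakes = intakes[intakes["subject_id"].isin(included)].reset_index(drop=True)
    manifest.stages["filter"] = {"rows": int(len(included))}

    # -- recode ------------------------------------------------------------
    try:
        binary = bjsq.recode_binary(responses)
    except bjsq.ValidationError as exc:
        raise StageError("recode", str(exc)) from exc
    _write_csv(binary, outdir / "binary.csv", manifest)
    manifest.stages["recode"] = {"rows": int(len(binary))}

    scores6 = bjsq.score_subscales(responses)
    _write_csv(scores6, outdir / "subscale_scores.csv", manifest)
    grades = bjsq.grade_severity(scores6)
    _write_csv(grades, outdir / "severity_grades.csv", manifest)
    manifest.warnings.append(
        "severity grades use the package default boundary tables, not the "
        "official manual's unpublished ones"
    )

    assignment: dict[str, str] | None = None

    # -- factors -----------------------------------------------------------
    if config.run_factors:
        corr = fa.item_correlations(binary)
        kmo_val = fa.kmo(corr)
        counts = fa.count_factors(
            binary, n_iter=config.pa_iterations,
            percentile=config.pa_percentile, seed=config.seed,
        )
        k = config.n_factors or counts.parallel_count or 5
        solution = fa.efa(binary, k=k)
        manifest.warnings.extend(solution.warnings)
        assignment, unassigned = fa.assign_items(
            solution, threshold=config.assignment_threshold
        )
        cfa = fa.cfa_fit(binary, model=assignment)
        pattern = solution.pattern.copy()
        pattern.insert(0, "item", pattern.index)
        _write_csv(pattern.reset_index(drop=True), outdir / "pattern.csv", manifest)
        _write_csv(pd.DataFrame(solution.phi), outdir / "phi.csv", manifest)
        _write_json(
            {
                "kmo": kmo_val,
                "eigenvalues": counts.eigenvalues.tolist(),
                "parallel_count": counts.parallel_count,
                "map_count": counts.map_count,
                "k_used": k,
                "assignment": assignment,
                "unassigned": unassigned,
                "cfi": cfa.indices.cfi,
                "tli": cfa.indices.tli,
                "srmr": cfa.indices.srmr,
                "chi2": cfa.indices.chi2,
                "df": cfa.indices.df,
            },
            outdir / "factor_summary.json", manifest,
        )
        manifest.stages["factors"] = {"rows": int(len(binary)), "k": int(k)}

    # -- irt ---------------------------------------------------------------
    if config.run_irt:
        if assignment is None:
            solution = fa.efa(binary, k=config.n_factors or 5)
            assignment, _ = fa.assign_items(solution, config.assignment_threshold)
        factor_items: dict[str, list[str]] = {}
        for item, f in assignment.items():
            factor_items.setdefault(f, []).append(item)
        factor_items = {f: its for f, its in factor_items.items() if len(its) >= 2}
        all_params = []
        curves = {}
        thresholds = {}
        if config.irt_joint:
            fit = irt.fit_2pl(binary, quadrature=config.irt_quadrature,
                              tol=config.irt_tol, max_iter=config.irt_max_iter)
            manifest.warnings.extend(fit.warnings)
            for f, its in sorted(factor_items.items()):
                its = [q for q in its if q in set(fit.params["item"])]
                curve = irt.factor_curve(its, fit)
                curves[f] = curve
                thresholds[f] = _safe_threshold(curve)
            all_params.append(fit.params)
        else:
            for f, its in sorted(factor_items.items()):
                fit = irt.fit_2pl(binary[["subject_id"] + its],
                                  quadrature=config.irt_quadrature,
                                  tol=config.irt_tol, max_iter=config.irt_max_iter)
                manifest.warnings.extend(fit.warnings)
                fitted = [q for q in its if q in set(fit.params["item"])]
                curve = irt.factor_curve(fitted, fit)
                curves[f] = curve
                thresholds[f] = _safe_threshold(curve)
                all_params.append(fit.params)
        params = pd.concat(all_params, ignore_index=True)
        _write_csv(params, outdir / "item_params.csv", manifest)
        grid = next(iter(curves.values())).theta
        curve_df = pd.DataFrame({"theta": grid})
        for f, c in sorted(curves.items()):
            curve_df[f] = c.probability
        _write_csv(curve_df, outdir / "curves.csv", manifest)
        _write_json(
            {"mode": "joint" if config.irt_joint else "per_factor",
             "thresholds": thresholds},
            outdir / "irt_thresholds.json", manifest,
        )
        manifest.stages["irt"] = {"rows": int(len(binary)),
                                  "factors": len(factor_items)}

    # -- mhc scores and split ---------------------------------------------
    mhc_scores = mhc_mod.score_mhc(responses)
    _write_csv(mhc_scores, outdir / "mhc_scores.csv", manifest)
    split = mhc_mod.median_split(mhc_scores)
    _write_csv(split.labels, outdir / "splits.csv", manifest)
    _write_json({"medians": split.medians, "direction": split.direction},
                outdir / "medians.json", manifest)
    manifest.stages["mhc"] = {"rows": int(len(mhc_scores))}

    # -- screen / cutoffs / stratification --------------------------------
    if config.run_screen:
        screen_res = ns.screen(intakes, split.labels, alpha=config.alpha)
        _write_csv(screen_res.cells, outdir / "screen.csv", manifest)
        overrides = {}
        if config.cutoff_overrides_path:
            ov = pd.read_csv(config.cutoff_overrides_path)
            overrides = dict(zip(ov["nutrient"], ov["cutoff"]))
        entries = ns.derive_cutoffs(screen_res, overrides=overrides)
        cut_df = pd.DataFrame([
            {
                "nutrient": e.nutrient, "lo": e.lo, "hi": e.hi,
                "cutoff": e.cutoff, "source": e.source,
                "violations": ";".join(f"{i}:{v}" for i, v in e.violations),
            }
            for e in entries
        ])
        _write_csv(cut_df, outdir / "cutoffs.csv", manifest)
        for e in entries:
            if e.cutoff is None:
                manifest.warnings.append(
                    f"empty feasible interval for {e.nutrient}; no cut-off derived"
                )
        groups, summary, warns = ns.stratify_and_compare(
            intakes, entries, mhc_scores, alpha=config.alpha
        )
        manifest.warnings.extend(warns)
        _write_csv(groups, outdir / "groups.csv", manifest)
        _write_csv(summary, outdir / "group_comparison.csv", manifest)
        manifest.stages["screen"] = {
            "rows": int(len(screen_res.cells)),
            "selected": len(screen_res.selected),
            "n_tests": screen_res.n_tests,
        }

    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _safe_threshold(curve) -> float | None:
    try:
        return irt.threshold(curve)
    except ValueError:
        return None
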