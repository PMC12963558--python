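"""End-to-end orchestration: simulate -> preprocess -> neurometrics ->
questionnaire composites -> mixed ANOVA (+ Duncan post-hoc) -> report.

Each stage can run standalone on the previous stage's on-disk outputs; the
in-memory path (:func:`analyze_study`) is what the file-based runner and the
test-suite both call, so disk and memory routes share one implementation.
A run manifest records the config hash, seed, package version and output
checksums, making end-to-end determinism checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import NeurometricsConfig, PipelineConfig
from .io import StudyLayout, read_study, write_study
from .montage import ChannelMontage
from .neurometrics import aggregate_study, band_edges, estimate_iaf
from .preprocess import preprocess
from .questionnaire import (build_composite, correlation_matrix,
                            default_constructs, validate_merge)
from .stats import (duncan_mrt, format_p, mixed_anova_2x2,
                    verify_all_printed_tables)
from .synthetic import StudyDataset, generate_study

logger = logging.getLogger(__name__)

MEASURE_LABELS = {
    "work_performance": "Impact on work performance",
    "willingness_to_use": "Willingness to use",
    "wl": "Mental workload (WL)",
    "aw": "Acceptance (approach-withdrawal, AW)",
}


def _montage_from_config(cfg: NeurometricsConfig) -> ChannelMontage:
    return ChannelMontage(frontal=tuple(cfg.wl_frontal),
                          parietal=tuple(cfg.wl_parietal),
                          frontal_left=tuple(cfg.aw_left),
                          frontal_right=tuple(cfg.aw_right))


@dataclass
class AnalysisResults:
    """Everything the analysis stage produces."""

    neurometrics: pd.DataFrame
    composites: dict                 # measure -> long DataFrame
    anova_tables: dict               # measure -> AnovaTable
    duncan: dict                     # measure -> DuncanResult | None
    merge_reports: dict              # construct -> MergeDecision
    warnings: list
    report: str = ""


def compute_neurometrics(recordings: dict, rest_segments: dict,
                         config: PipelineConfig) -> pd.DataFrame:
    """Preprocess every recording, anchor bands to each subject's IAF and
    emit one tidy neurometric record per subject x condition."""
    pp, nm = config.preprocess, config.neurometrics
    montage = _montage_from_config(nm)
    schemes, warnings_ = {}, []
    for sid, rest in sorted(rest_segments.items()):
        iaf, found = estimate_iaf(rest, search_range=tuple(nm.iaf_search),
                                  subset=tuple(nm.wl_parietal),
                                  return_found=True)
        if not found:
            warnings_.append(f"IAF fallback used for {sid}")
        schemes[sid] = band_edges(iaf)
    epoch_sets = {}
    for (sid, cond), rec in sorted(recordings.items()):
        result = preprocess(rec, low=pp.low, high=pp.high, order=pp.order,
                            epoch_length=pp.epoch_length,
                            threshold_uv=pp.threshold_uv,
                            blink_mode=pp.blink_mode,
                            blink_threshold_uv=pp.blink_threshold_uv)
        epochs = result.epochs
        if epochs.n_epochs and result.n_rejected > epochs.n_epochs / 2:
            warnings_.append(
                f"{sid}/{cond}: only {epochs.n_clean}/{epochs.n_epochs} "
                "epochs survived artifact rejection")
        epoch_sets[(sid, cond)] = epochs
    table = aggregate_study(epoch_sets, schemes, montage=montage,
                            gfp_mode=nm.gfp_mode)
    table.attrs["warnings"] = warnings_
    return table


def _anova_with_posthoc(long: pd.DataFrame, dv: str,
                        config: PipelineConfig):
    table = mixed_anova_2x2(long, dv=dv)
    alpha = config.stats.alpha
    significant = any(table.table.loc[k, "p"] < alpha
                      for k in ("condition", "interaction", "group"))
    duncan = None
    if significant:
        cells = long.groupby(["group", "condition"])[dv].agg(["mean",
                                                              "count"])
        # within-cell error pooled across both residual strata
        ss = table.table["SS"]
        df_pool = int(table.table.loc["within_resid", "df"]
                      + table.table.loc["between_resid", "df"])
        ms_pool = float((ss["within_resid"] + ss["between_resid"]) / df_pool)
        duncan = duncan_mrt(cells["mean"].to_numpy(),
                            cells["count"].to_numpy(),
                            ms_pool, df_pool, alpha=alpha,
                            labels=[f"{g}/{c}" for g, c in cells.index])
    return table, duncan


def analyze_study(study: StudyDataset | StudyLayout,
                  config: PipelineConfig) -> AnalysisResults:
    """Run the full analysis chain on an in-memory or on-disk study."""
    warnings_: list[str] = []
    neuro = compute_neurometrics(study.recordings, study.rest_segments,
                                 config)
    warnings_.extend(neuro.attrs.get("warnings", []))

    composites, merge_reports = {}, {}
    qcfg = config.questionnaire
    table = study.questionnaire
    matrix = correlation_matrix(table)
    for spec in default_constructs():
        decision = validate_merge(matrix, spec, alpha=qcfg.alpha)
        merge_reports[spec.name] = decision
        if not decision.approved:
            warnings_.append(
                f"correlation screen failed for composite {spec.name!r}; "
                "composite built under forced override")
        comp = build_composite(table, spec, decision,
                               force=not decision.approved or
                               qcfg.force_merge,
                               method=qcfg.method)
        composites[spec.name] = comp.rename(columns={spec.name: "value"})

    anova_tables, duncan = {}, {}
    for name, comp in composites.items():
        anova_tables[name], duncan[name] = _anova_with_posthoc(
            comp, "value", config)
    for dv in ("wl", "aw"):
        long = neuro[["subject_id", "group", "condition", dv]]
        anova_tables[dv], duncan[dv] = _anova_with_posthoc(long, dv, config)

    results = AnalysisResults(neuro, composites, anova_tables, duncan,
                              merge_reports, warnings_)
    results.report = render_report(results, config)
    return results


def render_report(results: AnalysisResults, config: PipelineConfig) -> str:
    """Plain-text effects report mirroring the published table layout."""
    lines = ["Mixed 2x2 repeated-measures ANOVA "
             "(within: Explainability BB vs HM; between: Expertise)", ""]
    for name, table in results.anova_tables.items():
        lines.append(f"== {MEASURE_LABELS.get(name, name)} ==")
        for key, label in (("condition", "Explainability"),
                           ("interaction", "Explainability x Expertise"),
                           ("group", "Expertise")):
            row = table.table.loc[key]
            lines.append(
                f"  {label}: F(1, {int(table.table.loc['within_resid' if key != 'group' else 'between_resid', 'df'])}) "
                f"= {row['F']:.3f}, p = {format_p(row['p'])}, "
                f"eta2_classical = {row['eta2_classical']:.3f}, "
                f"eta2_partial = {row['eta2_partial']:.3f}")
        dr = results.duncan.get(name)
        if dr is not None:
            sig = dr.comparisons.loc[dr.comparisons["significant"]]
            lines.append(f"  Duncan post-hoc ({len(sig)} significant pair(s) "
                         f"at alpha = {dr.alpha:g}):")
            for _, c in sig.iterrows():
                lines.append(f"    {c['a']} > {c['b']} "
                             f"(diff {c['diff']:.3f} > "
                             f"critical {c['critical_range']:.3f})")
        lines.append("")
    lines.append("Clean-epoch counts per record:")
    for _, row in results.neurometrics.iterrows():
        lines.append(f"  {row['subject_id']}/{row['condition']}: "
                     f"{int(row['n_clean_epochs'])} clean epochs, "
                     f"IAF {row['iaf_hz']:.1f} Hz")
    if results.warnings:
        lines.append("")
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in results.warnings)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file-based stage runners


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {"/".join(k) if isinstance(k, tuple) else str(k):
                _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_manifest(out_dir: Path, config: PipelineConfig,
                   warnings_: list) -> dict:
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "warnings": list(warnings_),
        "checksums": {str(p.relative_to(out_dir)): _sha256(p)
                      for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_simulate(config: PipelineConfig, out_dir=None,
                 format: str = "csv") -> StudyDataset:
    """Generate a study and write it (with manifest) to disk."""
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = generate_study(config.simulate)
    write_study(dataset, out_dir, format=format)
    write_manifest(out_dir, config, [])
    return dataset


def run_analysis(config: PipelineConfig, study_dir,
                 out_dir=None) -> AnalysisResults:
    """Analyse an on-disk study and write the results bundle."""
    study_dir = Path(study_dir)
    if not (study_dir / "index.csv").exists():
        raise FileNotFoundError(
            f"stage 'simulate' outputs not found in {study_dir} "
            "(missing index.csv)")
    study = read_study(study_dir)
    results = analyze_study(study, config)
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.neurometrics.to_csv(out_dir / "neurometrics.csv", index=False)
    for name, comp in results.composites.items():
        comp.to_csv(out_dir / f"composite_{name}.csv", index=False)
    for name, table in results.anova_tables.items():
        formatted = table.formatted(
            eta_convention=config.stats.eta_convention)
        formatted.to_csv(out_dir / f"anova_{name}.csv", index=False)
    (out_dir / "report.txt").write_text(results.report)
    write_manifest(out_dir, config, results.warnings)
    return results


def run_verify_tables():
    """Reconstruct the published ANOVA tables from their printed SS/df and
    compare; returns (report DataFrame, all-checks-passed flag)."""
    return verify_all_printed_tables()
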