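"""End-to-end orchestration: config, seed fan-out, stages, manifest.

A single YAML config drives a run.  It names either a pair of input files
(NPX long table + sample annotations) or a ``simulation`` block; the
analysis stages then execute in order — differential expression over the
six contrasts, the orthogonal screen, clinical correlations, sex
comparisons, random-forest importance of the treatment-responsive proteins,
and (when a GMT file is configured) enrichment with the intersectional
comparison.  All tables land as TSV in the output directory together with a
``summary.json`` of the headline numbers and a ``manifest.json`` with
content digests sufficient to re-run seeded stages bit-identically.

One global seed fans out to per-stage seeds by hashing the stage name, so
adding or re-configuring a late stage (e.g. swapping the GMT) leaves every
upstream output byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clinical_assoc, diffexp, enrichment, feature_importance, npx_io, ortho_screen
from .npx_io import NPXMatrix, StudyDesign, Timepoint, write_table
from .synthetic_cohort import SimulationConfig, SimulationTruth, simulate_full

logger = logging.getLogger(__name__)

__all__ = ["load_config", "stage_seed", "run_pipeline", "replicate_study", "PUBLISHED_COUNTS"]

#: Printed reference counts of the emulated study, used only by the
#: replication comparison table (computed-vs-reported).
PUBLISHED_COUNTS: dict[str, int] = {
    "G1": 17, "G2": 10, "G3": 9, "G4": 17, "P1": 45, "P2": 14,
    "set1": 24, "set2": 14, "set3": 45, "set4": 19, "set5": 16, "core": 12,
    "nihss_significant": 13, "esrs_significant": 6, "nihss_core_overlap": 4,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, hashed from the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config_path: str | Path) -> dict[str, Any]:
    with Path(config_path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{config_path}: config must be a YAML mapping")
    has_input = "input" in cfg and cfg["input"]
    has_sim = "simulation" in cfg and cfg["simulation"] is not None
    if not has_input and not has_sim:
        raise ValueError(
            f"{config_path}: config needs either an 'input' block (npx + annotations) "
            "or a 'simulation' block"
        )
    return cfg


def _analysis_config(cfg: dict[str, Any], seed: int) -> diffexp.AnalysisConfig:
    block = dict(cfg.get("analysis") or {})
    block.setdefault("seed", stage_seed(seed, "rf"))
    return diffexp.AnalysisConfig(**block)


def _simulation_config(cfg: dict[str, Any], seed: int) -> SimulationConfig:
    block = dict(cfg.get("simulation") or {})
    if isinstance(block.get("mu_range"), list):
        block["mu_range"] = tuple(block["mu_range"])
    block.setdefault("seed", stage_seed(seed, "simulate"))
    return SimulationConfig(**block)


def _load_or_simulate(
    cfg: dict[str, Any], seed: int, out_dir: Path
) -> tuple[NPXMatrix, SimulationTruth | None]:
    if cfg.get("input"):
        inp = cfg["input"]
        matrix = npx_io.read_npx_long(inp["npx"], inp["annotations"])
        return matrix, None
    sim_cfg = _simulation_config(cfg, seed)
    matrix, truth = simulate_full(sim_cfg)
    npx_io.write_npx_long(matrix, out_dir / "simulated_npx.tsv", out_dir / "simulated_annotations.tsv")
    truth_rows = [
        {
            "protein": g,
            "class": truth.class_of[g],
            "delta": truth.delta_g[g],
            "gamma": truth.gamma_g[g],
            "beta": truth.beta_g[g],
        }
        for g in truth.protein_ids
    ]
    write_table(pd.DataFrame(truth_rows), out_dir / "simulation_truth.tsv")
    return matrix, truth


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    membership_rule: str | None = None,
) -> dict[str, Any]:
    """Execute the full pipeline from a YAML config; return the manifest."""
    t_start = time.time()
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    out_dir = Path(out_dir or cfg.get("out_dir", "npxscreen_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    acfg = _analysis_config(cfg, seed)
    if membership_rule:
        acfg.membership_rule = membership_rule

    stage_counts: dict[str, int] = {}
    outputs: list[Path] = []
    summary: dict[str, Any] = {"alpha": acfg.alpha, "membership_rule": acfg.membership_rule}

    def fail(stage: str, err: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # ---- input ----
    try:
        matrix, truth = _load_or_simulate(cfg, seed, out_dir)
        design = npx_io.validate_design(matrix)
    except Exception as err:
        raise fail("input", err) from err
    stage_counts["proteins"] = len(matrix.proteins)
    stage_counts["samples"] = len(matrix.samples)

    # ---- differential expression + screen ----
    try:
        results = ortho_screen.run_contrasts(matrix, design, acfg)
        dep_counts: dict[str, Any] = {}
        for name, res in results.items():
            for rule in ("p_only", "p_and_fc"):
                _, counts = diffexp.classify_deps(res, acfg, rule=rule)
                dep_counts.setdefault(name, {})[rule] = counts
            diffexp.classify_deps(res, acfg)  # leave configured-rule labels on the result
            path = out_dir / f"contrast_{name}.tsv"
            write_table(res.to_frame(), path)
            outputs.append(path)
        sets = ortho_screen.build_screen_sets(results, acfg)
        path = out_dir / "screen_sets.tsv"
        write_table(sets.to_frame(), path)
        outputs.append(path)
    except Exception as err:
        raise fail("screen", err) from err
    summary["dep_counts"] = dep_counts
    summary["set_cardinalities"] = sets.cardinalities()
    stage_counts["screen_universe"] = len(sets.universe)

    if truth is not None:
        recovery = ortho_screen.evaluate_recovery(sets, truth)
        path = out_dir / "recovery_report.tsv"
        write_table(recovery.to_frame(), path)
        outputs.append(path)
        summary["recovery"] = {
            "sensitivity": recovery.sensitivity,
            "specificity": recovery.specificity,
            "leakage": recovery.leakage,
        }

    # ---- clinical associations ----
    have_scores = any(s.nihss is not None for s in matrix.samples)
    if have_scores:
        try:
            corr_records = []
            for score in ("NIHSS", "ESRS"):
                corr_records += clinical_assoc.spearman_scores(
                    matrix, design, score, scope=acfg.correlation_scope, alpha=acfg.alpha
                )
            path = out_dir / "correlations.tsv"
            write_table(clinical_assoc.correlations_frame(corr_records), path)
            outputs.append(path)
            nihss_records = [r for r in corr_records if r.score_name.startswith("NIHSS")]
            overlap, n_overlap = clinical_assoc.overlap_with_core(nihss_records, sets)
            summary["nihss_significant"] = sum(r.significant for r in nihss_records)
            summary["esrs_significant"] = sum(
                r.significant for r in corr_records if r.score_name.startswith("ESRS")
            )
            summary["nihss_core_overlap"] = {"proteins": overlap, "count": n_overlap}
        except Exception as err:
            raise fail("clinical_assoc", err) from err

    sexes = {s.sex.value for s in matrix.samples}
    if {"male", "female"} <= sexes:
        try:
            sex_records = []
            for tp in (Timepoint.BASELINE, Timepoint.POST):
                sex_records += clinical_assoc.sex_comparison(matrix, design, tp, acfg)
            path = out_dir / "sex_comparison.tsv"
            write_table(clinical_assoc.sex_comparison_frame(sex_records), path)
            outputs.append(path)
            summary["sex_significant_after_fdr"] = {
                tp.value: sum(
                    r.significant_after_fdr for r in sex_records if r.timepoint == tp.value
                )
                for tp in (Timepoint.BASELINE, Timepoint.POST)
            }
        except Exception as err:
            raise fail("sex_comparison", err) from err

    # ---- feature importance on the treatment-responsive set ----
    if len(sets.set3) >= 2:
        try:
            imp = feature_importance.rf_importance(matrix, design, sets.set3, acfg)
            path = out_dir / "importance.tsv"
            write_table(feature_importance.importance_frame(imp), path)
            outputs.append(path)
            top = min(imp, key=lambda r: r.rank_mda)
            summary["rf_top_protein"] = top.protein
        except Exception as err:
            raise fail("feature_importance", err) from err

    # ---- enrichment ----
    gmt_path = (cfg.get("enrichment") or {}).get("gmt")
    if gmt_path:
        try:
            terms = enrichment.read_gmt(gmt_path)
            symbol_of = {p.assay_id: p.gene_symbol for p in matrix.proteins}
            background = {symbol_of[g] for g in sets.universe}
            tables: dict[str, list] = {}
            for label, query in (("set3", sets.set3), ("set4", sets.set4), ("set5", sets.set5), ("core", sets.core)):
                if not query:
                    continue
                recs = enrichment.hypergeom_ora(
                    {symbol_of[g] for g in query}, background, terms, alpha=acfg.alpha
                )
                path = out_dir / f"enrichment_{label}.tsv"
                write_table(enrichment.enrichment_frame(recs), path)
                outputs.append(path)
                if label != "core":
                    tables[label] = recs
            summary["enrichment_sets_tested"] = sorted(tables)
            if len(tables) >= 2:
                venn = enrichment.intersect_enrichments(tables, alpha=acfg.alpha)
                path = out_dir / "venn_regions.tsv"
                write_table(venn, path)
                outputs.append(path)
        except Exception as err:
            raise fail("enrichment", err) from err

    # ---- summary + manifest ----
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=_json_default))
    outputs.append(summary_path)

    input_digests = {}
    if cfg.get("input"):
        for key in ("npx", "annotations"):
            input_digests[key] = _sha256(Path(cfg["input"][key]))
    manifest = {
        "config": cfg,
        "seed": seed,
        "input_digests": input_digests,
        "stage_counts": stage_counts,
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
        "elapsed_seconds": round(time.time() - t_start, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    manifest["summary"] = summary
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def replicate_study(config_path: str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Recompute the emulated study's printed counts and compare side by side.

    Requires a config whose ``input`` block points at the locally downloaded
    deposit files (Zenodo DOI 10.5281/zenodo.16551369).  Both membership
    rules are run; the comparison table reports the computed count, the
    published count and their difference per quantity and rule.
    """
    cfg = load_config(config_path)
    if not cfg.get("input"):
        raise FileNotFoundError(
            "replication needs the deposited study files; download the deposit at "
            "DOI 10.5281/zenodo.16551369 and point the config 'input' block at the "
            "NPX and annotation tables"
        )
    for key in ("npx", "annotations"):
        p = Path(cfg["input"][key])
        if not p.exists():
            raise FileNotFoundError(
                f"deposit file {p} not found; download it from DOI 10.5281/zenodo.16551369"
            )

    out_dir = Path(out_dir or cfg.get("out_dir", "npxscreen_replicate"))
    rows = []
    for rule in ("p_only", "p_and_fc"):
        manifest = run_pipeline(config_path, out_dir / rule, membership_rule=rule)
        summary = manifest["summary"]
        computed: dict[str, int] = {}
        for name, by_rule in summary["dep_counts"].items():
            counts = by_rule[rule]
            computed[name] = counts["up"] + counts["down"]
        computed.update(summary["set_cardinalities"])
        if "nihss_significant" in summary:
            computed["nihss_significant"] = summary["nihss_significant"]
            computed["esrs_significant"] = summary["esrs_significant"]
            computed["nihss_core_overlap"] = summary["nihss_core_overlap"]["count"]
        for key, published in PUBLISHED_COUNTS.items():
            if key in computed:
                rows.append(
                    {
                        "quantity": key,
                        "membership_rule": rule,
                        "computed": computed[key],
                        "published": published,
                        "difference": computed[key] - published,
                        "agrees": computed[key] == published,
                    }
                )
    table = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(table, Path(out_dir) / "replication_comparison.tsv")
    return table
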