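"""End-to-end orchestration: extract -> cascades -> rank -> enrich -> kg ->
linkpred, with the survival comparison as an independent stage.

Each stage reads its inputs, writes its artifacts under ``outdir``,
checksums them, and contributes counts/parameters/warnings to a run report
(JSON + markdown). A failing stage stops the run, leaves earlier artifacts
intact, and marks downstream stages skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cascades import (build_graph, enumerate_cascades, eda_summary,
                       level_histogram, to_cascade_table, table_to_cascades)
from .enrichment import enrich_cascades, load_gmt, to_report_frame
from .extraction import (collapse_modes, edges_to_frame, filter_tf_edges,
                         load_actions, load_id_map, load_registry,
                         map_and_dedupe, registry_to_protein_ids,
                         annotate_context)
from .kg import assemble_kg, export_kg, kg_summary, tf_subgraph
from .linkpred import evaluate_link_prediction
from .ranking import build_extraction_graph, prioritize_tfs, rank_table, top_k_tables
from .survival import analyze_endpoints, group_summary, load_survival

logger = logging.getLogger(__name__)

STAGE_ORDER = ("extract", "cascades", "rank", "enrich", "kg", "linkpred",
               "survival")

#: upstream requirements within one run
_DEPENDS = {
    "extract": (),
    "cascades": ("extract",),
    "rank": ("cascades",),
    "enrich": ("cascades",),
    "kg": ("cascades", "enrich"),
    "linkpred": ("kg",),
    "survival": (),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = config.resolve("outdir")
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "stages": {},
        "artifacts": {},
        "warnings": [],
    }
    state: dict = {}
    completed: set[str] = set()

    def record(stage: str, info: dict, files: dict[str, Path]) -> None:
        report["stages"][stage] = info
        for name, path in files.items():
            report["artifacts"][name] = {
                "path": str(path), "sha256": _sha256(path),
            }
        completed.add(stage)

    for stage in enabled:
        missing_dep = [d for d in _DEPENDS[stage]
                       if d in enabled and d not in completed]
        if missing_dep or any(d not in enabled and d in _DEPENDS[stage]
                              and d not in completed for d in _DEPENDS[stage]):
            report["stages"][stage] = {"status": "skipped",
                                       "reason": f"missing upstream {_DEPENDS[stage]}"}
            continue
        try:
            _run_stage(stage, config, state, record, outdir)
        except Exception as exc:  # fail fast, keep prior artifacts
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            for later in enabled[enabled.index(stage) + 1:]:
                if stage in _DEPENDS.get(later, ()):  # direct dependents
                    report["stages"][later] = {"status": "skipped",
                                               "reason": f"upstream {stage} failed"}
            write_report(report, outdir)
            raise StageError(stage, exc) from exc

    write_report(report, outdir)
    return report


def _require_input(config: PipelineConfig, name: str) -> Path:
    p = config.resolve(name)
    if not p.exists():
        raise FileNotFoundError(f"input {name!r} not found at {p}")
    return p


def _run_stage(stage: str, config: PipelineConfig, state: dict,
               record, outdir: Path) -> None:
    if stage == "extract":
        actions_path = _require_input(config, "actions")
        registry = load_registry(_require_input(config, "tf_registry"))
        id_map = load_id_map(_require_input(config, "id_map"))
        loaded = load_actions(actions_path)
        tf_ids = registry_to_protein_ids(registry, id_map)
        filtered = filter_tf_edges(loaded.records, tf_ids,
                                   min_score=config.min_score,
                                   modes=config.modes)
        deduped = map_and_dedupe(filtered.edges, id_map)
        edges = collapse_modes(deduped.edges)
        state["edges"] = edges
        frame = edges_to_frame(edges)
        path = outdir / "edges.tsv"
        frame.to_csv(path, sep="\t", index=False)
        alt_path = config.resolve("alterations")
        if alt_path.exists():
            annot = annotate_context(edges, pd.read_csv(alt_path))
            annot_path = outdir / "gene_annotations.csv"
            annot.to_csv(annot_path, index=False)
            state["alterations"] = pd.read_csv(alt_path)
        record("extract", {
            "status": "ok",
            "n_rows": loaded.n_rows,
            "n_rejected_rows": len(loaded.rejected),
            "n_filtered_edges": len(filtered.edges),
            "reject_counts": dict(filtered.reject_counts),
            "n_duplicates_collapsed": deduped.n_duplicates,
            "n_self_loops_removed": deduped.n_self_loops,
            "n_edges": len(edges),
        }, {"edges": path})

    elif stage == "cascades":
        graph = build_graph(state["edges"])
        cascades = enumerate_cascades(graph,
                                      max_length=config.max_length,
                                      max_cascades=config.max_cascades,
                                      include_prefixes=config.include_prefixes)
        state["cascades"] = cascades
        table = to_cascade_table(cascades)
        state["cascade_table"] = table
        path = outdir / "cascades.csv"
        table.to_csv(path, index=False)
        hist = level_histogram(table)
        hist_path = outdir / "level_histogram.csv"
        pd.DataFrame(sorted(hist.items()),
                     columns=["chain_length", "frequency"]).to_csv(
            hist_path, index=False)
        eda = eda_summary(table)
        eda_path = outdir / "eda_summary.json"
        eda_path.write_text(json.dumps(eda, indent=1))
        record("cascades", {
            "status": "ok",
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_cascades": len(cascades),
            "level_histogram": {str(k): v for k, v in hist.items()},
        }, {"cascades": path, "level_histogram": hist_path,
            "eda_summary": eda_path})

    elif stage == "rank":
        xg = build_extraction_graph(state["cascades"])
        state["extraction_graph"] = xg
        tab = rank_table(xg, damping=config.damping,
                         iterations=config.iterations, init=config.init)
        counts = {tf: int(c) for tf, c in
                  xg.nodes(data="cascade_count", default=0)}
        alt = state.get("alterations",
                        pd.DataFrame({"gene": []}))
        pri = prioritize_tfs(tab, counts, alt,
                             min_cascades=config.min_cascades_prioritized,
                             min_cohorts=config.min_cohorts)
        state["rank_table"] = pri
        path = outdir / "rank_table.csv"
        pri.to_csv(path, index=False)
        occ_sum = sum(d["occurrence_count"] for _, _, d in xg.edges(data=True))
        record("rank", {
            "status": "ok",
            "n_nodes": xg.number_of_nodes(),
            "n_unique_edges": xg.number_of_edges(),
            "occurrence_count_sum": occ_sum,
            "n_prioritized": int(pri["prioritized"].sum()),
        }, {"rank_table": path})

    elif stage == "enrich":
        library = load_gmt(_require_input(config, "gmt"))
        results, summary = enrich_cascades(state["cascade_table"], library,
                                           alpha=config.alpha)
        state["enrichment"] = results
        path = outdir / "enrichment.csv"
        to_report_frame(results).to_csv(path, index=False)
        record("enrich", {"status": "ok", **summary}, {"enrichment": path})

    elif stage == "kg":
        kg = assemble_kg(state["cascades"], state["enrichment"],
                         alpha=config.alpha)
        state["kg"] = kg
        path = outdir / "kg.graphml"
        export_kg(kg, path, format="graphml")
        summ = kg_summary(kg)
        record("kg", {"status": "ok", **summ}, {"kg": path})

    elif stage == "linkpred":
        sub = tf_subgraph(state["kg"])
        rep = evaluate_link_prediction(
            sub, mode=config.linkpred_mode, seed=config.seed,
            train_frac=config.train_frac, num_walks=config.num_walks,
            walk_length=config.walk_length, dim=config.embedding_dim,
            window=config.window, epochs=config.epochs)
        path = outdir / "linkpred_report.csv"
        rep.to_frame().to_csv(path, index=False)
        record("linkpred", {
            "status": "ok", "auc": rep.auc, "best_operator": rep.best_operator,
            "mode": rep.mode, "split_sizes": rep.split_sizes,
        }, {"linkpred": path})

    elif stage == "survival":
        records = load_survival(_require_input(config, "survival"))
        table = analyze_endpoints(records)
        path = outdir / "survival_endpoints.csv"
        table.to_csv(path, index=False)
        summ = group_summary(records, "overall")
        summ_path = outdir / "survival_groups.csv"
        summ.to_csv(summ_path, index=False)
        record("survival", {
            "status": "ok",
            "endpoints": {r["Survival Type"]: {"p": r["p-Value"],
                                               "q": r["q-Value"]}
                          for _, r in table.iterrows()},
        }, {"survival_endpoints": path, "survival_groups": summ_path})

    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")


def write_report(report: dict, outdir: Path) -> tuple[Path, Path]:
    """Persist the run report as JSON and human-readable markdown."""
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "run_report.json"
    json_path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                    default=str))
    lines = ["# tfcascade run report", ""]
    for stage, info in report.get("stages", {}).items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    md_path = outdir / "run_report.md"
    md_path.write_text("\n".join(lines))
    return json_path, md_path
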