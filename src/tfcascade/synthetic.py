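"""Synthetic input generator with planted ground truth.

Emulates the six external inputs of the cascade pipeline — a STRING-actions
style interaction table, a TF registry, a protein-ID/gene-symbol map, a GMT
gene-set library, a per-gene alteration-frequency table and a survival
table — with structure planted so that every downstream stage has a
closed-loop test: known cascades, known enriched pathways and a known
between-group hazard ratio.

All randomness flows from ``SimulationConfig.seed``; a fixed seed gives
byte-identical artifact files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig

ACTIONS_COLUMNS = [
    "item_id_a",
    "item_id_b",
    "mode",
    "action",
    "is_directional",
    "a_is_acting",
    "score",
]

ENDPOINTS = ("disease_specific", "overall", "progression_free", "disease_free")

#: baseline monthly event rates per endpoint for the unaltered group
#: (median survival ln2/rate: 90, 75, 60 and 120 months respectively)
_BASE_RATES = {
    "disease_specific": np.log(2) / 90.0,
    "overall": np.log(2) / 75.0,
    "progression_free": np.log(2) / 60.0,
    "disease_free": np.log(2) / 120.0,
}


@dataclass
class SyntheticInteractions:
    """Actions table plus registry, ID map and planted ground truth."""

    actions: pd.DataFrame
    tf_registry: list[str]
    id_map: pd.DataFrame
    planted_cascades: list[list[str]]

    @property
    def symbol_of(self) -> dict[str, str]:
        return dict(zip(self.id_map["protein_id"], self.id_map["gene_symbol"]))


def _symbols(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i:04d}" for i in range(1, config.n_tfs + 1)]
    nontfs = [f"NT{i:04d}" for i in range(1, config.n_nontf + 1)]
    return tfs, nontfs


def _protein_ids(symbols: Sequence[str]) -> dict[str, str]:
    return {sym: f"ENSP_SIM{i:04d}" for i, sym in enumerate(symbols, start=1)}


def plant_paths(config: SimulationConfig, rng: np.random.Generator) -> list[list[str]]:
    """Assign TF symbols to the planted simple chains.

    Node-disjoint by default so the planted set equals the expected
    enumerated cascade set; with ``allow_overlap`` paths may share nodes.
    """
    tfs, _ = _symbols(config)
    order = list(rng.permutation(tfs))
    paths: list[list[str]] = []
    cursor = 0
    for length, count in config.planted_paths:
        for _ in range(count):
            if config.allow_overlap:
                chain = list(rng.choice(tfs, size=length, replace=False))
            else:
                chain = order[cursor : cursor + length]
                cursor += length
            paths.append(chain)
    return paths


def simulate_interactions(config: SimulationConfig) -> SyntheticInteractions:
    """Emit an actions-dialect table containing every planted edge plus noise.

    Planted edges are directional, mode activation/inhibition, score >= 700.
    Noise comprises: sub-threshold TF-TF rows, non-directional rows,
    non-regulatory modes (binding), non-TF pairs, duplicated planted rows
    with a lower score, and (with probability ``extra_edge_prob``) extra
    high-confidence TF-TF edges that never point into a planted-path
    interior, keeping the planted cascade set exact when
    ``extra_edge_prob = 0``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tfs, nontfs = _symbols(config)
    all_symbols = tfs + nontfs
    pid = _protein_ids(all_symbols)

    paths = plant_paths(config, rng)
    planted_edges: list[tuple[str, str]] = []
    interiors: set[str] = set()
    for chain in paths:
        planted_edges.extend(zip(chain[:-1], chain[1:]))
        interiors.update(chain[1:])
    planted_set = set(planted_edges)

    rows: list[tuple] = []

    def emit(src: str, dst: str, mode: str, directional: bool, score: int,
             flip_ok: bool = True) -> None:
        # randomly present the pair as (a=src) or (a=dst, a_is_acting=f) to
        # exercise the orientation rule downstream
        flip = flip_ok and directional and rng.random() < 0.5
        a, b = (dst, src) if flip else (src, dst)
        rows.append((
            pid[a], pid[b], mode, mode,
            "t" if directional else "f",
            ("f" if flip else "t") if directional else "f",
            int(score),
        ))

    hi = lambda: int(rng.integers(700, config.score_high + 1))
    lo = lambda: int(rng.integers(config.score_low, 700))

    for src, dst in planted_edges:
        mode = "activation" if rng.random() < 0.7 else "inhibition"
        emit(src, dst, mode, True, hi())
        if rng.random() < 0.3:  # duplicate with a lower score
            emit(src, dst, mode, True, int(rng.integers(700, 800)))

    # sub-threshold / undirected / wrong-mode noise between TFs
    n_low = max(0, int(round(config.extra_edge_prob * 4 * config.n_tfs)))
    for _ in range(n_low):
        u, v = rng.choice(tfs, size=2, replace=False)
        kind = rng.random()
        if kind < 0.4:
            emit(u, v, "activation", True, lo())
        elif kind < 0.7:
            emit(u, v, "activation", False, hi())
        else:
            emit(u, v, "binding", rng.random() < config.p_directed, hi())

    # high-confidence extra edges; never into a planted interior unless
    # overlap is allowed
    if config.extra_edge_prob > 0:
        allowed_targets = [t for t in tfs
                           if config.allow_overlap or t not in interiors]
        n_extra = rng.binomial(config.n_tfs * 2, config.extra_edge_prob)
        for _ in range(n_extra):
            if not allowed_targets:
                break
            u = str(rng.choice(tfs))
            v = str(rng.choice(allowed_targets))
            if u == v or (u, v) in planted_set:
                continue
            mode = "activation" if rng.random() < 0.7 else "inhibition"
            emit(u, v, mode, True, hi())

    # non-TF pairs (filtered out by the registry rule)
    for _ in range(max(1, config.n_nontf // 2) if nontfs else 0):
        u = str(rng.choice(nontfs))
        v = str(rng.choice(all_symbols))
        if u == v:
            continue
        emit(u, v, "activation", True, hi())

    actions = pd.DataFrame(rows, columns=ACTIONS_COLUMNS)
    id_map = pd.DataFrame(
        {"protein_id": [pid[s] for s in all_symbols], "gene_symbol": all_symbols}
    )
    return SyntheticInteractions(
        actions=actions,
        tf_registry=list(tfs),
        id_map=id_map,
        planted_cascades=sorted(paths),
    )


def _target_sets(config: SimulationConfig,
                 paths: list[list[str]]) -> list[list[str]]:
    if config.enriched_pathway_targets is not None:
        return [sorted(s) for s in config.enriched_pathway_targets]
    return [sorted(chain) for chain in paths[:3]]


def simulate_gene_sets(config: SimulationConfig,
                       planted_cascades: Optional[list[list[str]]] = None
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Build the gene-set library as a (set_name, description, genes) table.

    The first ``len(targets)`` sets contain their full target TF set (plus
    random padding), so a query equal to a target set yields a hypergeometric
    overlap far beyond chance; remaining sets sample uniformly from the
    universe. Returns the library table and the list of enriched set names.
    """
    config.validate()
    if config.n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    tfs, nontfs = _symbols(config)
    universe = tfs + nontfs
    lo, hi = config.pathway_size_range
    if hi > len(universe):
        raise ValueError(
            f"pathway_size_range max {hi} exceeds universe of {len(universe)} genes"
        )
    if planted_cascades is None:
        planted_cascades = plant_paths(config, np.random.default_rng(config.seed))
    targets = _target_sets(config, planted_cascades)
    if len(targets) > config.n_pathways:
        raise ValueError("more enriched target sets than pathways")

    names, descs, members = [], [], []
    enriched_names = []
    for i in range(config.n_pathways):
        name = f"PATH{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < len(targets):
            core = list(targets[i])
            pad_pool = [g for g in universe if g not in set(core)]
            n_pad = max(0, size - len(core))
            genes = core + list(rng.choice(pad_pool, size=n_pad, replace=False))
            desc = "planted enriched set"
            enriched_names.append(name)
        else:
            genes = list(rng.choice(universe, size=size, replace=False))
            desc = "background set"
        names.append(name)
        descs.append(desc)
        members.append(sorted(set(genes)))
    lib = pd.DataFrame({"set_name": names, "description": descs, "genes": members})
    return lib, enriched_names


def write_gmt(library: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in library.iterrows():
            fh.write("\t".join([row["set_name"], row["description"], *row["genes"]]))
            fh.write("\n")


def simulate_survival(config: SimulationConfig) -> pd.DataFrame:
    """Four-endpoint cohort with exponential event times.

    Event times in the altered group run at ``hazard_ratio`` times the
    endpoint's baseline rate; censoring is independent with probability
    ``censor_prob`` (a censored patient is observed for a uniform fraction
    of the latent event time).
    """
    config.validate()
    if not 0.0 < config.altered_fraction < 1.0:
        raise ValueError("altered_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_patients
    altered = rng.random(n) < config.altered_fraction
    recs = []
    for endpoint in ENDPOINTS:
        base = _BASE_RATES[endpoint]
        rate = np.where(altered, base * config.hazard_ratio, base)
        t = rng.exponential(1.0 / rate)
        censored = rng.random(n) < config.censor_prob
        months = np.where(censored, t * rng.random(n), t)
        for i in range(n):
            recs.append((
                f"P{i + 1:05d}",
                endpoint,
                float(round(months[i], 4)),
                int(not censored[i]),
                "altered" if altered[i] else "unaltered",
            ))
    return pd.DataFrame(
        recs, columns=["patient_id", "endpoint", "months", "event", "group"]
    )


def simulate_alterations(config: SimulationConfig,
                         planted_cascades: Optional[list[list[str]]] = None
                         ) -> pd.DataFrame:
    """Per-gene alteration frequencies across ``n_cohorts`` synthetic cohorts.

    Planted-cascade members (the priority TFs of the closed loop) receive a
    non-zero frequency in every cohort; other genes are sparsely altered.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    tfs, nontfs = _symbols(config)
    if planted_cascades is None:
        planted_cascades = plant_paths(config, np.random.default_rng(config.seed))
    priority = set(g for chain in planted_cascades for g in chain)
    cohorts = [f"cohort_{i + 1}" for i in range(config.n_cohorts)]
    rows = []
    for gene in tfs + nontfs:
        freqs = []
        for _ in cohorts:
            if gene in priority:
                freqs.append(float(round(rng.uniform(0.01, 0.4), 4)))
            else:
                freqs.append(
                    float(round(rng.uniform(0.0, 0.2), 4))
                    if rng.random() < 0.3 else 0.0
                )
        rows.append([gene, *freqs])
    return pd.DataFrame(rows, columns=["gene", *cohorts])


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write all six artifacts plus the ground-truth JSON; return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_interactions(config)
    library, enriched = simulate_gene_sets(config, sim.planted_cascades)
    surv = simulate_survival(config)
    alts = simulate_alterations(config, sim.planted_cascades)

    paths = {
        "actions": outdir / "actions.tsv",
        "tf_registry": outdir / "tf_registry.txt",
        "id_map": outdir / "id_map.tsv",
        "gmt": outdir / "pathways.gmt",
        "survival": outdir / "survival.csv",
        "alterations": outdir / "alterations.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    sim.actions.to_csv(paths["actions"], sep="\t", index=False)
    paths["tf_registry"].write_text("\n".join(sim.tf_registry) + "\n")
    sim.id_map.to_csv(paths["id_map"], sep="\t", index=False)
    write_gmt(library, paths["gmt"])
    surv.to_csv(paths["survival"], index=False)
    alts.to_csv(paths["alterations"], index=False)
    truth = {
        "planted_cascades": sim.planted_cascades,
        "enriched_pathways": enriched,
        "config": config.as_dict(),
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
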