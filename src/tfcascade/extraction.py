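"""Parsing and filtering of STRING-actions style interaction tables.

The actions dialect is tab-separated with columns item_id_a, item_id_b,
mode, action, is_directional, a_is_acting, score (0-1000 combined
confidence). Extraction keeps only directional regulatory edges
(activation/inhibition) between registry TFs at high confidence
(score >= 700), orients them regulator -> target, maps protein IDs to gene
symbols and deduplicates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "item_id_a",
    "item_id_b",
    "mode",
    "is_directional",
    "a_is_acting",
    "score",
]

REGULATORY_MODES = ("activation", "inhibition")

_TRUTHY = {"t", "true", "1", "yes"}
_FALSY = {"f", "false", "0", "no", ""}


class FormatError(ValueError):
    """Raised when an input file lacks required structure."""


@dataclass(frozen=True)
class InteractionRecord:
    """One row of the actions table."""

    item_a: str
    item_b: str
    mode: str
    is_directional: bool
    a_is_acting: bool
    score: int


@dataclass(frozen=True)
class DirectedEdge:
    """A regulator -> target edge with regulation mode and confidence score."""

    regulator: str
    target: str
    mode: str
    score: int


@dataclass
class LoadedActions:
    records: list[InteractionRecord]
    rejected: list[tuple[int, str]]  # (1-based line number, reason)
    n_rows: int = 0


@dataclass
class FilterResult:
    edges: list[DirectedEdge]
    reject_counts: Counter = field(default_factory=Counter)


@dataclass
class DedupeResult:
    edges: list[DirectedEdge]
    n_duplicates: int = 0
    n_self_loops: int = 0


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"not a boolean flag: {value!r}")


def load_actions(path: str | Path) -> LoadedActions:
    """Parse an actions TSV; malformed rows are recorded, not fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"actions table missing column(s): {', '.join(missing)}")
    records: list[InteractionRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        try:
            score = int(str(getattr(row, "score")).strip())
        except ValueError:
            rejected.append((line_no, f"non-integer score {getattr(row, 'score')!r}"))
            continue
        if not 0 <= score <= 1000:
            rejected.append((line_no, f"score {score} outside [0, 1000]"))
            continue
        a = str(getattr(row, "item_id_a")).strip()
        b = str(getattr(row, "item_id_b")).strip()
        if not a or not b:
            rejected.append((line_no, "empty item id"))
            continue
        if a == b:
            rejected.append((line_no, "self-interaction"))
            continue
        try:
            directional = _parse_bool(getattr(row, "is_directional"))
            acting = _parse_bool(getattr(row, "a_is_acting"))
        except ValueError as exc:
            rejected.append((line_no, str(exc)))
            continue
        records.append(InteractionRecord(
            item_a=a, item_b=b, mode=str(getattr(row, "mode")).strip().lower(),
            is_directional=directional, a_is_acting=acting, score=score,
        ))
    logger.info("loaded %d/%d action rows from %s (%d rejected)",
                len(records), len(df), path, len(rejected))
    return LoadedActions(records=records, rejected=rejected, n_rows=len(df))


def load_registry(path: str | Path) -> list[str]:
    """TF registry: one identifier per line, upper-cased, order preserved."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip().upper()
        if sym and sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def load_id_map(path: str | Path) -> dict[str, str]:
    """Two-column protein-ID -> gene-symbol table (TSV, header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("id map needs two columns (protein id, gene symbol)")
    keys = df.iloc[:, 0].str.strip()
    vals = df.iloc[:, 1].str.strip().str.upper()
    if (vals == "").any():
        raise FormatError("id map contains empty gene symbols")
    if keys.duplicated().any():
        dups = sorted(keys[keys.duplicated()].unique())
        raise FormatError(f"duplicate protein ids in map: {dups[:5]}")
    return dict(zip(keys, vals))


def registry_to_protein_ids(registry: Iterable[str],
                            id_map: Mapping[str, str]) -> set[str]:
    """Protein IDs whose mapped symbol is in the registry (symbol space)."""
    wanted = {s.upper() for s in registry}
    return {pid for pid, sym in id_map.items() if sym.upper() in wanted}


def filter_tf_edges(records: Iterable[InteractionRecord],
                    registry: Iterable[str],
                    min_score: int = 700,
                    modes: Sequence[str] = REGULATORY_MODES) -> FilterResult:
    """Keep directional regulatory TF-TF records at high confidence.

    Retention requires, in order checked: both endpoints in ``registry``,
    score >= ``min_score`` (inclusive), is_directional, and mode among
    ``modes``. Orientation: regulator = item_a when a_is_acting, else
    item_b. Rejections are tallied per reason.
    """
    allowed = {s.upper() for s in registry}
    if not allowed:
        raise ValueError("TF registry is empty")
    mode_set = {m.lower() for m in modes}
    edges: list[DirectedEdge] = []
    rejects: Counter = Counter()
    for rec in records:
        if rec.item_a.upper() not in allowed or rec.item_b.upper() not in allowed:
            rejects["non_tf_endpoint"] += 1
            continue
        if rec.score < min_score:
            rejects["low_score"] += 1
            continue
        if not rec.is_directional:
            rejects["undirected"] += 1
            continue
        if rec.mode not in mode_set:
            rejects["non_regulatory_mode"] += 1
            continue
        reg, tgt = (rec.item_a, rec.item_b) if rec.a_is_acting else (rec.item_b, rec.item_a)
        edges.append(DirectedEdge(regulator=reg, target=tgt,
                                  mode=rec.mode, score=rec.score))
    logger.info("retained %d edges (%s)", len(edges), dict(rejects))
    return FilterResult(edges=edges, reject_counts=rejects)


def map_and_dedupe(edges: Iterable[DirectedEdge],
                   id_map: Mapping[str, str]) -> DedupeResult:
    """Rename endpoints to gene symbols, drop self-loops, collapse duplicates.

    Exact duplicates on (regulator, target, mode) keep the maximum score.
    Self-loops produced by a many-to-one mapping are removed and counted.
    Raises if any endpoint protein ID is unmapped, listing the misses.
    """
    edges = list(edges)
    missing = sorted({e.regulator for e in edges if e.regulator not in id_map}
                     | {e.target for e in edges if e.target not in id_map})
    if missing:
        raise KeyError(f"unmapped protein id(s): {missing}")
    best: dict[tuple[str, str, str], int] = {}
    n_self = 0
    n_dup = 0
    for e in edges:
        reg, tgt = id_map[e.regulator], id_map[e.target]
        if reg == tgt:
            n_self += 1
            continue
        key = (reg, tgt, e.mode)
        if key in best:
            n_dup += 1
            best[key] = max(best[key], e.score)
        else:
            best[key] = e.score
    out = [DirectedEdge(regulator=k[0], target=k[1], mode=k[2], score=s)
           for k, s in sorted(best.items())]
    return DedupeResult(edges=out, n_duplicates=n_dup, n_self_loops=n_self)


def collapse_modes(edges: Iterable[DirectedEdge]) -> list[DirectedEdge]:
    """Collapse per-(regulator, target) across modes, keeping the max score.

    When both activation and inhibition rows survive for the same ordered
    pair the mode of the higher-scoring row wins (ties: activation).
    """
    best: dict[tuple[str, str], DirectedEdge] = {}
    for e in sorted(edges, key=lambda e: (e.regulator, e.target,
                                          -e.score, e.mode)):
        key = (e.regulator, e.target)
        if key not in best:
            best[key] = e
    return [best[k] for k in sorted(best)]


def edges_to_frame(edges: Iterable[DirectedEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.regulator, e.target, e.mode, e.score) for e in edges],
        columns=["regulator", "target", "mode", "score"],
    )


def annotate_context(edges: Iterable[DirectedEdge],
                     alteration_table: pd.DataFrame,
                     tissue_table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-gene annotation for edge endpoints: cohort alteration frequencies.

    Left-join on gene symbol; genes without alteration data get frequency 0
    in every cohort and ``no_data = True``. ``altered_any`` flags a non-zero
    frequency in at least one cohort. An optional tissue table (gene,
    tissue) is joined as a comma-separated ``tissues`` column.
    """
    genes = sorted({e.regulator for e in edges} | {e.target for e in edges})
    out = pd.DataFrame({"gene": genes})
    cohorts = [c for c in alteration_table.columns if c != "gene"]
    out = out.merge(alteration_table, on="gene", how="left")
    out["no_data"] = out[cohorts].isna().all(axis=1) if cohorts else True
    out[cohorts] = out[cohorts].fillna(0.0)
    out["altered_any"] = (out[cohorts] > 0).any(axis=1) if cohorts else False
    out["n_cohorts_altered"] = (out[cohorts] > 0).sum(axis=1) if cohorts else 0
    if tissue_table is not None and {"gene", "tissue"} <= set(tissue_table.columns):
        tt = (tissue_table.groupby("gene")["tissue"]
              .apply(lambda s: ",".join(sorted(set(s)))).rename("tissues"))
        out = out.merge(tt, on="gene", how="left")
        out["tissues"] = out["tissues"].fillna("")
    return out
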