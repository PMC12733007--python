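"""Over-representation analysis of TF sets against GMT gene-set libraries.

For a query of size n drawn from a universe of N genes and a pathway of
size K with overlap k, significance is the one-sided hypergeometric upper
tail P(X >= k). Odds ratios use the 2x2 contingency table with a Haldane
0.5 correction on zero cells; the z-score standardises k against the
hypergeometric mean and variance, and the combined score is the
Enrichr-style -ln(p) * z. Benjamini-Hochberg step-up adjusts across all
sets of a library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["pathway", "p", "p_adjusted", "odds_ratio", "z", "combined",
                  "overlap", "overlap_size"]


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets (GMT semantics)."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


def load_gmt(path: str | Path, name: Optional[str] = None) -> GeneSetLibrary:
    """Parse a GMT file: one set per line (name, description, members).

    Blank lines are skipped; duplicate member symbols within a set collapse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lib = GeneSetLibrary(name=name or path.stem)
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, "
                             f"genes): {line[:80]!r}")
        set_name, desc = parts[0], parts[1]
        members = frozenset(g.strip() for g in parts[2:] if g.strip())
        if not members:
            raise ValueError(f"gene set {set_name!r} has no members")
        if set_name in lib.sets:
            raise ValueError(f"duplicate set name {set_name!r}")
        lib.sets[set_name] = (desc, members)
    return lib


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values in input order.

    q(i) = min_{j >= i} (p(j) * m / j) over the ascending-sorted p-values,
    capped at 1 and mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _single_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float, float]:
    """(p, odds_ratio, z) for one 2x2 overlap table."""
    # one-sided upper tail P(X >= k), X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    mean = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
    z = (k - mean) / np.sqrt(var) if var > 0 else 0.0
    return p, float(odds), float(z)


def enrich(query: Iterable[str],
           library: GeneSetLibrary,
           universe_size: Optional[int] = None,
           cascade_id: Optional[int] = None) -> pd.DataFrame:
    """Test a query gene set against every set of the library.

    ``universe_size`` defaults to |query ∪ all library genes| and must be at
    least the size of any observed union. Combined score is -ln(p) * z.
    Rows are sorted by adjusted p, ties by raw p then name.
    """
    q = frozenset(query)
    if not q:
        raise ValueError("query gene set is empty")
    observed = q | library.all_genes
    if universe_size is None:
        universe_size = len(observed)
    if universe_size < len(observed):
        raise ValueError(
            f"universe_size {universe_size} smaller than observed union "
            f"of {len(observed)} genes"
        )
    rows = []
    for set_name in sorted(library.sets):
        _, members = library.sets[set_name]
        overlap = sorted(q & members)
        k = len(overlap)
        p, odds, z = _single_enrichment(k, len(q), len(members), universe_size)
        with np.errstate(divide="ignore"):
            combined = float(-np.log(p) * z) if p > 0 else float("inf")
        rows.append((set_name, p, odds, z, combined, overlap, k))
    df = pd.DataFrame(rows, columns=["pathway", "p", "odds_ratio", "z",
                                     "combined", "overlap", "overlap_size"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    if cascade_id is not None:
        df["cascade_id"] = cascade_id
    df = df.sort_values(["p_adjusted", "p", "pathway"],
                        kind="mergesort").reset_index(drop=True)
    return df


def enrich_cascades(cascade_table: pd.DataFrame,
                    library: GeneSetLibrary,
                    universe_size: Optional[int] = None,
                    alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-cascade over-representation across the whole cascade table.

    Returns the concatenated result table (all results, with a
    ``significant`` flag at p_adjusted <= alpha) and a summary dict with
    total/significant counts and the mean number of results per cascade.
    """
    from .cascades import table_to_cascades

    if universe_size is None and len(library):
        universe_size = None  # resolved per query inside enrich
    results = []
    cascades = table_to_cascades(cascade_table)
    ids = (cascade_table["cascade_id"].tolist()
           if "cascade_id" in cascade_table.columns
           else list(range(1, len(cascades) + 1)))
    universe = None
    if len(library):
        # one shared universe across cascades keeps p-values comparable
        all_query = set()
        for c in cascades:
            all_query |= set(c.chain)
        universe = len(all_query | set(library.all_genes))
    for cid, c in zip(ids, cascades):
        if not len(library):
            continue
        df = enrich(c.chain, library,
                    universe_size=universe_size or universe, cascade_id=cid)
        results.append(df)
    if results:
        out = pd.concat(results, ignore_index=True)
        out["significant"] = out["p_adjusted"] <= alpha
    else:
        out = pd.DataFrame(columns=RESULT_COLUMNS + ["cascade_id", "significant"])
    n_casc = len(cascades)
    summary = {
        "n_cascades": n_casc,
        "n_results": int(len(out)),
        "n_significant": int(out["significant"].sum()) if len(out) else 0,
        "mean_results_per_cascade": float(len(out) / n_casc) if n_casc else 0.0,
        "mean_significant_per_cascade":
            float(out["significant"].sum() / n_casc) if n_casc else 0.0,
    }
    return out, summary


def to_report_frame(results: pd.DataFrame) -> pd.DataFrame:
    """Rename columns to the conventional report layout."""
    ren = {"pathway": "Pathway", "p": "p-Value", "z": "Z-Score",
           "combined": "Combined Score", "p_adjusted": "Adjusted p-Value",
           "cascade_id": "Cascade"}
    cols = [c for c in ("pathway", "p", "z", "combined", "p_adjusted",
                        "cascade_id") if c in results.columns]
    return results[cols].rename(columns=ren)
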