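"""Configuration objects for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence


@dataclass
class SimulationConfig:
    """Parameters controlling all six synthetic input artifacts.

    The defaults describe a desk-scale regulatory network: 60 transcription
    factors, seven planted cascades (five of chain length 4, two of length 7),
    a modest rate of extra high-confidence edges, 20 pathway gene sets of
    which the first few are enriched for planted-cascade members, and a
    500-patient cohort with a two-fold hazard ratio between altered and
    unaltered groups.

    Attributes
    ----------
    n_tfs, n_nontf:
        Number of transcription-factor and non-TF genes in the universe.
    planted_paths:
        List of ``(length, count)`` pairs; each planted path is a simple
        directed chain of ``length`` distinct TFs. Paths are node-disjoint
        unless ``allow_overlap`` is set.
    extra_edge_prob:
        Per-candidate probability of adding a high-confidence noise edge
        between already-assigned TFs.
    p_directed:
        Probability that a noise interaction row is emitted as directional.
    score_low, score_high:
        Range of STRING-style combined scores (0-1000) for sub-threshold and
        planted/high-confidence rows respectively.
    n_pathways, pathway_size_range:
        Gene-set library shape.
    enriched_pathway_targets:
        TF-symbol sets that the first pathways over-sample. ``None`` derives
        one target set per planted path (up to three), closing the
        enrichment-recovery loop by default.
    n_patients, altered_fraction, hazard_ratio, censor_prob:
        Survival-cohort shape: exponential event times with the given rate
        ratio between altered and unaltered groups, independent censoring.
    """

    n_tfs: int = 60
    n_nontf: int = 40
    planted_paths: Sequence[tuple[int, int]] = ((4, 5), (7, 2))
    extra_edge_prob: float = 0.05
    p_directed: float = 0.9
    score_low: int = 150
    score_high: int = 990
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 30)
    enriched_pathway_targets: Optional[Sequence[Sequence[str]]] = None
    n_patients: int = 500
    altered_fraction: float = 0.15
    hazard_ratio: float = 2.0
    censor_prob: float = 0.3
    seed: int = 0
    allow_overlap: bool = False
    n_cohorts: int = 3

    def validate(self) -> None:
        probs = {
            "extra_edge_prob": self.extra_edge_prob,
            "p_directed": self.p_directed,
            "altered_fraction": self.altered_fraction,
            "censor_prob": self.censor_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_tfs < 0 or self.n_nontf < 0:
            raise ValueError("n_tfs and n_nontf must be non-negative")
        if not 0 <= self.score_low <= self.score_high <= 1000:
            raise ValueError(
                f"need 0 <= score_low <= score_high <= 1000, got "
                f"({self.score_low}, {self.score_high})"
            )
        for length, count in self.planted_paths:
            if length < 2:
                raise ValueError(f"planted path length must be >= 2, got {length}")
            if count < 0:
                raise ValueError("planted path count must be >= 0")
            if length > self.n_tfs:
                raise ValueError(
                    f"cannot place a simple path of length {length} among "
                    f"{self.n_tfs} TFs"
                )
        if not self.allow_overlap:
            needed = sum(l * c for l, c in self.planted_paths)
            if needed > self.n_tfs:
                raise ValueError(
                    f"node-disjoint planted paths need {needed} TFs, have {self.n_tfs}"
                )
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("pathway_size_range must satisfy 1 <= min <= max")
        if self.n_cohorts < 1:
            raise ValueError("need at least one cohort")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["planted_paths"] = [list(p) for p in self.planted_paths]
        if self.enriched_pathway_targets is not None:
            d["enriched_pathway_targets"] = [
                sorted(s) for s in self.enriched_pathway_targets
            ]
        return d


@dataclass
class PipelineConfig:
    """Declarative end-to-end pipeline configuration (one YAML file).

    Paths are resolved relative to ``workdir``. Stage toggles default to the
    full extract -> cascades -> rank -> enrich -> kg -> linkpred chain with the
    independent survival stage enabled.
    """

    workdir: Path = Path(".")
    # inputs
    actions: Path = Path("actions.tsv")
    tf_registry: Path = Path("tf_registry.txt")
    id_map: Path = Path("id_map.tsv")
    gmt: Path = Path("pathways.gmt")
    alterations: Path = Path("alterations.csv")
    survival: Path = Path("survival.csv")
    # outputs
    outdir: Path = Path("out")
    # toggles
    stages: Sequence[str] = (
        "extract",
        "cascades",
        "rank",
        "enrich",
        "kg",
        "linkpred",
        "survival",
    )
    # stage parameters
    min_score: int = 700
    modes: Sequence[str] = ("activation", "inhibition")
    max_length: int = 64
    max_cascades: int = 1_000_000
    include_prefixes: bool = False
    damping: float = 0.85
    iterations: int = 10
    init: float = 0.25
    alpha: float = 0.05
    min_cascades_prioritized: int = 1000
    min_cohorts: int = 2
    num_walks: int = 10
    walk_length: int = 80
    embedding_dim: int = 64
    window: int = 5
    epochs: int = 10
    train_frac: float = 0.75
    linkpred_mode: str = "holdout"  # or "full" (transductive, leaky)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("workdir", "actions", "tf_registry", "id_map", "gmt",
                    "alterations", "survival", "outdir"):
            if key in raw:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def resolve(self, name: str) -> Path:
        p: Path = getattr(self, name)
        return p if p.is_absolute() else self.workdir / p
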