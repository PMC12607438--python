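"""Run configuration: thresholds, seed handling, input/output paths.

All filtering thresholds of the pipeline live in :class:`RunConfig` so a
whole analysis is reproducible from one YAML file plus the input files.
Defaults follow the conventional ceRNA screening thresholds:
|log2FC| >= 1 with q <= 0.05 for circRNA/mRNA differential expression,
raw p <= 0.05 for miRNA, site score >= 50 with duplex energy <= -10
kcal/mol for target prediction, Pearson r <= -0.4 (negative edges) /
r >= +0.4 (positive edges) with p <= 0.05 for correlation edges,
PPI confidence >= 0.40 and top-10 miRNA core selection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a deterministic child seed for a named pipeline stage.

    A single user-facing seed governs the whole run; each stochastic
    stage draws from its own stream so that re-running one stage in
    isolation reproduces the full-pipeline behaviour.  The split is a
    blake2 hash of ``"<seed>:<stage>"`` folded to 31 bits.
    """
    digest = hashlib.blake2s(f"{int(root_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Thresholds, seed and paths for one pipeline run."""

    # differential expression
    lfc_min: float = 1.0
    q_max: float = 0.05
    p_max: float = 0.05
    # correlation edges
    r_neg_max: float = -0.4
    r_pos_min: float = 0.4
    corr_p_max: float = 0.05
    correlation_samples: str = "contrast"  # or "all"
    # target prediction
    site_score_min: float = 50.0
    energy_max_kcal: float = -10.0
    # PPI / core network
    ppi_conf_min: float = 0.40
    top_k_mirnas: int = 10
    # reproducibility
    rng_seed: int = 0
    # paths (None means: simulate inputs)
    out_dir: str = "cernanet_run"
    design_path: Optional[str] = None
    counts_paths: dict = field(default_factory=dict)   # layer -> TSV path
    fasta_paths: dict = field(default_factory=dict)    # kind -> FASTA path
    annotation_path: Optional[str] = None
    ppi_path: Optional[str] = None
    whitelist_path: Optional[str] = None
    contrasts: Sequence[Sequence[str]] = ()

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        for name in ("q_max", "p_max", "corr_p_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.r_neg_max < 0 < self.r_pos_min):
            raise ValueError("need r_neg_max < 0 < r_pos_min")
        if not (0 <= self.site_score_min <= 100):
            raise ValueError("site_score_min must lie in [0, 100]")
        if not (0 <= self.ppi_conf_min <= 1):
            raise ValueError("ppi_conf_min must lie in [0, 1]")
        if self.top_k_mirnas < 1:
            raise ValueError("top_k_mirnas must be a positive integer")
        if self.correlation_samples not in ("contrast", "all"):
            raise ValueError("correlation_samples must be 'contrast' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
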