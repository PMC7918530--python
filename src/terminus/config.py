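"""Pipeline configuration: every tunable of every stage in one place.

Defaults are the working values of the method: 100-nt windows with more than
80 positions of depth >= 7, up to 10 coverage segments, 50-nt end clustering,
500-nt terminal windows, the 5%/10% expression-call posteriors, |S1| >= 1,
|S2| >= 0.15 and FDR < 0.01 shift thresholds with the 0.2/0.8 stringent
cell-body fractions, the -100..+50 PAS scan window and 50-nt clone bins.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    # simulation
    seed: int = 0
    n_loci: int = 50
    n_shift: int = 10
    n_background: int = 20
    include_impa1: bool = True
    read_length: int = 150
    end_jitter_sd: float = 10.0
    nb_dispersion: float = 0.2
    replicates: int = 2
    background_rate: float = 0.2
    # expressed-region detection
    window: int = 100
    min_depth: float = 7
    min_positions: int = 80
    max_gap: int = 150
    max_assign_dist: int = 10_000
    # segmentation
    smooth_width: int = 150
    k_max: int = 10
    penalty_alpha: float = 1.0
    cluster_dist: int = 50
    min_drop_fold: float = 1.0
    # quantification / calling
    terminal_window: int = 500
    density_pseudocount: float = 0.01
    mixture_tol: float = 1e-8
    mixture_max_iter: int = 1000
    call_bg_threshold: float = 0.05
    call_expr_threshold: float = 0.10
    strict_calls: bool = False
    # differential usage
    s1_threshold: float = 1.0
    s2_threshold: float = 0.15
    fdr_threshold: float = 0.01
    stringent_low: float = 0.2
    stringent_high: float = 0.8
    score_pseudocount: float = 0.5
    # PAS scan
    pas_upstream: int = 100
    pas_downstream: int = 50
    # cleavage clones
    clone_bin: int = 50

    def __post_init__(self) -> None:
        positive = (
            "window",
            "min_depth",
            "min_positions",
            "k_max",
            "cluster_dist",
            "terminal_window",
            "s1_threshold",
            "s2_threshold",
            "fdr_threshold",
            "clone_bin",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Flat YAML key-value config; explicit keyword overrides win."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
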