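"""Run configuration: one flat set of thresholds, each defaulting to the
values of the study design the pipeline implements."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # differential expression
    fc_hi: float = 2.0          # linear fold-change upper flag threshold (strict >)
    fc_lo: float = 0.5          # linear fold-change lower flag threshold (strict <)
    fdr_max: float = 0.05       # BH q cut-off for DEG calling
    n_perm: int = 1000          # label permutations per probe
    # term enrichment
    kappa_min: float = 0.4      # term-term agreement threshold for network edges
    # network inference
    mi_alpha: float = 0.05      # permutation significance level for the MI threshold
    mi_n_perm: int = 1000       # null MI draws for the threshold
    dpi_tolerance: float = 0.0  # DPI tolerance (0 = strict triangle pruning)
    n_boot: int = 50            # bootstrap rounds
    consensus_min: float = 0.5  # bootstrap support fraction to keep an edge
    # master regulator analysis
    mra_fdr_max: float = 0.05
    promoter_upstream: int = 2000   # bp upstream of the TSS, strand-aware
    promoter_downstream: int = 500  # bp downstream of the TSS
    # motif scanning
    background_gc: float = 0.5  # uniform background by default
    pseudocount: float = 1.0
    rel_min: float = 0.8        # relative log-odds score threshold for hits
    merge_gap: int = 50         # bp start-to-start gap for cluster merging
    # qPCR
    reference_gene: str = "GAPDH"
    control_group: str = "C"
    input_fraction: float = 0.01
    # conservation
    distal_cutoff: int = 500_000  # bp beyond which a homolog is 'distal'
    # reproducibility
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
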