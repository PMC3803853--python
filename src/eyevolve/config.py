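"""Pipeline-wide thresholds and their YAML round-trip.

Every threshold a downstream stage consults lives here, so a run is fully
described by one config plus one seed.  The defaults encode the study's
filtering rules: contigs longer than 100 bp, normalized coverage of 10 or
more, more-than-two-fold expression difference, annotation transfer at
e-value 1e-10, contig similarity below 95% for duplication calls, and
FDR < 0.05 for enrichment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # length / expression filters
    min_contig_len: int = 100          # nt; contigs must be longer than this
    min_coverage: float = 10.0         # normalized average coverage, inclusive
    fold_change: float = 2.0           # strict: must exceed this ratio
    # homology search
    search_evalue: float = 1e-3        # reporting cutoff for the hit table
    annotation_evalue: float = 1e-10   # GO annotation transfer cutoff
    search_engine: str = "blastx"      # "blastx" (NCBI CLI) or "native"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267           # gapped BLOSUM62 Karlin-Altschul lambda
    ka_k: float = 0.041
    # event detection
    duplication_identity_max: float = 0.95
    same_region_min_overlap: float = 0.4   # fraction of the shorter interval
    conservation_max_identity: float = 0.60
    # enrichment
    fdr_alpha: float = 0.05
    fisher_two_tailed: bool = False
    # eye QC: require the whole-proteome best hit to be eye-related (False)
    # or to be the identical protein found in the eye-subset search (True)
    qc_strict: bool = False
    kimura: bool = True
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.min_contig_len <= 0 or self.min_coverage <= 0 or self.fold_change <= 0:
            raise ValueError("filter thresholds must be positive")
        for name in ("duplication_identity_max", "same_region_min_overlap",
                     "conservation_max_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.fdr_alpha <= 1.0:
            raise ValueError("fdr_alpha must be in (0, 1]")
        if self.gap_open < self.gap_extend or self.gap_extend < 1:
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.search_engine not in ("blastx", "native"):
            raise ValueError(f"unknown search engine {self.search_engine!r}")
        return self

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data).validate()
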