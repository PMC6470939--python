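"""Run configuration: every tunable of every stage, serializable to and
from a single YAML file and echoed into the run manifest."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .readproc import DEFAULT_ADAPTER

__all__ = ["RunConfig", "Paths"]


@dataclass
class Paths:
    reads: dict[str, str] = field(default_factory=dict)  # library_id -> FASTQ/FASTA
    contaminants: Optional[str] = None
    refs_mature: Optional[str] = None
    refs_hairpin: Optional[str] = None
    monocot_mature: Optional[str] = None
    monocot_hairpin: Optional[str] = None
    genome: Optional[str] = None
    transcripts: Optional[str] = None
    degradome: Optional[str] = None          # per-position count TSV
    gene_annotations: Optional[str] = None   # TSV: gene <tab> description
    gene_map: Optional[str] = None           # TSV: transcript <tab> gene


@dataclass
class RunConfig:
    paths: Paths = field(default_factory=Paths)
    library_ids: list[str] = field(default_factory=lambda: ["C0", "C1", "Cd1"])
    comparison: tuple[str, str] = ("C1", "Cd1")   # the Cd contrast
    rng_seed: int = 0

    # read processing
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    length_range: tuple[int, int] = (18, 30)

    # annotation
    annotate_length_range: tuple[int, int] = (20, 22)
    max_shift: int = 2
    max_subs: int = 1
    flank: int = 120
    max_mfe: float = -18.0
    min_mfei: float = 0.85
    max_duplex_unpaired: int = 4
    max_asym_bulge: int = 2
    hc_min_reads: float = 10
    hc_min_libraries: int = 2

    # differential expression
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 0.5
    norm_scale: float = 1e6
    de_method: str = "auto"

    # target prediction
    cutoff_a: float = 5.0
    max_gaps: int = 2
    cutoff_b: float = 2.5
    min_site_overlap: float = 0.5
    targets_from: str = "all"  # "all" | "significant" | "high_confidence"
    compute_upe: bool = True

    # degradome
    category_max: int = 2
    pos_tolerance: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparison"] = list(self.comparison)
        d["length_range"] = list(self.length_range)
        d["annotate_length_range"] = list(self.annotate_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        paths = Paths(**d.pop("paths", {}))
        for key in ("comparison", "length_range", "annotate_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(paths=paths, **d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
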