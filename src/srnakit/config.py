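"""Pipeline configuration: every fixed constant of the annotation pipeline.

Defaults follow the published protocol for each stage: 5-nt minimum adapter
match, pool size windows 18-22 / 28-32 / 35-42 nt, one mapping mismatch,
±50 bp folding and motif windows, 75% paired stem bases, 1000 bp gene
flanks, 15-nt reference seed with 95% mature identity, 100 composition-
preserving shuffles, a 5-distinct-3-mer complexity gate and a 1/3
mirror-match share threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Mapping

import yaml

POOLS = ("mirna", "pirna", "crasirna")


def _default_size_ranges() -> dict[str, tuple[int, int]]:
    return {"mirna": (18, 22), "pirna": (28, 32), "crasirna": (35, 42)}


@dataclass
class PipelineConfig:
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str | None = None
    min_adapter_match: int = 5
    size_ranges: dict[str, tuple[int, int]] = field(default_factory=_default_size_ranges)
    max_mismatches: int = 1
    hairpin_flank: int = 50
    min_stem_paired_frac: float = 0.75
    min_loop: int = 3
    gene_flank: int = 1000
    ref_min_seed: int = 15
    ref_min_identity: float = 0.95
    motif_flank: int = 50
    motif_min_distinct_3mers: int = 5
    motif_n_shuffles: int = 100
    motif_share_threshold: float = 1.0 / 3.0
    rng_seed: int = 17
    peak_min_reads: int = 2
    peak_max_gap: int = 0
    loop_overhang: int = 0
    index_k: int = 9
    no_lonely_pairs: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "min_adapter_match", "max_mismatches", "hairpin_flank", "min_loop",
            "gene_flank", "ref_min_seed", "motif_flank", "motif_min_distinct_3mers",
            "motif_n_shuffles", "peak_min_reads", "peak_max_gap", "loop_overhang",
            "index_k",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        for name in ("min_stem_paired_frac", "ref_min_identity", "motif_share_threshold"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {value!r}")
        if self.adapter3 and len(self.adapter3) < self.min_adapter_match:
            raise ValueError("adapter3 shorter than min_adapter_match")
        normalized = {}
        for pool, rng in self.size_ranges.items():
            lo, hi = rng
            if lo < 1 or hi < lo:
                raise ValueError(f"empty size range {rng!r} for pool {pool!r}")
            normalized[pool] = (int(lo), int(hi))
        self.size_ranges = normalized

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_ranges"] = {k: list(v) for k, v in self.size_ranges.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "size_ranges" in kwargs:
            kwargs["size_ranges"] = {
                k: tuple(v) for k, v in kwargs["size_ranges"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
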