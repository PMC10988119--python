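"""Run configuration: every analysis threshold in one structured file.

Defaults are the thresholds of the source study, so a bare run applies the
published rules: CPM fold changes with a pseudocount of 1, DE filter
(>=15 total reads, FDR <= 0.05, |log2FC| >= 1), transcript synergy at an
observed/additive ratio >= 2, protein synergy at combined FC > 1.5x the
added single FCs with nominal p < 0.05, demultiplexing at >=5 tags with the
second tag < 25% of the top, cell filter (>=20 genes, >=400 reads), gene
filter (> 21 cells), 10k/log normalization, and a 20% display fraction.
Configs round-trip through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class BulkParams:
    pseudocount: float = 1.0
    min_total_reads: int = 15
    max_fdr: float = 0.05
    min_abs_log2fc: float = 1.0
    ratio_threshold: float = 2.0
    include_repressed: bool = False

    def validate(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.min_total_reads < 0:
            raise ValidationError("min_total_reads must be >= 0")
        if not 0 <= self.max_fdr <= 1:
            raise ValidationError("max_fdr must be in [0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if self.ratio_threshold <= 0:
            raise ValidationError("ratio_threshold must be > 0")


@dataclass
class NPXParams:
    synergy_factor: float = 1.5
    max_p: float = 0.05
    paired_test: bool = True

    def validate(self) -> None:
        if self.synergy_factor <= 0:
            raise ValidationError("synergy_factor must be > 0")
        if not 0 < self.max_p <= 1:
            raise ValidationError("max_p must be in (0, 1]")


@dataclass
class ScrnaParams:
    min_tags: int = 5
    second_fraction: float = 0.25
    min_genes: int = 20
    min_reads: int = 400
    min_cells_strict: int = 21
    target_sum: float = 10000.0
    n_pcs: int = 20
    n_neighbors: int = 15
    resolution: float = 1.0
    cluster_method: str = "louvain"
    marker_fraction: float = 0.5
    display_fraction: float = 0.20
    mesothelial_type: str = "mesothelial"

    def validate(self) -> None:
        if self.min_tags < 1:
            raise ValidationError("min_tags must be >= 1")
        if not 0 < self.second_fraction <= 1:
            raise ValidationError("second_fraction must be in (0, 1]")
        if self.min_genes < 1 or self.min_reads < 1:
            raise ValidationError("min_genes and min_reads must be >= 1")
        if self.min_cells_strict < 0:
            raise ValidationError("min_cells_strict must be >= 0")
        if self.target_sum <= 0:
            raise ValidationError("target_sum must be > 0")
        if self.n_pcs < 1 or self.n_neighbors < 1:
            raise ValidationError("n_pcs and n_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValidationError("resolution must be > 0")
        if self.cluster_method not in {"louvain", "leiden"}:
            raise ValidationError("cluster_method must be 'louvain' or 'leiden'")
        if not 0 < self.marker_fraction <= 1:
            raise ValidationError("marker_fraction must be in (0, 1]")
        if not 0 <= self.display_fraction <= 1:
            raise ValidationError("display_fraction must be in [0, 1]")


@dataclass
class RunConfig:
    bulk: BulkParams = field(default_factory=BulkParams)
    npx: NPXParams = field(default_factory=NPXParams)
    scrna: ScrnaParams = field(default_factory=ScrnaParams)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.bulk.validate()
        self.npx.validate()
        self.scrna.validate()
        if not 0 <= int(self.seed) < 2**31:
            raise ValidationError("seed must be in [0, 2**31)")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {"bulk": BulkParams, "npx": NPXParams, "scrna": ScrnaParams}
        kwargs: dict = {}
        for section, klass in known.items():
            payload = dict(data.pop(section, {}) or {})
            unknown = set(payload) - {f.name for f in dataclasses.fields(klass)}
            if unknown:
                raise ValidationError(f"unknown {section} option(s): {sorted(unknown)}")
            kwargs[section] = klass(**payload)
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ValidationError(f"unknown config section(s): {sorted(data)}")
        return cls(**kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
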