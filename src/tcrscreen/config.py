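"""Run configuration: YAML/JSON loading with embedded defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .qc import QcThresholds
from .scoring import ModuleScoreParams


@dataclass
class RunConfig:
    matrix_dir: str | None = None
    contig_csv: str | None = None
    out_dir: str = "tcrscreen-out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    score: ModuleScoreParams = field(default_factory=ModuleScoreParams)
    min_cells: int = 3
    k: int = 3
    clonotype_key: str = "cdr3nt_vj"
    signature: str = "default"  # or a path to a one-symbol-per-line file
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        return hashlib.sha1(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"]["cd3_genes"] = list(d["qc"]["cd3_genes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "qc" in d:
            q = dict(d["qc"])
            if "cd3_genes" in q:
                q["cd3_genes"] = tuple(q["cd3_genes"])
            d["qc"] = QcThresholds(**q)
        if "score" in d:
            d["score"] = ModuleScoreParams(**d["score"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (JSON is a YAML subset and is accepted too)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_signature(spec: str) -> tuple[str, ...]:
    """Resolve a signature spec: "default" or a path to a gene list."""
    from .scoring import DEFAULT_SIGNATURE

    if spec == "default":
        return tuple(DEFAULT_SIGNATURE)
    lines = Path(spec).read_text().splitlines()
    genes = tuple(g.strip() for g in lines if g.strip() and not g.startswith("#"))
    if not genes:
        raise ValueError(f"signature file {spec} contains no genes")
    return genes
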