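"""Run configuration: every tunable of the pipeline with its default."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    # graph clustering
    k: int = 20
    prune: float = 1.0 / 15.0
    resolution: float = 1.0
    n_restarts: int = 5
    min_recluster_cells: int = 10
    # preprocessing
    n_hvg: int = 2000
    span: float = 0.3
    n_pcs: int = 50
    clip: float = 10.0
    scale_to: float = 10_000.0
    # quality control
    qc: bool = True
    mito_prefix: str = "MT-"
    max_mito_frac: float = 0.20
    min_umi: int = 500
    min_genes: int = 200
    max_genes: int = 6000
    # annotation
    r_first: float = 0.6
    r_deep: float = 0.3
    alpha: float = 0.05
    expressed_quantile: float = 0.75
    weight_scope: str = "leaves"
    min_shared_markers: int = 10
    # reproducibility
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)

    def header_lines(self) -> list[str]:
        """Config echo written atop every output table; enough to re-run."""
        return [f"# {f.name}={getattr(self, f.name)}" for f in fields(self)]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
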