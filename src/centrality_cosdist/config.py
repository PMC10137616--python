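"""Run configuration: every knob of the pipeline with a documented default.

Serialises to/from YAML; unknown keys are rejected so a typo in a config
file fails loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # feature space
    weighted: bool = False              # use edge weights where measures define them
    dedupe_eigenvector: bool = False    # drop the duplicated eigenvector column (8-dim)
    zscore: bool = False                # z-score columns before cosine
    # seed pruning (optional step)
    prune_seeds: bool = False
    tau: float | None = None            # None = mean off-diag seed sim − 2 sd
    # reporting
    top_k: int = 10
    # baselines
    rwr_restart: float = 0.5
    rwr_tolerance: float = 1e-10
    rwr_max_iterations: int = 10_000
    diamond_n_added: int = 100
    # importance analysis
    cluster_method: str = "kmeans"      # kmeans | dbscan
    kmeans_k: int = 4
    dbscan_eps: float | None = None     # None = knee heuristic
    dbscan_min_samples: int = 5
    rf_trees: int = 500
    perm_repeats: int = 10
    random_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def as_dict(self) -> dict:
        return asdict(self)
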