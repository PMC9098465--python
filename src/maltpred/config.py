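"""Structured run configuration (YAML) for the end-to-end analysis."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings of one analysis run.

    Unknown keys in a YAML file are rejected; every run writes its fully
    resolved configuration next to its outputs (see ``cli``).
    """

    # paths
    spectra_path: str = "spectra.tsv"
    phenotype_path: str = "phenotypes.tsv"
    output_dir: str = "results"
    # preprocessing
    excluded_regions: list = field(
        default_factory=lambda: [[-1e30, 0.70], [4.7, 4.9], [-0.2, 0.2], [9.00, 1e30]]
    )
    interval_length: int = 200
    max_shift: int = 3
    # MBLUP
    reml_bounds: list = field(default_factory=lambda: [1e-6, 1.0 - 1e-6])
    reml_tol: float = 1e-8
    refit_per_fold: bool = True
    # PLSR
    component_grid: list = field(default_factory=lambda: [5, 10, 20, 50])
    n_components: int = 20
    plsr_mode: str = "fixed"  # "fixed" | "loo"
    # cross-validation
    strategies: list = field(default_factory=lambda: ["SIZE", "LINE", "LOC"])
    tp_sizes: list = field(default_factory=lambda: [50, 100, 200, 400])
    replicates: int = 15
    traits: list = field(default_factory=lambda: ["FS", "EY", "WC", "BG", "WV"])
    # misc
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown configuration key(s): {unknown}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8"
        )

    def as_dict(self) -> dict:
        return asdict(self)
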