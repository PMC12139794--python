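"""Run configuration: every tunable of the pipeline with its default.

Defaults reproduce the published workflow parameters, so a bare run on
real inputs follows the reference protocol; any value can be overridden
from a flat YAML config file or command-line flags (flags win).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .model import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables.

    Distances in Angstrom, temperature in K, density in A^-3.
    """

    #: first-hydration-shell cutoff for grid accumulation and WT site finding
    shell_predict: float = 3.25
    #: shell for pooling experimental waters around the reference protomer
    shell_aggregate: float = 4.0
    #: coarse grid voxel edge
    coarse_voxel: float = 0.1
    #: sliding-window size in coarse voxels (window * coarse_voxel = 1 A cube)
    window: int = 10
    #: minimum center-to-center separation between accepted cubes
    min_separation: float = 2.25
    #: minimum cube-center distance from any solute atom
    min_solute_dist: float = 2.25
    #: fine grid voxel edge for WT estimation
    fine_voxel: float = 0.005
    #: half edge of the fine cube around each reference position
    half_extent: float = 0.5
    #: densest fraction of fine voxels entering the Boltzmann average
    top_fraction: float = 0.01
    #: single-linkage connection distance for consensus clustering (strict <)
    link_cutoff: float = 1.0
    #: first-shell cutoff applied to cluster mean positions
    first_shell: float = 3.25
    #: distinct-structure count at/above which a cluster is high-consensus
    high_threshold: int = 5
    #: one-to-one predicted/experimental match cutoff
    match_cutoff: float = 2.2
    #: simulation temperature
    temperature: float = 300.0
    #: bulk water number density
    rho_bulk: float = 0.033
    #: keep every stride-th trajectory frame
    stride: int = 1
    #: maximum number of predicted sites (None = until counts reach zero)
    max_sites: int | None = 200
    #: seed for any stochastic step
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if f.name in ("seed",):
                continue
            if isinstance(v, (int, float)) and v <= 0:
                raise ValidationError(f"config field {f.name} must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML config, then apply *overrides*
        (only non-None override values are applied)."""
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
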