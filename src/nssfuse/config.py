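"""Fusion configuration.

All tunables of the fusion pipeline in one dataclass.  Defaults follow the
reference operating point: 4 pyramid levels with 4, 8, 8, 16 directions
(coarsest to finest), 8x8 patches, PCA energy fraction delta = 0.95 and
SML step 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["FusionConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass
class FusionConfig:
    #: number of pyramid scales
    levels: int = 4
    #: directional bands per scale, coarsest to finest; each a power of two
    directions: tuple[int, ...] = (4, 8, 8, 16)
    #: pyramid filter family ("9-7" or "maxflat")
    pyramid_filter: str = "9-7"
    #: fan filter family ("pkva" or "dmaxflat")
    fan_filter: str = "pkva"
    #: side of the square patches taken from the low-pass band (pixels)
    patch_size: int = 8
    #: sliding-window step (pixels); 1 gives maximal overlap
    stride: int = 1
    #: SOMP residual-norm target; None means 0.01 * patch_size
    eps: float | None = None
    #: hard cap on atoms per sparse code (guarantees termination)
    max_atoms: int = 16
    #: number of joint patch clusters for dictionary learning
    n_clusters: int = 8
    #: retained eigenvalue mass fraction per sub-dictionary
    delta: float = 0.95
    #: patches used to train the clustering (seeded subsample); coding
    #: always visits every patch
    max_train_patches: int = 20000
    #: SML window half-sizes: window is (2p+1) x (2q+1)
    sml_p: int = 1
    sml_q: int = 1
    #: spacing of the modified-Laplacian second differences
    sml_step: int = 1
    #: square the ML terms inside the SML window (the reference definition)
    sml_squared: bool = True
    #: boundary handling of the pipeline: "symmetric" pads the inputs by
    #: ``boundary_pad`` before the transform and crops afterwards;
    #: "periodic" uses the transform's native circular extension
    boundary: str = "symmetric"
    boundary_pad: int = 32
    #: seed for every stochastic step (clustering init, training subsample)
    seed: int = 0
    #: colour handling: "luma" fuses luminance and switches chroma,
    #: "per_channel" fuses each channel independently
    color_mode: str = "luma"

    @property
    def resolved_eps(self) -> float:
        """SOMP stopping tolerance: 0.01 * sqrt(n) for n-pixel patches."""
        if self.eps is not None:
            return float(self.eps)
        return 0.01 * self.patch_size

    def validate(self) -> "FusionConfig":
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        dirs = tuple(int(d) for d in self.directions)
        if len(dirs) != self.levels:
            raise ConfigError("directions must have one entry per level")
        for d in dirs:
            if d < 1 or (d & (d - 1)) != 0:
                raise ConfigError(f"direction count {d} is not a power of two")
        if self.patch_size < 1 or self.stride < 1:
            raise ConfigError("patch_size and stride must be positive")
        if not (0.0 < self.delta <= 1.0):
            raise ConfigError("delta must lie in (0, 1]")
        if self.max_atoms < 1:
            raise ConfigError("max_atoms must be >= 1")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if min(self.sml_p, self.sml_q) < 0 or self.sml_step < 1:
            raise ConfigError("invalid SML window/step")
        if self.boundary not in ("symmetric", "periodic"):
            raise ConfigError("boundary must be 'symmetric' or 'periodic'")
        if self.color_mode not in ("luma", "per_channel"):
            raise ConfigError("color_mode must be 'luma' or 'per_channel'")
        object.__setattr__(self, "directions", dirs)
        return self

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def load_config(path: str, **overrides) -> FusionConfig:
    """Load a flat YAML mapping into a :class:`FusionConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(FusionConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    data.update(overrides)
    if "directions" in data and data["directions"] is not None:
        dirs = data["directions"]
        if isinstance(dirs, str):
            dirs = [int(s) for s in dirs.replace(",", " ").split()]
        data["directions"] = tuple(int(d) for d in dirs)
    return FusionConfig(**data).validate()
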