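"""Configuration for the synthetic seasonal-study generator.

Defaults mirror the field study the package emulates: 11 dry-season and 9
wet-season adult female frogs, an ant-dominated dry diet versus a diverse
wet diet, and a 41-feature skin-alkaloid panel in which a small subset of
alkaloids shifts in abundance between seasons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


def _simplex5(values, what: str) -> tuple[float, ...]:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (5,):
        raise ConfigError(f"{what} must have 5 entries (ants, mites, larvae, termites, other)")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ConfigError(f"{what} entries must be finite and non-negative")
    if arr.sum() <= 0:
        raise ConfigError(f"{what} must have a positive sum")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{what} must sum to 1 (got {arr.sum()!r})")
    return tuple(float(v) for v in arr)


def _normalized(values) -> tuple[float, ...]:
    arr = np.asarray(values, dtype=float)
    return tuple(float(v) for v in arr / arr.sum())


# Default category means follow the observed seasonal compositions by counts,
# dry ~ (85.1, 3.4, 0, 3.4, 8.1)% and wet ~ (35.5, 10.8, 12.5, 0.8, 40.3)%,
# renormalised so each vector sums to exactly 1.
DRY_CATEGORY_MEANS = _normalized((85.1, 3.4, 0.0, 3.4, 8.1))
WET_CATEGORY_MEANS = _normalized((35.5, 10.8, 12.5, 0.8, 40.3))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study; the seed is mandatory.

    Diet: per-frog prey counts are negative-binomial (mean
    ``prey_count_mean``, dispersion ``prey_count_dispersion``); category
    mixes are Dirichlet-multinomial around season means with concentration
    ``dirichlet_concentration``; item lengths are log-normal per category on
    the mm scale.  Alkaloids: log-normal intensities, ``n_shifted`` features
    with their wet-season location multiplied by ``fold_change``, and
    independent below-detection zeroing with probability
    ``1 - detection_prob``.
    """

    seed: int
    n_dry: int = 11
    n_wet: int = 9
    category_means_dry: tuple = DRY_CATEGORY_MEANS
    category_means_wet: tuple = WET_CATEGORY_MEANS
    dirichlet_concentration: float = 15.0
    prey_count_mean: float = 40.0
    prey_count_dispersion: float = 5.0
    size_log_mean: tuple = (1.1, -0.7, 1.4, 1.4, 0.9)
    size_log_sd: tuple = (0.3, 0.25, 0.4, 0.3, 0.5)
    mite_sphere_prob: float = 0.9
    n_alkaloids: int = 41
    n_shifted: int = 7
    fold_change: float = 4.0
    abundance_log_mean: float = 10.0
    abundance_log_sd: float = 0.6
    detection_prob: float = 0.95
    skin_mass_mean_g: float = 0.15
    skin_mass_sd_g: float = 0.04

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        for name in ("n_dry", "n_wet", "n_alkaloids"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer")
        if not isinstance(self.n_shifted, (int, np.integer)) or self.n_shifted < 0:
            raise ConfigError("n_shifted must be a non-negative integer")
        if self.n_shifted > self.n_alkaloids:
            raise ConfigError("n_shifted cannot exceed n_alkaloids")
        object.__setattr__(self, "category_means_dry",
                           _simplex5(self.category_means_dry, "category_means_dry"))
        object.__setattr__(self, "category_means_wet",
                           _simplex5(self.category_means_wet, "category_means_wet"))
        for name in ("dirichlet_concentration", "prey_count_mean",
                     "prey_count_dispersion", "fold_change",
                     "skin_mass_mean_g", "skin_mass_sd_g"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.detection_prob <= 1):
            raise ConfigError("detection_prob must lie in (0, 1]")
        if not (0 <= self.mite_sphere_prob <= 1):
            raise ConfigError("mite_sphere_prob must lie in [0, 1]")
        for name in ("size_log_mean", "size_log_sd"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (5,) or not np.isfinite(arr).all():
                raise ConfigError(f"{name} must be a finite 5-vector")
            object.__setattr__(self, name, tuple(float(v) for v in arr))
        if (np.asarray(self.size_log_sd) < 0).any():
            raise ConfigError("size_log_sd entries must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("category_means_dry", "category_means_wet",
                    "size_log_mean", "size_log_sd"):
            d[key] = list(d[key])
        return d


def load_config(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML or JSON file; the seed is required."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    if "seed" not in data:
        raise ConfigError("config must set a seed")
    valid = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticConfig(**data)
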