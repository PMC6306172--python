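"""Alkaloid feature matrices: normalization, prevalence filtering, annotation.

A matrix holds GC/MS model-ion intensities (integrated area under the curve,
unitless) for one alkaloid feature per column and one frog per row, together
with each frog's season label and the skin mass used for extraction.
Normalization divides intensities by skin mass (grams), so abundances are
comparable across frogs of different sizes; absence (below detection) is
encoded as exactly 0 and is preserved by the positive rescaling.

Alkaloids carry Daly-catalogue codes (nominal mass + letter, e.g. "323A")
with a structural class and, where the literature proposes one, an arthropod
origin (ant or mite).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRUCTURAL_CLASSES = (
    "DHQ", "PTX", "aPTX", "hPTX", "3,5-P", "5,8,6-I", "5,8-I", "3,5-I",
    "izidine", "tricyclic", "quinoline", "unclassified",
)
ORIGINS = ("ant", "mite", "unknown")

#: Documented structural class and proposed arthropod origin for alkaloid
#: codes reported in this species.  Decahydroquinolines (DHQ), one tricyclic
#: and one 3,5-disubstituted pyrrolizidine are proposed ant-derived;
#: pumiliotoxins (PTX/aPTX/hPTX) and 5,6,8-trisubstituted indolizidines are
#: proposed mite-derived; the rest have no proposed origin.
DOCUMENTED_ALKALOIDS: dict[str, tuple[str, str]] = {
    "189": ("DHQ", "ant"),
    "193D": ("DHQ", "ant"),
    "195A": ("DHQ", "ant"),
    "195J": ("DHQ", "ant"),
    "209A": ("DHQ", "ant"),
    "211A": ("DHQ", "ant"),
    "211K": ("DHQ", "ant"),
    "219A": ("DHQ", "ant"),
    "237O": ("tricyclic", "ant"),
    "239K": ("3,5-P", "ant"),
    "197G": ("5,8,6-I", "mite"),
    "211L": ("5,8,6-I", "mite"),
    "225K": ("5,8,6-I", "mite"),
    "239W": ("5,8,6-I", "mite"),
    "267W": ("5,8,6-I", "mite"),
    "253F": ("PTX", "mite"),
    "275E": ("5,8,6-I", "mite"),
    "291E": ("PTX", "mite"),
    "305A": ("aPTX", "mite"),
    "307A": ("PTX", "mite"),
    "307G": ("PTX", "mite"),
    "321B": ("hPTX", "mite"),
    "321D": ("hPTX", "mite"),
    "323A": ("PTX", "mite"),
    "337B": ("hPTX", "mite"),
    "153B": ("unclassified", "unknown"),
    "225D": ("5,8-I", "unknown"),
    "233B": ("izidine", "unknown"),
    "237E": ("3,5-I", "unknown"),
    "380": ("quinoline", "unknown"),
}

#: code -> proposed origin, for :func:`annotate_origin`.
DOCUMENTED_ORIGINS: dict[str, str] = {c: o for c, (_, o) in DOCUMENTED_ALKALOIDS.items()}


@dataclass(frozen=True)
class AlkaloidFeature:
    """One alkaloid feature: Daly code, structural class, proposed origin."""

    code: str
    structural_class: str = "unclassified"
    proposed_origin: str = "unknown"

    def __post_init__(self) -> None:
        if self.structural_class not in STRUCTURAL_CLASSES:
            raise ValueError(f"unknown structural class {self.structural_class!r}")
        if self.proposed_origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.proposed_origin!r}")


@dataclass
class AlkaloidMatrix:
    """Frogs x alkaloid-features abundance matrix with sample metadata.

    ``samples`` has columns frog_id, season, skin_mass_g (one row per frog,
    aligned with the rows of ``abundance``); ``abundance`` is indexed by
    frog_id with one column per feature code.  ``normalized`` records
    whether intensities have already been divided by skin mass.
    """

    samples: pd.DataFrame
    features: list[AlkaloidFeature]
    abundance: pd.DataFrame
    normalized: bool = False
    internal_standard_ug: float = 25.0

    def __post_init__(self) -> None:
        codes = [f.code for f in self.features]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate feature codes")
        if list(self.abundance.columns) != codes:
            raise ValueError("abundance columns do not match feature codes")
        if list(self.abundance.index) != list(self.samples["frog_id"]):
            raise ValueError("abundance rows do not match sample frog_ids")
        arr = self.abundance.to_numpy(float)
        if np.isnan(arr).any():
            raise ValueError("missing entries; encode absence as 0")
        if (arr < 0).any():
            raise ValueError("negative abundances")

    @property
    def codes(self) -> list[str]:
        return [f.code for f in self.features]

    @property
    def n_frogs(self) -> int:
        return len(self.samples)


def normalize_abundance(
    raw_intensity: float,
    skin_mass_g: float,
    standard_intensity: float | None = None,
    batch_median_standard: float | None = None,
) -> float:
    """Normalize one intensity to skin mass (per gram).

    If a per-sample internal-standard intensity and the batch median are
    supplied, the raw value is first divided by the sample's standard ratio
    (standard / batch median) — an optional recovery correction, off by
    default.
    """
    if not (skin_mass_g > 0):
        raise ValueError(f"skin mass must be positive, got {skin_mass_g}")
    if raw_intensity < 0:
        raise ValueError("negative intensity")
    value = float(raw_intensity)
    if standard_intensity is not None:
        if batch_median_standard is None or not (batch_median_standard > 0):
            raise ValueError("batch median standard intensity required and positive")
        if not (standard_intensity > 0):
            raise ValueError("standard intensity must be positive")
        value /= standard_intensity / batch_median_standard
    return value / skin_mass_g


def normalize_matrix(
    matrix: AlkaloidMatrix, standard_intensities: np.ndarray | None = None
) -> AlkaloidMatrix:
    """Return a mass-normalized copy of the matrix (per gram of skin)."""
    if matrix.normalized:
        warnings.warn("matrix already normalized; normalizing again", stacklevel=2)
    mass = matrix.samples["skin_mass_g"].to_numpy(float)
    if (mass <= 0).any():
        raise ValueError("non-positive skin mass")
    values = matrix.abundance.to_numpy(float)
    if standard_intensities is not None:
        std = np.asarray(standard_intensities, float)
        if std.shape != (len(mass),) or (std <= 0).any():
            raise ValueError("standard intensities must be positive, one per frog")
        values = values / (std / np.median(std))[:, None]
    abundance = pd.DataFrame(values / mass[:, None],
                             index=matrix.abundance.index, columns=matrix.codes)
    return AlkaloidMatrix(
        samples=matrix.samples.copy(),
        features=list(matrix.features),
        abundance=abundance,
        normalized=True,
        internal_standard_ug=matrix.internal_standard_ug,
    )


def prevalence_filter(
    matrix: AlkaloidMatrix, min_fraction: float = 0.5, floor: float = 0.0
) -> AlkaloidMatrix:
    """Retain features present (abundance > floor) in at least ``min_fraction`` of frogs.

    "At least half" with n frogs means >= ceil(n/2) frogs, inclusive at the
    boundary (10 of 20 is retained).  Feature order is preserved; the filter
    is idempotent and monotone in ``min_fraction``.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = matrix.n_frogs
    threshold = math.ceil(min_fraction * n - 1e-9)
    present = (matrix.abundance.to_numpy(float) > floor).sum(axis=0)
    keep = present >= threshold
    kept_features = [f for f, k in zip(matrix.features, keep) if k]
    logger.info("prevalence filter: %d of %d features retained (>= %d of %d frogs)",
                len(kept_features), len(matrix.features), threshold, n)
    boundary = int((present == threshold).sum())
    if boundary:
        logger.info("%d features sit exactly at the prevalence boundary", boundary)
    return AlkaloidMatrix(
        samples=matrix.samples.copy(),
        features=kept_features,
        abundance=matrix.abundance.loc[:, [f.code for f in kept_features]].copy(),
        normalized=matrix.normalized,
        internal_standard_ug=matrix.internal_standard_ug,
    )


def annotate_origin(
    matrix: AlkaloidMatrix, origin_table: dict[str, str] | None = None
) -> AlkaloidMatrix:
    """Attach proposed arthropod origins to features (unknown when absent)."""
    table = DOCUMENTED_ORIGINS if origin_table is None else origin_table
    features = [replace(f, proposed_origin=table.get(f.code, "unknown"))
                for f in matrix.features]
    return AlkaloidMatrix(
        samples=matrix.samples.copy(),
        features=features,
        abundance=matrix.abundance.copy(),
        normalized=matrix.normalized,
        internal_standard_ug=matrix.internal_standard_ug,
    )


def write_alkaloid_csv(matrix: AlkaloidMatrix, path) -> None:
    """Write the wide-format alkaloid CSV (frog_id, season, skin_mass_g, codes...)."""
    wide = matrix.samples.copy()
    wide = pd.concat([wide.reset_index(drop=True),
                      matrix.abundance.reset_index(drop=True)], axis=1)
    wide.to_csv(path, index=False)


def read_alkaloid_csv(path, normalized: bool = False) -> AlkaloidMatrix:
    """Read the wide-format alkaloid CSV written by :func:`write_alkaloid_csv`.

    Also accepts any spreadsheet export with frog_id, season, skin_mass_g
    followed by one column per alkaloid code.  Structural classes and
    origins are filled from the documented catalogue where the code is known.
    """
    df = pd.read_csv(path, dtype={"frog_id": str})
    meta_cols = ["frog_id", "season", "skin_mass_g"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f"alkaloid CSV missing columns: {sorted(missing)}")
    codes = [c for c in df.columns if c not in meta_cols]
    features = []
    for code in codes:
        cls, origin = DOCUMENTED_ALKALOIDS.get(code, ("unclassified", "unknown"))
        features.append(AlkaloidFeature(code, cls, origin))
    abundance = df[codes].astype(float)
    abundance.index = df["frog_id"]
    return AlkaloidMatrix(
        samples=df[meta_cols].copy(),
        features=features,
        abundance=abundance,
        normalized=normalized,
    )
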