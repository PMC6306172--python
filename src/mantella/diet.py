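"""Prey morphometrics and per-frog diet composition.

Stomach-content items are grouped into five prey categories (ants, mites,
insect larvae, termites, other) and quantified two ways per frog: percent
number (share of item counts) and percent volume (share of estimated prey
volumes).  Elongate prey are modelled as prolate spheroids,
``V = (4*pi/3) * (L/2) * (W/2)**2`` with length ``L`` measured from the
foremost to the rearmost point and width ``W`` at the midpoint; round mites
are modelled as spheres with the measured width taken as the diameter,
``V = (4*pi/3) * (W/2)**3``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed category order used by every composition vector in the package.
CATEGORIES = ("ants", "mites", "larvae", "termites", "other")

SHAPES = ("prolate", "sphere")

# Arachnid orders counted as mites (Acari); spiders (Araneae) are arachnids
# but not Acari and fall into "other".
ACARI_ORDERS = frozenset(
    {"acari", "sarcoptiformes", "mesostigmata", "trombidiformes",
     "oribatida", "ixodida"}
)
TERMITE_LABELS = frozenset({"isoptera", "termitoidae", "termite"})
# Hexapod orders whose larvae go to the "larvae" category.
INSECT_ORDERS = frozenset(
    {"diptera", "lepidoptera", "coleoptera", "hymenoptera", "hemiptera",
     "orthoptera", "blattodea", "isoptera", "psocoptera", "neuroptera",
     "trichoptera", "collembola", "thysanoptera", "dermaptera"}
)


def prey_volume(length_mm: float, width_mm: float, shape: str = "prolate") -> float:
    """Volume of one prey item in mm^3 from its length/width in mm.

    For ``shape="sphere"`` the width is interpreted as the diameter and the
    length is ignored, so the prolate formula with L == W degenerates to the
    sphere exactly.  A prolate item with W > L is geometrically suspicious
    (an oblate measurement) but is kept and computed as given, with a
    warning.
    """
    if shape not in SHAPES:
        raise ValueError(f"shape must be one of {SHAPES}, got {shape!r}")
    if not (width_mm > 0):
        raise ValueError(f"width_mm must be positive, got {width_mm}")
    if shape == "sphere":
        return (4.0 * math.pi / 3.0) * (width_mm / 2.0) ** 3
    if not (length_mm > 0):
        raise ValueError(f"length_mm must be positive, got {length_mm}")
    if width_mm > length_mm:
        warnings.warn(
            f"prolate item with width ({width_mm}) > length ({length_mm}); kept",
            stacklevel=2,
        )
    return (4.0 * math.pi / 3.0) * (length_mm / 2.0) * (width_mm / 2.0) ** 2


def classify_prey_category(
    order: str | None = None,
    family: str | None = None,
    genus: str | None = None,
    life_stage: str = "adult",
) -> str:
    """Map a taxonomy record plus life stage onto the five diet categories.

    Rules: any insect larva -> "larvae"; adult Formicidae -> "ants";
    Acari -> "mites"; termites -> "termites"; every other adult arthropod
    (spiders, flies, beetles, springtails, wasps, barkflies, ...) -> "other".
    A record with no usable taxonomy is logged and assigned "other".
    """
    o = (order or "").strip().lower()
    f = (family or "").strip().lower()
    if not o and not f and not (genus or "").strip():
        logger.warning("prey item with no taxonomy; assigned category 'other'")
        return "other"
    if life_stage == "larva" and o in INSECT_ORDERS:
        return "larvae"
    if f == "formicidae":
        return "ants"
    if o in TERMITE_LABELS or f == "termitidae":
        return "termites"
    if o in ACARI_ORDERS:
        return "mites"
    return "other"


@dataclass
class PreyItem:
    """One arthropod recovered from a stomach, with derived volume."""

    item_id: str
    frog_id: str
    category: str
    length_mm: float
    width_mm: float
    shape: str = "prolate"
    volume_mm3: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.volume_mm3 is None:
            self.volume_mm3 = prey_volume(self.length_mm, self.width_mm, self.shape)


@dataclass
class FrogRecord:
    """A voucher frog with its season label and stomach contents."""

    frog_id: str
    season: str
    mass_g: float | None = None
    prey: list = field(default_factory=list)


@dataclass
class DietComposition:
    """Per-frog diet composition over the five categories (percent scale)."""

    frog_id: str
    percent_number: np.ndarray
    percent_volume: np.ndarray
    total_number: int
    total_volume_mm3: float


def frog_composition(frog: FrogRecord) -> DietComposition | None:
    """Percent-number and percent-volume vectors for one frog.

    An empty stomach leaves both vectors undefined; the frog is logged and
    ``None`` is returned so callers can exclude it from group statistics.
    """
    if not frog.prey:
        logger.warning("frog %s has an empty stomach; composition undefined", frog.frog_id)
        return None
    counts = np.zeros(len(CATEGORIES))
    vols = np.zeros(len(CATEGORIES))
    for item in frog.prey:
        idx = CATEGORIES.index(item.category)
        counts[idx] += 1
        vols[idx] += item.volume_mm3
    total_n = int(counts.sum())
    total_v = float(vols.sum())
    return DietComposition(
        frog_id=frog.frog_id,
        percent_number=100.0 * counts / counts.sum(),
        percent_volume=100.0 * vols / vols.sum(),
        total_number=total_n,
        total_volume_mm3=total_v,
    )


def add_volumes(items: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a prey-item table with a ``volume_mm3`` column."""
    out = items.copy()
    length = out["length_mm"].to_numpy(float)
    width = out["width_mm"].to_numpy(float)
    if (width <= 0).any() or (length <= 0).any():
        raise ValueError("non-positive prey dimensions")
    sphere = out["shape"].to_numpy() == "sphere"
    vol = (4.0 * math.pi / 3.0) * (length / 2.0) * (width / 2.0) ** 2
    vol[sphere] = (4.0 * math.pi / 3.0) * (width[sphere] / 2.0) ** 3
    n_oblate = int(((width > length) & ~sphere).sum())
    if n_oblate:
        logger.info("%d prolate items measured wider than long (kept)", n_oblate)
    out["volume_mm3"] = vol
    return out


def compositions_table(items: pd.DataFrame) -> pd.DataFrame:
    """Per-frog composition table from a prey-item table.

    Expects columns frog_id, season, category, length_mm, width_mm, shape
    (``volume_mm3`` is derived if absent).  Returns one row per frog with
    ``num_pct_<cat>`` and ``vol_pct_<cat>`` columns; frogs with empty
    stomachs simply do not appear (they contribute no rows to the input).
    """
    if items.empty:
        raise ValueError("empty prey-item table")
    if "volume_mm3" not in items.columns:
        items = add_volumes(items)
    bad = set(items["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown prey categories: {sorted(bad)}")
    rows = []
    for (frog_id, season), grp in items.groupby(["frog_id", "season"], sort=True):
        counts = grp.groupby("category").size().reindex(CATEGORIES, fill_value=0).to_numpy(float)
        vols = grp.groupby("category")["volume_mm3"].sum().reindex(CATEGORIES, fill_value=0.0).to_numpy(float)
        row = {
            "frog_id": frog_id,
            "season": season,
            "total_number": int(counts.sum()),
            "total_volume_mm3": float(vols.sum()),
        }
        for i, cat in enumerate(CATEGORIES):
            row[f"num_pct_{cat}"] = 100.0 * counts[i] / counts.sum()
            row[f"vol_pct_{cat}"] = 100.0 * vols[i] / vols.sum()
        rows.append(row)
    return pd.DataFrame(rows)


def group_diet_table(items: pd.DataFrame) -> pd.DataFrame:
    """Season-level diet summary in both pooling conventions.

    For each season and measure (number, volume) two summaries are reported:
    ``pooled`` (sum counts/volumes over all frogs, then take percentages) and
    ``frog_mean`` (mean of per-frog percentage vectors).  The two differ
    whenever frogs contribute unequal item counts, so both are labelled
    explicitly.  Returns a tidy frame with columns season, convention,
    measure, category, percent.
    """
    comps = compositions_table(items)
    if "volume_mm3" not in items.columns:
        items = add_volumes(items)
    out = []
    for season, grp in items.groupby("season", sort=True):
        counts = grp.groupby("category").size().reindex(CATEGORIES, fill_value=0).to_numpy(float)
        vols = grp.groupby("category")["volume_mm3"].sum().reindex(CATEGORIES, fill_value=0.0).to_numpy(float)
        season_comps = comps[comps["season"] == season]
        for measure, pooled, cols in (
            ("number", 100.0 * counts / counts.sum(), [f"num_pct_{c}" for c in CATEGORIES]),
            ("volume", 100.0 * vols / vols.sum(), [f"vol_pct_{c}" for c in CATEGORIES]),
        ):
            averaged = season_comps[cols].mean(axis=0).to_numpy()
            for i, cat in enumerate(CATEGORIES):
                out.append({"season": season, "convention": "pooled", "measure": measure,
                            "category": cat, "percent": pooled[i]})
                out.append({"season": season, "convention": "frog_mean", "measure": measure,
                            "category": cat, "percent": averaged[i]})
    return pd.DataFrame(out)


def table1_wide(group_table: pd.DataFrame, convention: str = "pooled") -> pd.DataFrame:
    """Pivot the tidy group summary into rows=season, columns=measure x category."""
    sub = group_table[group_table["convention"] == convention]
    wide = sub.pivot_table(index="season", columns=["measure", "category"],
                           values="percent", sort=False)
    wide.columns = [f"pct_{m}_{c}" for m, c in wide.columns]
    order = [f"pct_{m}_{c}" for m in ("number", "volume") for c in CATEGORIES]
    return wide[[c for c in order if c in wide.columns]]


def read_prey_csv(path) -> pd.DataFrame:
    """Read a prey-item CSV (frog_id, season, item_id, category, length_mm, width_mm, shape)."""
    df = pd.read_csv(path, dtype={"frog_id": str, "item_id": str})
    required = {"frog_id", "season", "category", "length_mm", "width_mm", "shape"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prey CSV missing columns: {sorted(missing)}")
    return df


def read_preaggregated_csv(path) -> pd.DataFrame:
    """Read a pre-aggregated diet CSV (frog_id, season, category, count, volume).

    Returns a per-frog composition table in the same layout as
    :func:`compositions_table`, for data already summarised per category.
    """
    df = pd.read_csv(path, dtype={"frog_id": str})
    required = {"frog_id", "season", "category", "count", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pre-aggregated CSV missing columns: {sorted(missing)}")
    rows = []
    for (frog_id, season), grp in df.groupby(["frog_id", "season"], sort=True):
        counts = grp.groupby("category")["count"].sum().reindex(CATEGORIES, fill_value=0).to_numpy(float)
        vols = grp.groupby("category")["volume"].sum().reindex(CATEGORIES, fill_value=0.0).to_numpy(float)
        if counts.sum() == 0:
            logger.warning("frog %s has zero prey; skipped", frog_id)
            continue
        row = {"frog_id": frog_id, "season": season,
               "total_number": int(counts.sum()), "total_volume_mm3": float(vols.sum())}
        for i, cat in enumerate(CATEGORIES):
            row[f"num_pct_{cat}"] = 100.0 * counts[i] / counts.sum()
            row[f"vol_pct_{cat}"] = 100.0 * vols[i] / vols.sum()
        rows.append(row)
    return pd.DataFrame(rows)
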