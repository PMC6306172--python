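"""Identity-threshold taxonomic assignment for barcode best hits.

Pre-computed CO1 best-hit tables (query, taxonomy, percent identity,
E-value) are turned into rank-resolved assignments: identities above 96%
support genus/species, identities below 95% only order/family, and the
unspecified [95, 96] band is resolved conservatively to family.  Missing
taxonomy levels degrade the assignment to the next coarser available rank.
No alignment is performed here — searches happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("order", "family", "genus", "species")
#: Fineness order used for monotonicity checks: lower index = finer.
RANK_FINENESS = {"species": 0, "genus": 1, "family": 2, "order": 3, "unassigned": 4}

#: Species assignments additionally require a best-hit E-value at or below
#: this ceiling; otherwise the hit only supports genus.
SPECIES_EVALUE_CEILING = 1e-5


@dataclass(frozen=True)
class BarcodeHit:
    """One best hit: 7-digit query id, database, taxonomy, identity, E-value.

    ``taxonomy`` is (order, family, genus, species); missing levels are
    ``None``.  An all-``None`` taxonomy is allowed and yields "unassigned".
    """

    query_id: str
    database: str
    taxonomy: tuple
    percent_identity: float
    e_value: float

    def __post_init__(self) -> None:
        if len(self.taxonomy) != 4:
            raise ValueError("taxonomy must be (order, family, genus, species)")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent identity must lie in [0, 100]")
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    assigned_rank: str  # species | genus | family | order | unassigned
    assigned_label: str
    basis: str = "barcode"  # barcode | morphology


def _clean(level) -> str | None:
    if level is None:
        return None
    s = str(level).strip()
    return s or None


def assign_taxonomic_rank(
    hit: BarcodeHit, species_e_ceiling: float = SPECIES_EVALUE_CEILING
) -> TaxonAssignment:
    """Apply the identity-threshold decision table to one best hit.

    identity > 96: species when a species epithet exists and the E-value is
    at or below the ceiling, else genus (derived from the binomial when no
    genus label is given), degrading to family/order when finer levels are
    missing.  identity < 95: family, else order.  identity in [95, 96]
    (unspecified by the stated rules): family, else order — the conservative
    midpoint.  A hit whose available levels cannot support the permitted
    ranks is "unassigned".
    """
    order_, family_, genus_, species_ = (_clean(t) for t in hit.taxonomy)
    if order_ is None and family_ is None and genus_ is None and species_ is None:
        return TaxonAssignment(hit.query_id, "unassigned", "")
    pid = hit.percent_identity
    if pid > 96:
        if species_ is not None and hit.e_value <= species_e_ceiling:
            return TaxonAssignment(hit.query_id, "species", species_)
        derived_genus = genus_ or (species_.split()[0] if species_ else None)
        for rank, label in (("genus", derived_genus), ("family", family_),
                            ("order", order_)):
            if label is not None:
                return TaxonAssignment(hit.query_id, rank, label)
        return TaxonAssignment(hit.query_id, "unassigned", "")
    # identity <= 96: rank is capped at family; [95, 96] resolves the same
    # way as < 95 (family preferred, order as fallback).
    for rank, label in (("family", family_), ("order", order_)):
        if label is not None:
            return TaxonAssignment(hit.query_id, rank, label)
    return TaxonAssignment(hit.query_id, "unassigned", "")


def morphology_assignment(query_id: str, label: str, rank: str = "species") -> TaxonAssignment:
    """Morphospecies record from photographs; bypasses identity thresholds."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    return TaxonAssignment(query_id, rank, label, basis="morphology")


def _hit_sort_key(row) -> tuple:
    tax = tuple("" if pd.isna(v) else str(v)
                for v in (row["order"], row["family"], row["genus"], row["species"]))
    return (-row["percent_identity"], row["e_value"], tax)


def assign_table(hits: pd.DataFrame,
                 species_e_ceiling: float = SPECIES_EVALUE_CEILING) -> pd.DataFrame:
    """Rank assignments for a best-hit table (one row kept per query).

    Ties on percent identity are broken by lower E-value, then
    lexicographically on the taxonomy string, so the outcome is
    deterministic.  Returns columns query_id, assigned_rank, assigned_label,
    basis.
    """
    required = {"query_id", "order", "family", "genus", "species",
                "percent_identity", "e_value"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    rows = []
    for query_id, grp in hits.groupby("query_id", sort=True):
        best = min(grp.to_dict("records"), key=_hit_sort_key)
        hit = BarcodeHit(
            query_id=str(query_id),
            database=str(best.get("database", "")),
            taxonomy=tuple(None if pd.isna(best[r]) else best[r] for r in RANKS),
            percent_identity=float(best["percent_identity"]),
            e_value=float(best["e_value"]),
        )
        a = assign_taxonomic_rank(hit, species_e_ceiling)
        rows.append({"query_id": a.query_id, "assigned_rank": a.assigned_rank,
                     "assigned_label": a.assigned_label, "basis": a.basis})
    return pd.DataFrame(rows)


def barcode_success_summary(attempted, succeeded) -> pd.DataFrame:
    """Amplification/sequencing success proportions per prey class.

    ``attempted`` and ``succeeded`` map prey class -> count; success percent
    is reported to one decimal.  Classes with zero attempts get an undefined
    (NaN) percent and are logged.
    """
    attempted = pd.Series(attempted, dtype=float)
    succeeded = pd.Series(succeeded, dtype=float).reindex(attempted.index, fill_value=0)
    if (succeeded > attempted).any():
        raise ValueError("succeeded counts exceed attempted counts")
    if (attempted < 0).any() or (succeeded < 0).any():
        raise ValueError("negative counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(attempted > 0, 100.0 * succeeded / attempted, np.nan)
    undefined = attempted.index[attempted == 0].tolist()
    if undefined:
        logger.warning("no attempts for classes %s; percent undefined", undefined)
    return pd.DataFrame({
        "attempted": attempted.astype(int),
        "succeeded": succeeded.astype(int),
        "percent": np.round(pct, 1),
    })
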