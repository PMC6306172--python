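"""Synthetic seasonal-study generator.

Emulates the statistical structure of a two-season poison-frog study so the
whole analysis pipeline is testable without any field data: per-frog prey
items with morphometrics (diet branch), barcode best-hit tables straddling
the identity thresholds (identification branch), and frog x alkaloid
intensity matrices with planted seasonal effects (chemistry branch).  All
draws come from seeded ``numpy`` generators, one independent stream per
dataset kind, so identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mantella.alkaloids import (
    DOCUMENTED_ALKALOIDS,
    AlkaloidFeature,
    AlkaloidMatrix,
)
from mantella.config import SyntheticConfig
from mantella.diet import CATEGORIES

# Stream tags keeping the three generators independent under one seed.
_DIET_STREAM, _ALKALOID_STREAM, _BARCODE_STREAM = 0, 1, 2

# Width/length ratio of prolate prey (log scale): arthropod bodies are
# roughly three times longer than wide.
_LOG_WIDTH_RATIO = np.log(0.35)
_LOG_WIDTH_RATIO_SD = 0.15

#: Synthetic filler codes used to pad the alkaloid catalogue to 41 features;
#: they carry no structural class or proposed origin.
SYNTHETIC_FILLER_CODES = (
    "205A", "207B", "217C", "223A", "235C", "241D",
    "249B", "251A", "263C", "269A", "281B",
)

# Small fixed taxonomy catalogue for barcode hits:
# (order, family, genus, species, database, weight)
_BARCODE_TAXA = (
    ("Hymenoptera", "Formicidae", "Pheidole", "Pheidole sp. MG051", "BOLD", 30),
    ("Hymenoptera", "Formicidae", "Pheidole", "Pheidole sp. MGS128", "BOLD", 12),
    ("Hymenoptera", "Formicidae", "Pheidole", "Pheidole nr. madecassa", "BOLD", 10),
    ("Hymenoptera", "Formicidae", "Paratrechina", "Paratrechina longicornis", "BOLD", 3),
    ("Hymenoptera", "Formicidae", "Tetramorium", None, "BOLD", 4),
    ("Hymenoptera", "Formicidae", "Solenopsis", None, "BOLD", 3),
    ("Sarcoptiformes", None, None, None, "GenBank", 10),
    ("Mesostigmata", None, None, None, "GenBank", 2),
    ("Araneae", None, None, None, "GenBank", 3),
    ("Diptera", "Ceratopogonidae", None, None, "GenBank", 8),
    ("Lepidoptera", "Crambidae", None, None, "GenBank", 3),
    ("Coleoptera", "Elateridae", None, None, "GenBank", 4),
    ("Collembola", None, None, None, "GenBank", 3),
    ("Hymenoptera", "Braconidae", None, None, "GenBank", 2),
    ("Psocoptera", None, None, None, "GenBank", 2),
)


def _vouchers(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    dry = [f"{1000 + i + 1}" for i in range(config.n_dry)]
    wet = [f"{2000 + i + 1}" for i in range(config.n_wet)]
    return dry, wet


def _dirichlet(rng: np.random.Generator, alphas: np.ndarray, size: int) -> np.ndarray:
    """Dirichlet draws via gamma variables; zero concentrations give exact zeros."""
    g = rng.gamma(np.broadcast_to(alphas, (size, alphas.size)).copy())
    totals = g.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return g / totals


def generate_diet_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Per-prey-item table with frog metadata and morphometrics.

    Per frog the prey count is negative-binomial; item categories follow a
    Dirichlet-multinomial around the season's mean composition; lengths and
    widths are log-normal on the mm scale per category.  Mites are spheres
    with probability ``mite_sphere_prob`` (width = diameter = length); all
    other items are prolate.  Item ids are seven digits: four-digit frog
    voucher + three-digit isolation ordinal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DIET_STREAM]))
    dry_ids, wet_ids = _vouchers(config)
    mu = np.asarray([config.size_log_mean]).ravel()
    sd = np.asarray([config.size_log_sd]).ravel()
    k = config.prey_count_dispersion
    p_nb = k / (k + config.prey_count_mean)
    mite_idx = CATEGORIES.index("mites")

    frames = []
    for season, vouchers, means in (
        ("dry", dry_ids, np.asarray(config.category_means_dry)),
        ("wet", wet_ids, np.asarray(config.category_means_wet)),
    ):
        n_frogs = len(vouchers)
        counts = np.minimum(rng.negative_binomial(k, p_nb, size=n_frogs), 999)
        probs = _dirichlet(rng, config.dirichlet_concentration * means, n_frogs)
        total = int(counts.sum())
        frog_idx = np.repeat(np.arange(n_frogs), counts)
        u = rng.random(total)
        cum = np.cumsum(probs, axis=1)
        cat = (cum[frog_idx] < u[:, None]).sum(axis=1)
        cat = np.minimum(cat, len(CATEGORIES) - 1)
        length = np.exp(rng.normal(mu[cat], sd[cat]))
        width = length * np.exp(rng.normal(_LOG_WIDTH_RATIO, _LOG_WIDTH_RATIO_SD,
                                           size=total))
        width = np.minimum(width, length)
        sphere = (cat == mite_idx) & (rng.random(total) < config.mite_sphere_prob)
        width = np.where(sphere, length, width)
        ordinal = np.concatenate([np.arange(1, c + 1) for c in counts]) if total else np.array([], int)
        frames.append(pd.DataFrame({
            "frog_id": np.asarray(vouchers)[frog_idx],
            "season": season,
            "item_id": [f"{v}{o:03d}" for v, o in
                        zip(np.asarray(vouchers)[frog_idx], ordinal)],
            "category": np.asarray(CATEGORIES)[cat],
            "length_mm": np.round(length, 3),
            "width_mm": np.round(width, 3),
            "shape": np.where(sphere, "sphere", "prolate"),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["frog_id", "item_id"], kind="stable").reset_index(drop=True)


def alkaloid_catalogue(n: int) -> list[AlkaloidFeature]:
    """First ``n`` features of the built-in catalogue: 30 documented codes,
    11 synthetic fillers, then generated placeholder codes if more are asked for."""
    features = [AlkaloidFeature(code, cls, origin)
                for code, (cls, origin) in DOCUMENTED_ALKALOIDS.items()]
    features += [AlkaloidFeature(code) for code in SYNTHETIC_FILLER_CODES]
    i = 0
    while len(features) < n:
        features.append(AlkaloidFeature(f"{400 + i}X"))
        i += 1
    return features[:n]


def generate_alkaloid_dataset(
    config: SyntheticConfig,
) -> tuple[AlkaloidMatrix, np.ndarray]:
    """Raw frog x alkaloid intensity matrix plus ground-truth effect labels.

    Log-intensities are normal around per-feature baselines; for
    ``n_shifted`` randomly chosen features the wet-season location is
    multiplied by ``fold_change`` (additive ``log(fold_change)`` on the log
    scale).  Entries drop below detection (exact 0) independently with
    probability ``1 - detection_prob``; skin masses are normal truncated at
    zero.  Returns the matrix (un-normalized intensities) and the sorted
    indices of the truly shifted features.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _ALKALOID_STREAM]))
    dry_ids, wet_ids = _vouchers(config)
    frog_ids = dry_ids + wet_ids
    seasons = ["dry"] * config.n_dry + ["wet"] * config.n_wet
    n = len(frog_ids)
    p = config.n_alkaloids
    features = alkaloid_catalogue(p)

    shifted = np.sort(rng.choice(p, size=config.n_shifted, replace=False))
    baselines = rng.normal(config.abundance_log_mean, 0.5, size=p)
    logx = rng.normal(baselines, config.abundance_log_sd, size=(n, p))
    wet_rows = np.asarray(seasons) == "wet"
    logx[np.ix_(wet_rows, shifted)] += np.log(config.fold_change)
    x = np.exp(logx)
    detected = rng.random((n, p)) < config.detection_prob
    x = np.where(detected, x, 0.0)

    mass = rng.normal(config.skin_mass_mean_g, config.skin_mass_sd_g, size=n)
    for _ in range(100):
        bad = mass <= 0
        if not bad.any():
            break
        mass[bad] = rng.normal(config.skin_mass_mean_g, config.skin_mass_sd_g,
                               size=int(bad.sum()))
    mass = np.abs(mass)  # last-resort guard; practically never reached

    samples = pd.DataFrame({"frog_id": frog_ids, "season": seasons,
                            "skin_mass_g": np.round(mass, 4)})
    abundance = pd.DataFrame(np.round(x, 2), index=pd.Index(frog_ids, name="frog_id"),
                             columns=[f.code for f in features])
    matrix = AlkaloidMatrix(samples=samples, features=features,
                            abundance=abundance, normalized=False)
    return matrix, shifted


def generate_barcode_hits(config: SyntheticConfig, n_hits: int = 80) -> pd.DataFrame:
    """Best-hit table emulating barcode search output.

    Percent identities straddle the 95/96 rank-assignment thresholds (half
    the draws above 96.5, a fifth inside [95, 96], the rest below 95);
    taxonomy strings come from a small fixed catalogue that includes the ant
    genus *Pheidole* and the mite order Sarcoptiformes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _BARCODE_STREAM]))
    dry_ids, wet_ids = _vouchers(config)
    vouchers = np.asarray(dry_ids + wet_ids)
    weights = np.array([t[5] for t in _BARCODE_TAXA], float)
    weights /= weights.sum()
    taxa_idx = rng.choice(len(_BARCODE_TAXA), size=n_hits, p=weights)
    band = rng.random(n_hits)
    identity = np.where(
        band < 0.5, rng.uniform(96.5, 100.0, n_hits),
        np.where(band < 0.7, rng.uniform(95.0, 96.0, n_hits),
                 rng.uniform(88.0, 95.0, n_hits)),
    )
    rows = []
    owner = rng.choice(len(vouchers), size=n_hits)
    e_value = 10.0 ** (-rng.uniform(20.0, 120.0, size=n_hits))
    for i in range(n_hits):
        order, family, genus, species, database, _ = _BARCODE_TAXA[taxa_idx[i]]
        rows.append({
            "query_id": f"{vouchers[owner[i]]}{i + 1:03d}",
            "database": database,
            "order": order, "family": family, "genus": genus, "species": species,
            "percent_identity": round(float(identity[i]), 1),
            "e_value": float(e_value[i]),
        })
    return pd.DataFrame(rows)
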