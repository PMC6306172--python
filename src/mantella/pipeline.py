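"""End-to-end orchestration of the diet and alkaloid analysis branches.

Each branch consumes a table (real CSV or synthetic), runs the seasonal
statistics, and writes tidy CSV results plus a run-metadata JSON recording
sample sizes, options, derived stage seeds and the package version, so
every number in the report is traceable to a named operation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mantella import __version__
from mantella.alkaloids import (
    AlkaloidMatrix,
    annotate_origin,
    normalize_matrix,
    prevalence_filter,
)
from mantella.diet import CATEGORIES, compositions_table, group_diet_table, table1_wide
from mantella.stats import (
    anosim,
    bray_curtis_matrix,
    mann_whitney_u,
    nmds,
    permanova,
    permutation_screen,
)

logger = logging.getLogger(__name__)

# Stage tags for the counter-based seed fan-out: each analysis stage gets an
# independently reproducible substream of the top-level seed.
_STAGES = ("nmds_number", "nmds_volume", "permanova_number", "permanova_volume",
           "nmds_alkaloid", "permanova_alkaloid", "anosim_alkaloid", "screen")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the top-level seed."""
    idx = _STAGES.index(stage)
    state = np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
    return int(state % (2 ** 31))


@dataclass
class StatOptions:
    """Statistical options shared by both branches."""

    u_method: str = "auto"
    tie_correction: bool = False
    n_permutations: int = 999
    screen_permutations: int = 250
    alpha: float = 0.05
    nmds_restarts: int = 20
    min_prevalence: float = 0.5


def _write_metadata(out_dir: Path, name: str, payload: dict) -> None:
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _season_tests(comps: pd.DataFrame, options: StatOptions) -> pd.DataFrame:
    """Per-category Mann-Whitney tests (dry = group 1) on percent vectors."""
    dry = comps[comps["season"] == "dry"]
    wet = comps[comps["season"] == "wet"]
    rows = []
    for measure, prefix in (("number", "num_pct"), ("volume", "vol_pct")):
        for cat in CATEGORIES:
            col = f"{prefix}_{cat}"
            res = mann_whitney_u(dry[col], wet[col], method=options.u_method,
                                 tie_correction=options.tie_correction)
            rows.append({"measure": measure, "category": cat,
                         "U_dry": res.U_group1, "U_wet": res.U_group2,
                         "p": res.p_two_sided, "p_rounded": round(res.p_two_sided, 3),
                         "method": res.method, "tie_corrected": res.tie_corrected})
    return pd.DataFrame(rows)


def _ordination_frame(result, ids, seasons) -> pd.DataFrame:
    return pd.DataFrame({
        "frog_id": ids, "season": seasons,
        "nmds1": result.coordinates[:, 0], "nmds2": result.coordinates[:, 1],
    })


def _maybe_plot(df: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for season, marker in (("dry", "o"), ("wet", "s")):
        sub = df[df["season"] == season]
        ax.scatter(sub["nmds1"], sub["nmds2"], marker=marker, label=season)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_diet_analysis(
    items: pd.DataFrame, out_dir, seed: int,
    options: StatOptions | None = None, plot: bool = False,
) -> dict:
    """Diet branch: compositions, per-category tests, NMDS + PERMANOVA.

    The ordination and PERMANOVA run twice, once on percent-number and once
    on percent-volume compositions.  Requires at least two frogs with
    non-empty stomachs per season.
    """
    options = options or StatOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if items.empty:
        raise ValueError("empty prey-item table")
    comps = compositions_table(items)
    n_per_season = comps["season"].value_counts().to_dict()
    if len(n_per_season) < 2 or min(n_per_season.values()) < 2:
        raise ValueError(f"need >= 2 frogs per season, got {n_per_season}")
    logger.info("diet branch: %s frogs", n_per_season)

    group = group_diet_table(items)
    tests = _season_tests(comps, options)
    table1 = table1_wide(group, convention="pooled")

    results = {"compositions": comps, "group_table": group, "tests": tests,
               "table1_pooled": table1}
    comps.to_csv(out_dir / "diet_compositions.csv", index=False)
    group.to_csv(out_dir / "diet_group_table.csv", index=False)
    tests.to_csv(out_dir / "diet_tests.csv", index=False)
    table1.to_csv(out_dir / "diet_table1_pooled.csv")
    table1_wide(group, convention="frog_mean").to_csv(out_dir / "diet_table1_frog_mean.csv")

    seasons = comps["season"].to_numpy()
    summary = {}
    for measure, prefix in (("number", "num_pct"), ("volume", "vol_pct")):
        X = comps[[f"{prefix}_{c}" for c in CATEGORIES]].to_numpy()
        D = bray_curtis_matrix(X)
        ord_res = nmds(D, n_restarts=options.nmds_restarts,
                       seed=stage_seed(seed, f"nmds_{measure}"))
        perm = permanova(D, seasons, n_permutations=options.n_permutations,
                         seed=stage_seed(seed, f"permanova_{measure}"))
        coords = _ordination_frame(ord_res, comps["frog_id"], seasons)
        coords.to_csv(out_dir / f"diet_nmds_{measure}.csv", index=False)
        if plot:
            _maybe_plot(coords, out_dir / f"diet_nmds_{measure}.png",
                        f"Diet NMDS (percent {measure})")
        summary[measure] = {"stress": ord_res.stress, "pseudo_F": perm.pseudo_F,
                            "p_perm": perm.p_perm}
        results[f"nmds_{measure}"] = ord_res
        results[f"permanova_{measure}"] = perm

    _write_metadata(out_dir, "diet_metadata.json", {
        "version": __version__, "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES[:4]},
        "options": asdict(options), "n_per_season": n_per_season,
        "ordination": summary,
    })
    return results


def run_alkaloid_analysis(
    matrix: AlkaloidMatrix, out_dir, seed: int,
    options: StatOptions | None = None, plot: bool = False,
) -> dict:
    """Alkaloid branch: normalize, prevalence-filter, ordinate, screen.

    Normalizes to skin mass (if not already), retains features present in at
    least half the frogs, runs NMDS/PERMANOVA/ANOSIM on Bray-Curtis
    dissimilarities, then per-alkaloid Mann-Whitney tests calibrated by the
    label-permutation screen.  Directions of change are medians of the
    normalized abundances (wet-elevated vs dry-elevated).
    """
    options = options or StatOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_per_season = matrix.samples["season"].value_counts().to_dict()
    if len(n_per_season) < 2 or min(n_per_season.values()) < 2:
        raise ValueError(f"need >= 2 frogs per season, got {n_per_season}")
    logger.info("alkaloid branch: %s frogs, %d features",
                n_per_season, len(matrix.features))

    norm = matrix if matrix.normalized else normalize_matrix(matrix)
    filtered = annotate_origin(prevalence_filter(norm, options.min_prevalence))
    if not filtered.features:
        raise ValueError("prevalence filter removed every feature")

    seasons = filtered.samples["season"].to_numpy()
    X = filtered.abundance.to_numpy(float)
    D = bray_curtis_matrix(X)
    ord_res = nmds(D, n_restarts=options.nmds_restarts,
                   seed=stage_seed(seed, "nmds_alkaloid"))
    perm = permanova(D, seasons, n_permutations=options.n_permutations,
                     seed=stage_seed(seed, "permanova_alkaloid"))
    ano = anosim(D, seasons, n_permutations=options.n_permutations,
                 seed=stage_seed(seed, "anosim_alkaloid"))
    screen = permutation_screen(
        filtered.abundance, seasons, n_permutations=options.screen_permutations,
        alpha=options.alpha, seed=stage_seed(seed, "screen"), group1="dry",
        tie_correction=options.tie_correction,
    )

    dry_mask = seasons == "dry"
    med_dry = np.median(X[dry_mask], axis=0)
    med_wet = np.median(X[~dry_mask], axis=0)
    direction = np.where(med_wet > med_dry, "wet-elevated",
                         np.where(med_dry > med_wet, "dry-elevated", "equal"))
    table = screen.table.rename(columns={"feature": "code"}).copy()
    table.insert(1, "structural_class", [f.structural_class for f in filtered.features])
    table.insert(2, "proposed_origin", [f.proposed_origin for f in filtered.features])
    table["median_dry"] = med_dry
    table["median_wet"] = med_wet
    table["direction"] = direction
    table["p_rounded"] = table["p_real"].round(3)

    coords = _ordination_frame(ord_res, filtered.samples["frog_id"], seasons)
    table.to_csv(out_dir / "alkaloid_tests.csv", index=False)
    coords.to_csv(out_dir / "alkaloid_nmds.csv", index=False)
    if plot:
        _maybe_plot(coords, out_dir / "alkaloid_nmds.png", "Alkaloid NMDS")
    _write_metadata(out_dir, "alkaloid_metadata.json", {
        "version": __version__, "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES[4:]},
        "options": asdict(options), "n_per_season": n_per_season,
        "n_features_input": len(matrix.features),
        "n_features_retained": len(filtered.features),
        "normalized_on_ingest": not matrix.normalized,
        "ordination": {"stress": ord_res.stress},
        "permanova": {"pseudo_F": perm.pseudo_F, "p_perm": perm.p_perm},
        "anosim": {"R": ano.R, "p_perm": ano.p_perm},
        "n_significant": int(screen.significant.sum()),
    })
    return {"matrix": filtered, "tests": table, "nmds": ord_res,
            "permanova": perm, "anosim": ano, "screen": screen}
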