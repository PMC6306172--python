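"""Prey volume geometry, category rules, and composition arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from mantella.diet import (
    CATEGORIES,
    FrogRecord,
    PreyItem,
    classify_prey_category,
    compositions_table,
    frog_composition,
    group_diet_table,
    prey_volume,
    read_preaggregated_csv,
    read_prey_csv,
    table1_wide,
)


def test_unit_spheroid_and_sphere_agree():
    v = 4 * math.pi / 3
    assert prey_volume(2, 2, "prolate") == pytest.approx(v)
    assert prey_volume(2, 2, "sphere") == pytest.approx(v)


def test_prolate_degenerates_to_sphere_when_round():
    for w in (0.4, 1.3, 5.0):
        assert prey_volume(w, w, "prolate") == pytest.approx(prey_volume(w, w, "sphere"))


def test_prolate_volume_matches_solid_of_revolution():
    # independent oracle: revolve the ellipse y = b*sqrt(1 - x^2/a^2) about x
    length, width = 4.2, 1.1
    a, b = length / 2, width / 2
    oracle, _ = quad(lambda x: math.pi * b**2 * (1 - x**2 / a**2), -a, a)
    assert prey_volume(length, width, "prolate") == pytest.approx(oracle, rel=1e-10)
    assert oracle == pytest.approx(2.6609, abs=2e-4)


def test_volume_monotone_in_each_dimension():
    base = prey_volume(3.0, 1.0)
    assert prey_volume(3.5, 1.0) > base
    assert prey_volume(3.0, 1.2) > base


def test_volume_errors_and_oblate_warning():
    with pytest.raises(ValueError):
        prey_volume(0.0, 1.0)
    with pytest.raises(ValueError):
        prey_volume(2.0, -1.0)
    with pytest.raises(ValueError):
        prey_volume(1.0, 1.0, shape="cube")
    with pytest.warns(UserWarning):
        v = prey_volume(1.0, 2.0, "prolate")
    assert v > 0  # kept despite the warning


@pytest.mark.parametrize(
    "order,family,life_stage,expected",
    [
        ("Diptera", None, "larva", "larvae"),
        ("Lepidoptera", "Crambidae", "larva", "larvae"),
        ("Hymenoptera", "Formicidae", "adult", "ants"),
        ("Hymenoptera", "Formicidae", "larva", "larvae"),
        ("Sarcoptiformes", None, "adult", "mites"),
        ("Mesostigmata", None, "adult", "mites"),
        ("Araneae", None, "adult", "other"),  # spiders are not Acari
        ("Isoptera", None, "adult", "termites"),
        ("Collembola", None, "adult", "other"),
        ("Hymenoptera", "Braconidae", "adult", "other"),
        ("Coleoptera", "Elateridae", "adult", "other"),
    ],
)
def test_category_rules(order, family, life_stage, expected):
    assert classify_prey_category(order, family, life_stage=life_stage) == expected


def test_missing_taxonomy_goes_to_other():
    assert classify_prey_category(None, None) == "other"


def _frog(frog_id, specs):
    prey = [PreyItem(f"{frog_id}{i:03d}", frog_id, cat, 1.0, 1.0, "prolate", vol)
            for i, (cat, vol) in enumerate(specs, start=1)]
    return FrogRecord(frog_id, "dry", prey=prey)


def test_frog_composition_hand_counts():
    comp = frog_composition(_frog("1001", [("ants", 1.0)] * 3 + [("mites", 1.0)]))
    assert comp.percent_number == pytest.approx([75, 25, 0, 0, 0])
    assert comp.percent_volume == pytest.approx([75, 25, 0, 0, 0])

    comp = frog_composition(_frog("1002", [("ants", 1.0), ("larvae", 9.0)]))
    assert comp.percent_number == pytest.approx([50, 0, 50, 0, 0])
    assert comp.percent_volume == pytest.approx([10, 0, 90, 0, 0])
    assert comp.percent_number.sum() == pytest.approx(100, abs=1e-9)
    assert comp.percent_volume.sum() == pytest.approx(100, abs=1e-9)


def test_empty_stomach_is_undefined():
    assert frog_composition(FrogRecord("1003", "dry")) is None


def test_percent_volume_scale_invariant():
    specs = [("ants", 2.0), ("mites", 5.0), ("other", 3.0)]
    a = frog_composition(_frog("1001", specs))
    b = frog_composition(_frog("1001", [(c, 2 * v) for c, v in specs]))
    assert a.percent_volume == pytest.approx(b.percent_volume)


def _items_df(rows):
    return pd.DataFrame(rows, columns=["frog_id", "season", "item_id", "category",
                                       "length_mm", "width_mm", "shape"])


def test_group_conventions_differ_with_unequal_counts():
    rows = [("f1", "dry", f"f1{i:03d}", "ants", 2.0, 1.0, "prolate") for i in range(3)]
    rows += [("f2", "dry", "f2001", "mites", 2.0, 1.0, "prolate")]
    table = group_diet_table(_items_df(rows))
    num = table[(table.measure == "number") & (table.category == "ants")]
    pooled = num[num.convention == "pooled"]["percent"].item()
    averaged = num[num.convention == "frog_mean"]["percent"].item()
    assert pooled == pytest.approx(75.0)
    assert averaged == pytest.approx(50.0)


def test_group_conventions_agree_when_balanced():
    rows = [("f1", "dry", f"f1{i:03d}", "ants", 2.0, 1.0, "prolate") for i in range(2)]
    rows += [("f2", "dry", f"f2{i:03d}", "mites", 2.0, 1.0, "prolate") for i in range(2)]
    table = group_diet_table(_items_df(rows))
    num = table[(table.measure == "number") & (table.category == "ants")]
    assert set(num["percent"].round(9)) == {50.0}


def test_group_pooled_tracks_configured_means():
    from mantella.config import SyntheticConfig
    from mantella.synthetic import generate_diet_dataset

    cfg = SyntheticConfig(seed=5, n_dry=1000, n_wet=1000)
    table = group_diet_table(generate_diet_dataset(cfg))
    dry_ants = table[(table.season == "dry") & (table.convention == "pooled")
                     & (table.measure == "number") & (table.category == "ants")]
    assert dry_ants["percent"].item() == pytest.approx(
        100 * cfg.category_means_dry[0], abs=1.5)


def test_counts_conserved_in_composition_table():
    rows = [("f1", "wet", "f1001", "ants", 2.0, 1.0, "prolate"),
            ("f1", "wet", "f1002", "larvae", 4.0, 1.5, "prolate"),
            ("f1", "wet", "f1003", "mites", 0.5, 0.5, "sphere")]
    comps = compositions_table(_items_df(rows))
    assert comps["total_number"].item() == 3
    pct_cols = [f"num_pct_{c}" for c in CATEGORIES]
    assert comps[pct_cols].sum(axis=1).item() == pytest.approx(100, abs=1e-9)


def test_table1_wide_layout():
    rows = [("f1", "dry", "f1001", "ants", 2.0, 1.0, "prolate"),
            ("f2", "wet", "f2001", "mites", 0.5, 0.5, "sphere")]
    wide = table1_wide(group_diet_table(_items_df(rows)))
    assert list(wide.index) == ["dry", "wet"]
    assert wide.loc["dry", "pct_number_ants"] == pytest.approx(100.0)
    assert wide.loc["wet", "pct_volume_mites"] == pytest.approx(100.0)


def test_prey_csv_roundtrip(tmp_path):
    rows = [("1001", "dry", "1001001", "ants", 2.5, 1.0, "prolate")]
    df = _items_df(rows)
    path = tmp_path / "prey.csv"
    df.to_csv(path, index=False)
    back = read_prey_csv(path)
    assert back["frog_id"].dtype == object
    assert back.shape == df.shape


def test_preaggregated_reader(tmp_path):
    df = pd.DataFrame({
        "frog_id": ["1001", "1001", "2001"],
        "season": ["dry", "dry", "wet"],
        "category": ["ants", "other", "larvae"],
        "count": [3, 1, 2],
        "volume": [3.0, 1.0, 10.0],
    })
    path = tmp_path / "agg.csv"
    df.to_csv(path, index=False)
    comps = read_preaggregated_csv(path)
    dry = comps[comps.frog_id == "1001"]
    assert dry["num_pct_ants"].item() == pytest.approx(75.0)
    assert dry["vol_pct_ants"].item() == pytest.approx(75.0)
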