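"""Attribute rollup, coverage maps, digestion QC rates and Venn regions."""
from __future__ import annotations

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from mampep.digest import ProteinChain
from mampep.rollup import (
    AttributeDefinition,
    coverage_map,
    glycan_profile,
    missed_cleavage_rate,
    nonspecific_rate,
    relative_abundance,
    venn_membership,
)


def _df(rows):
    defaults = dict(lab="lab0", replicate=0, sample="s", timepoint=0.0,
                    chain_id="HC", start=1, end=5, missed_cleavages=0,
                    specific=True, found=True, include_in_rollup=True)
    return pd.DataFrame([{**defaults, **r} for r in rows])


def test_pairwise_relative_abundance():
    df = _df([{"component_id": "m", "area": 12.0}, {"component_id": "u", "area": 88.0}])
    attr = AttributeDefinition(label="a", mode="pairwise", modified=("m",), reference=("u",))
    res = relative_abundance(df, attr)
    assert res.value == pytest.approx(12.0)
    assert res.defined


def test_pairwise_zero_denominator_flagged_not_zero():
    df = _df([{"component_id": "m", "area": 0.0}, {"component_id": "u", "area": 0.0}])
    attr = AttributeDefinition(label="a", mode="pairwise", modified=("m",), reference=("u",))
    res = relative_abundance(df, attr)
    assert not res.defined
    assert np.isnan(res.value)


def test_proportional_missed_cleavage_partner_leaves_value_unchanged():
    base = [{"component_id": "m", "area": 12.0}, {"component_id": "u", "area": 88.0}]
    partner = [{"component_id": "m1", "area": 1.8}, {"component_id": "u1", "area": 13.2}]
    attr_a = AttributeDefinition(label="a", mode="pairwise", modified=("m",), reference=("u",))
    attr_b = AttributeDefinition(label="a", mode="pairwise",
                                 modified=("m", "m1"), reference=("u", "u1"))
    assert relative_abundance(_df(base), attr_a).value == pytest.approx(
        relative_abundance(_df(base + partner), attr_b).value)


def test_scaling_invariance():
    rows = [{"component_id": "m", "area": 3.0}, {"component_id": "u", "area": 97.0}]
    scaled = [{**r, "area": r["area"] * 123.0} for r in rows]
    attr = AttributeDefinition(label="a", mode="pairwise", modified=("m",), reference=("u",))
    assert relative_abundance(_df(rows), attr).value == pytest.approx(
        relative_abundance(_df(scaled), attr).value)


def test_profile_equal_areas():
    members = {f"g{i}": (f"g{i}",) for i in range(4)}
    df = _df([{"component_id": f"g{i}", "area": 5.0} for i in range(4)])
    attr = AttributeDefinition(label="site", mode="profile", site_label="site",
                               profile_members=members)
    results = glycan_profile(df, attr)
    assert [r.value for r in results] == pytest.approx([25.0] * 4)
    assert sum(r.value for r in results) == pytest.approx(100.0, abs=0.01)


def test_profile_zero_total_all_flagged():
    members = {"g0": ("g0",), "g1": ("g1",)}
    df = _df([{"component_id": "g0", "area": 0.0}, {"component_id": "g1", "area": 0.0}])
    attr = AttributeDefinition(label="s", mode="profile", profile_members=members)
    assert all(not r.defined for r in glycan_profile(df, attr))


def test_profile_sums_on_random_areas():
    rng = random.Random(0)
    members = {f"g{i}": (f"g{i}",) for i in range(8)}
    attr = AttributeDefinition(label="s", mode="profile", profile_members=members)
    for _ in range(10):
        df = _df([{"component_id": f"g{i}", "area": rng.uniform(0.1, 50)}
                  for i in range(8)])
        assert sum(r.value for r in glycan_profile(df, attr)) == pytest.approx(100.0, abs=0.01)


def test_attribute_definition_validation():
    with pytest.raises(ValueError):
        AttributeDefinition(label="a", mode="pairwise", modified=(), reference=("u",))
    with pytest.raises(ValueError):
        AttributeDefinition(label="a", mode="profile", profile_members={"g": ("g",)})
    with pytest.raises(ValueError):
        AttributeDefinition(label="a", mode="sideways")


# ------------------------------------------------------------------- coverage maps

def test_tiling_peptides_give_full_coverage():
    chain = ProteinChain(id="HC", sequence="AAKGGKVVK")
    df = _df([
        {"component_id": "p1", "area": 100.0, "start": 1, "end": 3},
        {"component_id": "p2", "area": 10.0, "start": 4, "end": 6},
        {"component_id": "p3", "area": 1.0, "start": 7, "end": 9},
    ])
    cmap = coverage_map(df, chain)
    assert cmap.coverage_percent == pytest.approx(100.0)
    assert cmap.recovery_class[:3] == [">50"] * 3


def test_no_peptides_zero_coverage():
    chain = ProteinChain(id="HC", sequence="AAKGGK")
    empty = pd.DataFrame(columns=["component_id", "chain_id", "start", "end",
                                  "area", "found"])
    cmap = coverage_map(empty, chain)
    assert cmap.coverage_percent == 0.0
    assert set(cmap.recovery_class) == {"<=1"}


def test_removing_only_spanning_peptide_lowers_coverage_exactly():
    chain = ProteinChain(id="HC", sequence="AAKGGKVVK")
    rows = [
        {"component_id": "p1", "area": 10.0, "start": 1, "end": 3},
        {"component_id": "p2", "area": 10.0, "start": 4, "end": 6},
        {"component_id": "p3", "area": 10.0, "start": 7, "end": 9},
    ]
    full = coverage_map(_df(rows), chain).coverage_percent
    partial = coverage_map(_df(rows[:2]), chain).coverage_percent
    assert full - partial == pytest.approx(100.0 * 3 / 9)


def test_recovery_class_thresholds_exact():
    chain = ProteinChain(id="HC", sequence="A" * 7 + "K")
    # distinct single-residue areas as % of max: 100, 51, 21, 11, 6, 3, 1.5, 0.5
    areas = [100.0, 51.0, 21.0, 11.0, 6.0, 3.0, 1.5, 0.5]
    rows = [{"component_id": f"p{i}", "area": a, "start": i + 1, "end": i + 1}
            for i, a in enumerate(areas)]
    cmap = coverage_map(_df(rows), chain)
    assert cmap.recovery_class == [">50", ">50", ">20", ">10", ">5", ">2", ">1", "<=1"]


# ------------------------------------------------------------------ digestion rates

def test_missed_cleavage_rate_examples():
    all_zero = _df([{"component_id": "a", "area": 10.0, "missed_cleavages": 0}])
    assert missed_cleavage_rate(all_zero) == pytest.approx(0.0)
    mix = _df([{"component_id": "a", "area": 30.0, "missed_cleavages": 1},
               {"component_id": "b", "area": 70.0, "missed_cleavages": 0}])
    assert missed_cleavage_rate(mix) == pytest.approx(30.0)
    assert np.isnan(missed_cleavage_rate(_df([{"component_id": "a", "area": 0.0}])))


def test_nonspecific_rate_examples():
    df = _df([{"component_id": "n", "area": 3.0, "specific": False},
              {"component_id": "s", "area": 97.0, "specific": True}])
    assert nonspecific_rate(df) == pytest.approx(3.0)
    scaled = df.assign(area=df.area * 7.0)
    assert nonspecific_rate(scaled) == pytest.approx(3.0)
    only_spec = _df([{"component_id": "s", "area": 5.0}])
    assert nonspecific_rate(only_spec) == pytest.approx(0.0)


def test_missed_rate_matches_generator_bookkeeping(
        table1_truth, table1_components, noiseless_quant):
    """The pipeline's rate equals the closed form from the truth's loadings."""
    num = den = 0.0
    for comp in table1_components:
        signal = table1_truth.loading_for(comp) * table1_truth.fraction_for(comp)
        if comp.specific:
            den += signal
            if comp.missed_cleavages >= 1:
                num += signal
    expected = 100.0 * num / den
    assert missed_cleavage_rate(noiseless_quant.components) == pytest.approx(
        expected, rel=5e-3)


# ------------------------------------------------------------------ Venn membership

def test_venn_identical_sets_all_central():
    peptides = [("AAK", "", 300.0), ("GGR", "oxidation", 400.0)]
    regions = venn_membership({f"lab{i}": list(peptides) for i in range(4)})
    assert regions == {frozenset({"lab0", "lab1", "lab2", "lab3"}): 2}


def test_venn_one_extra_peptide():
    base = [("AAK", "", 300.0)]
    regions = venn_membership({"A": base + [("GGR", "", 400.0)], "B": list(base)})
    assert regions[frozenset({"A", "B"})] == 1
    assert regions[frozenset({"A"})] == 1


def test_venn_mass_disagreement_splits_region():
    ppm_off = 400.0 * (1 + 50e-6)
    regions = venn_membership({"A": [("GGR", "", 400.0)], "B": [("GGR", "", ppm_off)]},
                              ppm=5.0)
    assert sum(regions.values()) == 2  # two singleton regions


def test_venn_partition_property():
    rng = random.Random(3)
    union = [(f"P{i}K", "", 500.0 + i) for i in range(30)]
    labs = {}
    membership: dict[tuple, set] = {}
    for lab in ("A", "B", "C"):
        chosen = [p for p in union if rng.random() < 0.7]
        labs[lab] = chosen
        for p in chosen:
            membership.setdefault(p, set()).add(lab)
    regions = venn_membership(labs)
    assert sum(regions.values()) == len(membership)
    for combo_size in (1, 2, 3):
        for combo in itertools.combinations("ABC", combo_size):
            expected = sum(1 for labs_seen in membership.values()
                           if labs_seen == set(combo))
            assert regions.get(frozenset(combo), 0) == expected


def test_venn_lab_count_limits():
    sets = {f"lab{i}": [("AAK", "", 300.0)] for i in range(5)}
    with pytest.raises(ValueError, match="2 to 4"):
        venn_membership(sets)


def test_nonspecific_rate_end_to_end_matches_truth():
    """A simulated semi-tryptic background is recovered as the area rate."""
    from mampep.components import ComponentEntry
    from mampep.quant import quantify_components
    from mampep.simulate import (
        ScenarioConfig, make_ground_truth, predict_rt, simulate_run)

    truth = make_ground_truth("stability_table2:mAb3_LC:M4:0:A",
                              missed_fraction=0.0)
    truth.nonspecific_fraction = 0.03
    full = ComponentEntry(sequence="DIQMTQSPSSLSASVGDR", charges=(2,),
                          expected_rt_min=predict_rt("DIQMTQSPSSLSASVGDR"))
    semi = ComponentEntry(sequence="IQMTQSPSSLSASVGDR", charges=(2,),
                          specific=False,
                          expected_rt_min=predict_rt("IQMTQSPSSLSASVGDR"))
    run = simulate_run(truth, [full, semi], ScenarioConfig(seed=12, noise_cv=0.0))
    df = quantify_components(run, [full, semi]).components
    assert nonspecific_rate(df) == pytest.approx(100.0 * 0.03 / 1.03, rel=5e-3)
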