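"""Precision statistics: RSD, one-way ANOVA variance components, trends."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mampep.constants import table_rows
from mampep.stats import anova_precision, precision_report, rsd, trend_summary


def _two_pass_rsd(values):
    arr = np.asarray(values, dtype=float)
    mean = arr.sum() / arr.size
    var = sum((x - mean) ** 2 for x in arr) / (arr.size - 1)
    return 100.0 * var**0.5 / mean


def test_rsd_on_reported_lys_loss_panel():
    """The four-laboratory Lys-loss row gives ~1.72% means-based RSD."""
    row = next(r for r in table_rows("nist_table1") if r["modification"] == "Lys loss")
    values = [float(row[lab]) for lab in ("Ireland", "Denmark", "UK", "Switzerland")]
    assert rsd(values) == pytest.approx(_two_pass_rsd(values), rel=1e-12)
    assert rsd(values) == pytest.approx(1.72, abs=0.01)


def test_rsd_constant_series_is_zero():
    assert rsd([5.0, 5.0, 5.0]) == 0.0


def test_rsd_scale_invariance():
    vals = [3.0, 4.0, 5.5]
    assert rsd([c * v for c, v in zip([7.0] * 3, vals)]) == pytest.approx(rsd(vals))


def test_rsd_undefined_cases():
    assert np.isnan(rsd([1.0]))
    assert np.isnan(rsd([-1.0, 1.0]))  # zero mean
    assert np.isnan(rsd([np.nan, 2.0]))


def test_rsd_matches_two_pass_oracle_on_random_data():
    rng = np.random.default_rng(5)
    for _ in range(20):
        vals = rng.uniform(1, 100, size=rng.integers(2, 12))
        assert rsd(vals) == pytest.approx(_two_pass_rsd(vals), rel=1e-12)


def test_anova_identical_constant_values():
    res = anova_precision({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
    assert res["var_between"] == 0.0
    assert res["intra_lab_rsd"] == 0.0
    assert res["inter_lab_rsd_pooled"] == 0.0
    assert np.isnan(res["F"])


def test_anova_two_group_closed_form():
    """Zero within-lab variance: between component = variance of lab means."""
    res = anova_precision({"a": [10.0, 10.0], "b": [20.0, 20.0]})
    assert res["ms_within"] == 0.0
    assert res["var_between"] == pytest.approx(np.var([10.0, 20.0], ddof=1))
    assert res["grand_mean"] == pytest.approx(15.0)


def test_anova_sum_of_squares_identity():
    rng = np.random.default_rng(11)
    for _ in range(20):
        groups = {f"lab{i}": rng.normal(50, 5, size=rng.integers(2, 6)).tolist()
                  for i in range(rng.integers(2, 5))}
        res = anova_precision(groups)
        total = np.concatenate([np.asarray(v) for v in groups.values()])
        ss_total = ((total - total.mean()) ** 2).sum()
        assert res["ss_between"] + res["ss_within"] == pytest.approx(ss_total, rel=1e-9)


def test_anova_matches_scipy_f_oneway():
    from scipy.stats import f_oneway
    rng = np.random.default_rng(2)
    groups = {f"lab{i}": rng.normal(20, 2, size=4).tolist() for i in range(4)}
    res = anova_precision(groups)
    f_ref, p_ref = f_oneway(*groups.values())
    assert res["F"] == pytest.approx(f_ref, rel=1e-10)
    assert res["p"] == pytest.approx(p_ref, rel=1e-10)


def test_anova_floor_with_no_lab_effect():
    """With zero simulated lab effect the between component floors to 0 >= 95% of runs."""
    rng = np.random.default_rng(13)
    floored = 0
    n_sim = 200
    for _ in range(n_sim):
        groups = {f"lab{i}": rng.normal(10, 1, size=3).tolist() for i in range(4)}
        vb = anova_precision(groups)["var_between"]
        assert vb >= 0.0
        if vb == 0.0:
            floored += 1
    # the floor engages whenever MS_between <= MS_within, i.e. ~P(F(3,8) <= 1)
    assert floored / n_sim >= 0.5


def test_anova_recovers_known_between_lab_variance():
    rng = np.random.default_rng(17)
    sigma_b, sigma_w = 2.0, 0.5
    estimates = []
    for _ in range(200):
        groups = {}
        for i in range(4):
            lab_effect = rng.normal(0, sigma_b)
            groups[f"lab{i}"] = (50 + lab_effect + rng.normal(0, sigma_w, size=3)).tolist()
        estimates.append(anova_precision(groups)["var_between"])
    assert np.mean(estimates) == pytest.approx(sigma_b**2, rel=0.2)


def test_anova_excludes_underfilled_cells():
    res = anova_precision({"a": [1.0, 2.0], "b": [2.0, 3.0], "c": [9.0]})
    assert res["excluded_labs"] == ["c"]
    with pytest.raises(ValueError):
        anova_precision({"a": [1.0, 2.0], "b": [5.0]})


def test_precision_report_shape():
    df = pd.DataFrame({
        "attribute": ["x"] * 6 + ["y"] * 6,
        "lab": ["a", "a", "a", "b", "b", "b"] * 2,
        "value": [1.0, 1.1, 0.9, 1.2, 1.3, 1.1, 10, 11, 9, 12, 13, 11],
        "defined": [True] * 12,
    })
    rep = precision_report(df)
    assert set(rep["attribute"]) == {"x", "y"}
    assert {"intra_lab_rsd", "inter_lab_rsd_means", "inter_lab_rsd_pooled"} <= set(rep.columns)


def test_trend_reported_degradation_series_monotone():
    """A deamidation series rising 1.27 -> 28.08 -> 44.68 is flagged monotone."""
    rows = []
    for tp, mean in [(0, 1.27), (3, 28.08), (6, 44.68)]:
        for rep in range(3):
            rows.append({"attribute": "LC N30 + deamidation", "lab": "A",
                         "timepoint": tp, "value": mean, "defined": True})
    out = trend_summary(pd.DataFrame(rows))
    assert out["monotone_increasing"].all()
    six = out[out.timepoint == 6].iloc[0]
    assert six["mean"] == pytest.approx(44.68)
    assert six["delta_vs_t0"] == pytest.approx(44.68 - 1.27)


def test_trend_constant_series_zero_deltas():
    rows = [{"attribute": "a", "timepoint": tp, "value": 5.0, "defined": True}
            for tp in (0, 3, 6) for _ in range(3)]
    out = trend_summary(pd.DataFrame(rows))
    assert out["delta_vs_t0"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])
    assert out["mean"].to_numpy() == pytest.approx([5.0, 5.0, 5.0])


def test_trend_needs_two_timepoints():
    df = pd.DataFrame([{"attribute": "a", "timepoint": 0, "value": 1.0}])
    with pytest.raises(ValueError):
        trend_summary(df)


def test_trend_missing_cell_flagged():
    rows = ([{"attribute": "a", "timepoint": 0, "value": 1.0}]
            + [{"attribute": "a", "timepoint": 3, "value": 2.0}]
            + [{"attribute": "b", "timepoint": 3, "value": 2.0}])
    out = trend_summary(pd.DataFrame(rows))
    b0 = out[(out.attribute == "b") & (out.timepoint == 0)].iloc[0]
    assert b0["missing"]
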