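"""XIC extraction, peak detection and component quantitation."""
from __future__ import annotations

import numpy as np
import pytest

from mampep.components import ComponentEntry
from mampep.msio import Run
from mampep.quant import (
    XICTrace,
    detect_peak,
    estimate_rt_shift,
    extract_xic,
    quantify_components,
)
from mampep.simulate import ScenarioConfig, make_ground_truth, predict_rt, simulate_run


def _run_with(rows):
    """rows: list of (rt, [(mz, intensity), ...])"""
    return Run(
        rt_minutes=np.array([r[0] for r in rows], dtype=float),
        mz_arrays=[np.array([p[0] for p in r[1]]) for r in rows],
        intensity_arrays=[np.array([p[1] for p in r[1]]) for r in rows],
    )


def test_xic_captures_exact_match():
    run = _run_with([(1.0, [(500.0, 42.0)]), (2.0, [])])
    trace = extract_xic(run, 500.0, ppm=0.1)
    assert trace.intensity == pytest.approx([42.0, 0.0])


def test_xic_ppm_boundary():
    mz = 500.0
    run = _run_with([(1.0, [(mz * (1 + 6e-6), 10.0)])])
    assert extract_xic(run, mz, ppm=5.0).intensity[0] == 0.0
    assert extract_xic(run, mz, ppm=7.0).intensity[0] == pytest.approx(10.0)


def test_xic_sums_cotolerant_centroids():
    mz = 800.0
    run = _run_with([(1.0, [(mz * (1 - 2e-6), 5.0), (mz * (1 + 2e-6), 7.0)])])
    assert extract_xic(run, mz, ppm=5.0).intensity[0] == pytest.approx(12.0)


def test_xic_matches_bruteforce_scan_sums(noiseless_run, table1_components):
    """Vectorised extraction equals a per-scan loop to 1e-9 relative."""
    comp = table1_components[0]
    mz = comp.form().mz(comp.charges[0])
    trace = extract_xic(noiseless_run, mz, 5.0)
    tol = mz * 5e-6
    for i in np.flatnonzero(trace.intensity)[:50]:
        mask = np.abs(noiseless_run.mz_arrays[i] - mz) <= tol
        brute = noiseless_run.intensity_arrays[i][mask].sum()
        assert trace.intensity[i] == pytest.approx(brute, rel=1e-9)


def _gaussian_trace(apex_rt=10.0, sigma=0.15, amp=1e5, dt=1 / 60.0, span=3.0):
    rt = np.arange(apex_rt - span, apex_rt + span, dt)
    y = amp * np.exp(-((rt - apex_rt) ** 2) / (2 * sigma**2))
    return XICTrace(rt_minutes=rt, intensity=y, mz=500.0, ppm=5.0)


def test_clean_gaussian_apex_and_area():
    sigma, amp = 0.15, 1e5
    trace = _gaussian_trace(sigma=sigma, amp=amp)
    peak = detect_peak(trace, expected_rt=10.0, window=1.5)
    assert peak is not None
    assert abs(peak.apex_rt - 10.0) <= 1 / 60.0
    analytic = amp * sigma * np.sqrt(2 * np.pi) * 60.0
    assert peak.area == pytest.approx(analytic, rel=0.01)


def test_flat_trace_not_found():
    rt = np.arange(0, 5, 1 / 60.0)
    trace = XICTrace(rt_minutes=rt, intensity=np.zeros_like(rt), mz=500.0, ppm=5.0)
    assert detect_peak(trace, expected_rt=2.5, window=1.0) is None


def test_equal_peaks_tie_break_to_nearer():
    rt = np.arange(8.0, 12.0, 1 / 60.0)
    y = (1e5 * np.exp(-((rt - 9.4) ** 2) / (2 * 0.1**2))
         + 1e5 * np.exp(-((rt - 10.5) ** 2) / (2 * 0.1**2)))
    trace = XICTrace(rt_minutes=rt, intensity=y, mz=500.0, ppm=5.0)
    peak = detect_peak(trace, expected_rt=10.0, window=1.0)
    assert peak is not None
    assert peak.apex_rt == pytest.approx(10.5, abs=0.05)


def test_window_validation():
    trace = _gaussian_trace()
    with pytest.raises(ValueError):
        detect_peak(trace, 10.0, window=0.0)
    with pytest.raises(ValueError):
        extract_xic(_run_with([(1.0, [])]), 500.0, ppm=0.0)


def test_area_linearity(noiseless_run, table1_components, noiseless_quant):
    """Doubling all intensities doubles every component area exactly."""
    doubled = Run(rt_minutes=noiseless_run.rt_minutes.copy(),
                  mz_arrays=[a.copy() for a in noiseless_run.mz_arrays],
                  intensity_arrays=[2.0 * a for a in noiseless_run.intensity_arrays],
                  metadata=noiseless_run.metadata)
    subset = table1_components[:8]
    base = quantify_components(noiseless_run, subset).components
    twice = quantify_components(doubled, subset).components
    assert np.allclose(twice["area"].to_numpy(), 2.0 * base["area"].to_numpy(), rtol=1e-12)


def test_tolerance_monotonicity(noiseless_run, table1_components):
    """Widening the ppm window can only grow a component's area."""
    subset = table1_components[:10]
    a5 = quantify_components(noiseless_run, subset, ppm=5.0).components["area"]
    a7 = quantify_components(noiseless_run, subset, ppm=7.0).components["area"]
    assert np.all(a7.to_numpy() >= a5.to_numpy() - 1e-9)


def test_absent_component_reported_not_found(noiseless_run):
    ghost = ComponentEntry(sequence="LLMYISR", charges=(2,), expected_rt_min=40.0)
    df = quantify_components(noiseless_run, [ghost]).components
    assert not df.iloc[0]["found"]
    assert df.iloc[0]["area"] == 0.0


def test_summed_area_equals_per_charge_sum(noiseless_quant):
    per_charge = noiseless_quant.per_charge.groupby("component_id")["area"].sum()
    for _, row in noiseless_quant.components.iterrows():
        if row["found"]:
            assert row["area"] == pytest.approx(per_charge[row["component_id"]], rel=1e-12)


def test_rt_shift_estimation_recovers_drift(table1_truth, table1_components):
    scenario = ScenarioConfig(seed=6, noise_cv=0.0, labs=2, rt_drift_min=1.9,
                              replicates=1)
    run = simulate_run(table1_truth, table1_components, scenario, lab=1)
    landmarks = [c for c in table1_components if not c.is_modified][:8]
    shift = estimate_rt_shift(run, landmarks)
    assert shift == pytest.approx(1.9, abs=0.05)


def test_rt_shift_zero_drift(noiseless_run, table1_components):
    landmarks = [c for c in table1_components if not c.is_modified][:8]
    assert abs(estimate_rt_shift(noiseless_run, landmarks)) <= 1 / 60.0


def test_rt_shift_needs_three_landmarks(noiseless_run, table1_components):
    with pytest.raises(ValueError, match="3 landmark"):
        estimate_rt_shift(noiseless_run, table1_components[:2])


def test_rt_shift_all_landmarks_missing(noiseless_run):
    ghosts = [ComponentEntry(sequence=s, charges=(2,), expected_rt_min=40.0)
              for s in ("LLMYISR", "KGNYGNYGK", "ASGYTFTSYWMQWVR")]
    with pytest.raises(ValueError, match="manually"):
        estimate_rt_shift(noiseless_run, ghosts)


def test_quantified_areas_match_trace_integral_oracle():
    """On a tiny run, the reported area equals integrating the oracle trace."""
    truth = make_ground_truth("stability_table2:mAb1_HC:M252:0:A")
    comp = ComponentEntry(sequence="DTLMISR", charges=(2,),
                          expected_rt_min=predict_rt("DTLMISR"))
    run = simulate_run(truth, [comp], ScenarioConfig(seed=9, noise_cv=0.0))
    result = quantify_components(run, [comp], envelope_correct=False)
    mz = comp.form().mz(2)
    tol = mz * 5e-6
    oracle_trace = np.array([
        run.intensity_arrays[i][np.abs(run.mz_arrays[i] - mz) <= tol].sum()
        for i in range(run.n_scans)])
    peak = detect_peak(XICTrace(run.rt_minutes, oracle_trace, mz, 5.0),
                       comp.expected_rt_min, comp.rt_window_min)
    assert result.components.iloc[0]["area"] == pytest.approx(peak.area, rel=1e-9)
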