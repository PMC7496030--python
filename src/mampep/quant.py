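"""Targeted MS1 quantitation: XICs at ppm tolerance, peak detection, areas.

The extraction tolerance defaults to +/-5 ppm on m/z. Peak detection inside
the component's RT window follows a documented reimplementation of an
ICIS-style detector: light smoothing, a low-decile baseline, a MAD noise
estimate, candidate apexes above baseline + k*noise, the candidate closest to
the expected RT, and bounds extended to the first valley or baseline crossing.
Areas are trapezoidal integrals in intensity*seconds.

XICs target the monoisotopic isotopologue per charge (optionally summing
further isotopologues); areas are divided by the theoretical abundance share
of the targeted isotopologues so that a form's summed area estimates its
total envelope signal independent of elemental composition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import isotope_envelope, mz_for_charge
from .components import ComponentEntry
from .constants import ISOTOPE_SPACING
from .msio import Run

DEFAULT_PPM = 5.0


@dataclass(frozen=True)
class XICTrace:
    rt_minutes: np.ndarray
    intensity: np.ndarray
    mz: float
    ppm: float


@dataclass(frozen=True)
class ChromPeak:
    apex_rt: float
    left_rt: float
    right_rt: float
    area: float  # intensity * seconds
    height: float
    snr: float


def extract_xic(run: Run, mz: float, ppm: float = DEFAULT_PPM) -> XICTrace:
    """Per-scan summed intensity of centroids within |obs - mz|/mz*1e6 <= ppm."""
    if ppm <= 0:
        raise ValueError("ppm tolerance must be > 0")
    flat_mz, flat_int, flat_scan = run._flat
    tol = mz * ppm * 1e-6
    lo = np.searchsorted(flat_mz, mz - tol, side="left")
    hi = np.searchsorted(flat_mz, mz + tol, side="right")
    trace = np.zeros(run.n_scans)
    if hi > lo:
        np.add.at(trace, flat_scan[lo:hi], flat_int[lo:hi])
    return XICTrace(rt_minutes=run.rt_minutes, intensity=trace, mz=mz, ppm=ppm)


def _moving_mean(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or y.size < width:
        return y.astype(float)
    kernel = np.ones(width) / width
    smoothed = np.convolve(y, kernel, mode="same")
    # fix edge shrinkage: renormalise by the effective kernel mass
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    return smoothed / norm


def _extend_bound(y: np.ndarray, apex: int, step: int, baseline: float,
                  rise_tol: float) -> int:
    """Walk from the apex to the first valley or baseline crossing.

    The bound is the lowest point passed before the trace either crosses the
    baseline or rises persistently (by more than ``rise_tol`` above the
    running minimum — i.e. a neighbouring peak starts). Tolerating small
    upticks keeps noisy single peaks integrated in full.
    """
    i = apex
    best = apex
    best_val = y[apex]
    while 0 <= i + step < y.size:
        i += step
        if y[i] < best_val:
            best, best_val = i, y[i]
        if y[i] <= baseline:
            return i
        if y[i] - best_val > rise_tol:
            break
    return best


def detect_peak(trace: XICTrace, expected_rt: float, window: float,
                smooth_points: int = 3, snr_k: float = 3.0) -> ChromPeak | None:
    """Find and integrate the chromatographic peak nearest the expected RT.

    Returns ``None`` when no candidate apex rises above baseline + k*noise
    within ``[expected_rt +/- window]`` (not-found is a value, not an error).
    """
    if window <= 0:
        raise ValueError("RT window must be > 0")
    rt, raw = trace.rt_minutes, trace.intensity
    sel = np.flatnonzero(np.abs(rt - expected_rt) <= window)
    if sel.size < 3:
        return None
    w_rt = rt[sel]
    w_raw = raw[sel]
    y = _moving_mean(w_raw, smooth_points)
    n_low = max(1, y.size // 10)
    baseline = float(np.median(np.sort(y)[:n_low]))
    noise = float(np.median(np.abs(y - np.median(y))))
    threshold = baseline + snr_k * noise
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1])
    cands = interior[is_max & (y[interior] > threshold) & (y[interior] > baseline)]
    if cands.size == 0:
        return None
    dist = np.abs(w_rt[cands] - expected_rt)
    best = np.lexsort((-y[cands], dist))[0]  # nearest to expected; ties -> taller
    apex = int(cands[best])
    rise_tol = max(snr_k * noise, 0.05 * (y[apex] - baseline))
    left = _extend_bound(y, apex, -1, baseline, rise_tol)
    right = _extend_bound(y, apex, +1, baseline, rise_tol)
    area = float(np.trapezoid(w_raw[left:right + 1], w_rt[left:right + 1] * 60.0))
    height = float(w_raw[left:right + 1].max())
    snr = float((y[apex] - baseline) / noise) if noise > 0 else float("inf")
    return ChromPeak(apex_rt=float(w_rt[apex]), left_rt=float(w_rt[left]),
                     right_rt=float(w_rt[right]), area=area, height=height, snr=snr)


@dataclass
class QuantResult:
    """Per-run component areas: a per-charge table and a per-component rollup.

    Components whose peak is missing at every charge are recorded with
    ``found=False`` and zero area — never silently dropped.
    """

    per_charge: pd.DataFrame  # component_id, charge, area, apex_rt, found
    components: pd.DataFrame  # component_id + metadata, summed area, found

    def area(self, component_id: str) -> float:
        row = self.components.loc[self.components.component_id == component_id]
        if row.empty:
            raise KeyError(component_id)
        return float(row.iloc[0]["area"])


def quantify_components(run: Run, components: list[ComponentEntry],
                        ppm: float = DEFAULT_PPM, rt_shift: float = 0.0,
                        isotope_sum: int = 1, envelope_correct: bool = True,
                        smooth_points: int = 3, snr_k: float = 3.0) -> QuantResult:
    """Quantify every listed component in one run.

    Per component and charge, the XIC of the first ``isotope_sum``
    isotopologues is extracted at ``ppm`` tolerance and the peak nearest
    ``expected_rt + rt_shift`` integrated. With ``envelope_correct`` the area
    is divided by the targeted isotopologues' theoretical abundance share.
    """
    charge_rows = []
    comp_rows = []
    for comp in components:
        form = comp.form()
        mass = form.mass
        expected = comp.expected_rt_min + rt_shift
        if envelope_correct:
            if isotope_sum == 1:
                share = form.composition.monoisotopic_fraction()
            else:
                env = isotope_envelope(form.composition, isotope_sum, normalize=False)
                share = float(env.abundances.sum())
        else:
            share = 1.0
        total_area = 0.0
        apex_rts = []
        any_found = False
        for z in comp.charges:
            area_z = 0.0
            apex_z = np.nan
            found_z = False
            for j in range(isotope_sum):
                mz = mz_for_charge(mass + j * ISOTOPE_SPACING, z)
                trace = extract_xic(run, mz, ppm)
                peak = detect_peak(trace, expected, comp.rt_window_min,
                                   smooth_points=smooth_points, snr_k=snr_k)
                if peak is not None:
                    area_z += peak.area
                    found_z = True
                    if j == 0:
                        apex_z = peak.apex_rt
            area_z /= share
            charge_rows.append({
                "component_id": comp.component_id, "charge": z,
                "area": area_z, "apex_rt": apex_z, "found": found_z,
            })
            total_area += area_z
            if found_z:
                any_found = True
                if np.isfinite(apex_z):
                    apex_rts.append(apex_z)
        comp_rows.append({
            "component_id": comp.component_id, "sequence": comp.sequence,
            "modification": comp.modification, "site_label": comp.site_label,
            "attribute": comp.attribute, "chain_id": comp.chain_id,
            "start": comp.start, "end": comp.end,
            "missed_cleavages": comp.missed_cleavages, "specific": comp.specific,
            "include_in_rollup": comp.include_in_rollup,
            "area": total_area if any_found else 0.0,
            "apex_rt": float(np.mean(apex_rts)) if apex_rts else np.nan,
            "found": any_found,
        })
    meta = run.metadata
    comp_df = pd.DataFrame(comp_rows)
    comp_df.insert(0, "lab", meta.lab)
    comp_df.insert(1, "replicate", meta.replicate)
    comp_df.insert(2, "sample", meta.sample)
    comp_df.insert(3, "timepoint", meta.timepoint)
    return QuantResult(per_charge=pd.DataFrame(charge_rows), components=comp_df)


def estimate_rt_shift(run: Run, landmarks: list[ComponentEntry],
                      ppm: float = DEFAULT_PPM, search_window: float = 3.0) -> float:
    """Median observed-minus-expected RT over landmark components.

    Landmarks are searched with a wide window (default +/-3 min) to absorb
    inter-laboratory drift. Requires at least 3 found landmarks, otherwise a
    ValueError advises updating the workbook retention times manually.
    """
    if len(landmarks) < 3:
        raise ValueError("need at least 3 landmark components to estimate RT drift")
    deltas = []
    for comp in landmarks:
        form = comp.form()
        z = comp.charges[0]
        trace = extract_xic(run, mz_for_charge(form.mass, z), ppm)
        peak = detect_peak(trace, comp.expected_rt_min, search_window)
        if peak is not None:
            deltas.append(peak.apex_rt - comp.expected_rt_min)
    if len(deltas) < 3:
        raise ValueError(
            "fewer than 3 landmark peptides found; update workbook retention times manually")
    return float(np.median(deltas))
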