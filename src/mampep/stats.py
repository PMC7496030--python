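"""Intra-/inter-laboratory precision and degradation-trend summaries.

Precision follows standard analytical-chemistry usage: RSD = 100 * sample
(n-1) standard deviation / mean; one-way ANOVA with laboratory as the factor
yields the repeatability variance (within-lab mean square) and a between-lab
variance component floored at zero. Inter-laboratory RSD is reported in two
clearly labelled forms: pooled (within + between components over the grand
mean) and means-based (RSD of the per-lab means), the latter matching how
multi-site summaries are usually quoted.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats


def rsd(values) -> float:
    """Relative standard deviation, %: 100 * sd(n-1) / mean.

    Undefined (NaN) for fewer than two finite values or a zero mean.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def anova_precision(values_by_lab: dict[str, list[float]]) -> dict:
    """One-way ANOVA precision summary for one attribute.

    Input: per-laboratory replicate values. Cells with fewer than two usable
    replicates are excluded (and listed under ``excluded_labs``). Returns the
    grand mean, between/within mean squares, F and p, variance components
    (between floored at 0), intra-lab RSD from the within mean square, and
    inter-lab RSD in pooled and means-based forms.
    """
    usable: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for lab, vals in values_by_lab.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size >= 2:
            usable[lab] = arr
        else:
            excluded.append(lab)
    if len(usable) < 2:
        raise ValueError("ANOVA needs >= 2 laboratories with >= 2 replicates each")
    labs = sorted(usable)
    groups = [usable[lab] for lab in labs]
    n_i = np.array([g.size for g in groups], dtype=float)
    N = float(n_i.sum())
    a = len(groups)
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_between = a - 1
    df_within = int(N) - a
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    # effective per-lab n for unbalanced designs (reduces to n when balanced)
    n0 = (N - float(np.sum(n_i ** 2)) / N) / df_between
    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)
    if ms_within > 0:
        f_stat = ms_between / ms_within
        p_value = float(_scipy_stats.f.sf(f_stat, df_between, df_within))
    else:
        f_stat, p_value = float("nan"), float("nan")
    intra_rsd = 100.0 * np.sqrt(var_within) / grand if grand != 0 else float("nan")
    inter_rsd_pooled = (100.0 * np.sqrt(var_within + var_between) / grand
                        if grand != 0 else float("nan"))
    return {
        "labs": labs,
        "excluded_labs": excluded,
        "n_per_lab": {lab: int(usable[lab].size) for lab in labs},
        "lab_means": {lab: float(usable[lab].mean()) for lab in labs},
        "lab_rsd": {lab: rsd(usable[lab]) for lab in labs},
        "grand_mean": grand,
        "ss_between": ss_between,
        "ss_within": ss_within,
        "ms_between": ms_between,
        "ms_within": ms_within,
        "F": f_stat,
        "p": p_value,
        "var_within": var_within,
        "var_between": var_between,
        "intra_lab_rsd": float(intra_rsd),
        "inter_lab_rsd_pooled": float(inter_rsd_pooled),
        "inter_lab_rsd_means": rsd(means),
    }


def precision_report(attr_df: pd.DataFrame) -> pd.DataFrame:
    """Per-attribute precision table from a tidy attribute-result frame.

    Expects columns attribute, lab, value (and optionally ``defined``);
    undefined values are dropped before grouping.
    """
    df = attr_df.copy()
    if "defined" in df.columns:
        df = df[df.defined.astype(bool)]
    rows = []
    for attribute, grp in df.groupby("attribute", sort=True):
        by_lab = {lab: sub["value"].tolist() for lab, sub in grp.groupby("lab")}
        try:
            res = anova_precision(by_lab)
        except ValueError:
            continue
        rows.append({
            "attribute": attribute,
            "grand_mean": res["grand_mean"],
            "intra_lab_rsd": res["intra_lab_rsd"],
            "inter_lab_rsd_pooled": res["inter_lab_rsd_pooled"],
            "inter_lab_rsd_means": res["inter_lab_rsd_means"],
            "ms_between": res["ms_between"],
            "ms_within": res["ms_within"],
            "F": res["F"],
            "p": res["p"],
            "var_between": res["var_between"],
            "var_within": res["var_within"],
            "n_labs": len(res["labs"]),
            "n_total": sum(res["n_per_lab"].values()),
            "excluded_labs": ";".join(res["excluded_labs"]),
        })
    return pd.DataFrame(rows)


def trend_summary(attr_df: pd.DataFrame) -> pd.DataFrame:
    """Degradation-series summary: per attribute x time point mean, RSD, delta vs t0.

    Expects columns attribute, timepoint, value (+ optional lab, defined).
    Rising attributes are flagged monotone when cell means never decrease.
    """
    df = attr_df.copy()
    if "defined" in df.columns:
        df = df[df.defined.astype(bool)]
    timepoints = sorted(df["timepoint"].unique())
    if len(timepoints) < 2:
        raise ValueError("trend summary needs >= 2 time points")
    rows = []
    for attribute, grp in df.groupby("attribute", sort=True):
        cells = {}
        for tp, sub in grp.groupby("timepoint"):
            vals = sub["value"].to_numpy(dtype=float)
            cells[tp] = (float(np.mean(vals)), rsd(vals), vals.size)
        t0 = timepoints[0]
        t0_mean = cells.get(t0, (float("nan"),))[0]
        means_series = [cells[tp][0] for tp in timepoints if tp in cells]
        monotone = bool(np.all(np.diff(means_series) >= 0)) if len(means_series) > 1 else False
        for tp in timepoints:
            if tp not in cells:
                rows.append({"attribute": attribute, "timepoint": tp, "mean": float("nan"),
                             "rsd": float("nan"), "n": 0, "delta_vs_t0": float("nan"),
                             "missing": True, "monotone_increasing": monotone})
                continue
            mean, cell_rsd, n = cells[tp]
            delta = mean - t0_mean if np.isfinite(t0_mean) else float("nan")
            rows.append({"attribute": attribute, "timepoint": tp, "mean": mean,
                         "rsd": cell_rsd, "n": n, "delta_vs_t0": delta,
                         "missing": False, "monotone_increasing": monotone})
    return pd.DataFrame(rows)
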