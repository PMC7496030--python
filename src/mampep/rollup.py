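"""Site-level attribute rollup from per-component areas.

Relative abundance of a modification is the area fraction of its modified
component set over modified + unmodified sets, summed over all charges and
all listed peptide forms (the fully-cleaved peptide and its <=1-missed-
cleavage partners). Glycoform profiles are fractions of the site total, with
the unglycosylated form a member. Undefined ratios (zero denominators) are
flagged and excluded from downstream statistics, never reported as zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .components import ComponentEntry
from .digest import ProteinChain

RUN_KEYS = ["lab", "replicate", "sample", "timepoint"]


@dataclass(frozen=True)
class AttributeDefinition:
    """Grouping of components into one quality attribute.

    ``pairwise`` mode: value = 100 * modified / (modified + reference).
    ``profile`` mode: each member is a fraction of the site total;
    ``profile_members`` maps member label -> component ids whose areas are
    combined (e.g. a glycoform on the tryptic peptide and on its missed-
    cleavage partner).
    """

    label: str
    mode: str  # pairwise | profile
    site_label: str = ""
    modified: tuple[str, ...] = ()
    reference: tuple[str, ...] = ()
    profile_members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode == "pairwise":
            if not self.modified or not self.reference:
                raise ValueError(f"{self.label}: pairwise mode needs both component sets")
        elif self.mode == "profile":
            if len(self.profile_members) < 2:
                raise ValueError(f"{self.label}: profile mode needs >= 2 members")
        else:
            raise ValueError(f"{self.label}: unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AttributeResult:
    attribute: str
    value: float  # percent; NaN when undefined
    defined: bool
    modified_area: float = 0.0
    reference_area: float = 0.0


def attribute_definitions(components: list[ComponentEntry]) -> list[AttributeDefinition]:
    """Derive attribute definitions from a workbook's site/modification labels."""
    by_site: dict[str, list[ComponentEntry]] = {}
    for c in components:
        if c.site_label and c.include_in_rollup:
            by_site.setdefault(c.site_label, []).append(c)
    defs: list[AttributeDefinition] = []
    for site, comps in by_site.items():
        glyco = any(c.modification == "unglycosylated" for c in comps)
        if glyco:
            members: dict[str, list[str]] = {}
            for c in comps:
                name = c.modification if c.modification else "unglycosylated"
                members.setdefault(name, []).append(c.component_id)
            defs.append(AttributeDefinition(
                label=site, mode="profile", site_label=site,
                profile_members={k: tuple(v) for k, v in members.items()}))
        else:
            reference = tuple(c.component_id for c in comps if not c.is_modified)
            mods = sorted({c.modification for c in comps if c.is_modified})
            for mod in mods:
                modified = tuple(c.component_id for c in comps if c.modification == mod)
                defs.append(AttributeDefinition(
                    label=f"{site} + {mod}", mode="pairwise", site_label=site,
                    modified=modified, reference=reference))
    return defs


def _area_sum(comp_df: pd.DataFrame, ids: tuple[str, ...]) -> float:
    return float(comp_df.loc[comp_df.component_id.isin(ids), "area"].sum())


def relative_abundance(comp_df: pd.DataFrame, attr: AttributeDefinition) -> AttributeResult:
    """Pairwise relative abundance (%) of one attribute in one run."""
    if attr.mode != "pairwise":
        raise ValueError(f"{attr.label}: relative_abundance requires pairwise mode")
    mod = _area_sum(comp_df, attr.modified)
    ref = _area_sum(comp_df, attr.reference)
    total = mod + ref
    if total <= 0:
        return AttributeResult(attr.label, float("nan"), False, mod, ref)
    return AttributeResult(attr.label, 100.0 * mod / total, True, mod, ref)


def glycan_profile(comp_df: pd.DataFrame, attr: AttributeDefinition) -> list[AttributeResult]:
    """Glycoform profile (%) at one site in one run; members sum to 100."""
    if attr.mode != "profile":
        raise ValueError(f"{attr.label}: glycan_profile requires profile mode")
    areas = {name: _area_sum(comp_df, ids) for name, ids in attr.profile_members.items()}
    total = sum(areas.values())
    out = []
    for name, area in areas.items():
        label = f"{attr.site_label} + {name}"
        if total <= 0:
            out.append(AttributeResult(label, float("nan"), False, area, total))
        else:
            out.append(AttributeResult(label, 100.0 * area / total, True, area, total))
    return out


def rollup_attributes(comp_df: pd.DataFrame,
                      attrs: list[AttributeDefinition]) -> pd.DataFrame:
    """Tidy per-run attribute table over one or many quantified runs."""
    rows = []
    for keys, run_df in comp_df.groupby(RUN_KEYS, sort=True):
        meta = dict(zip(RUN_KEYS, keys))
        for attr in attrs:
            results = ([relative_abundance(run_df, attr)] if attr.mode == "pairwise"
                       else glycan_profile(run_df, attr))
            for res in results:
                rows.append({**meta, "attribute": res.attribute, "value": res.value,
                             "defined": res.defined,
                             "modified_area": res.modified_area,
                             "reference_area": res.reference_area})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ coverage mapping

#: recovery classes, percent of the most-covered residue's MS1 area
_COVERAGE_BINS = ((50.0, ">50"), (20.0, ">20"), (10.0, ">10"),
                  (5.0, ">5"), (2.0, ">2"), (1.0, ">1"))


@dataclass
class CoverageMap:
    chain_id: str
    covered: np.ndarray  # bool per residue
    residue_area: np.ndarray
    recovery_class: list[str]

    @property
    def coverage_percent(self) -> float:
        return 100.0 * float(self.covered.sum()) / self.covered.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain_id": self.chain_id,
            "position": np.arange(1, self.covered.size + 1),
            "covered": self.covered,
            "area": self.residue_area,
            "recovery_class": self.recovery_class,
        })


def coverage_map(comp_df: pd.DataFrame, chain: ProteinChain) -> CoverageMap:
    """Per-residue coverage and recovery class from identified peptide areas.

    A residue is covered iff at least one found peptide spans it; its class
    is the summed area of spanning peptides relative to the chain's most-
    covered residue, binned by the standard recovery thresholds.
    """
    n = len(chain)
    area = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    rows = comp_df[(comp_df.chain_id == chain.id) & comp_df.found]
    for _, r in rows.iterrows():
        s, e = int(r["start"]), int(r["end"])
        if s < 1 or e > n:
            raise ValueError(f"peptide {r['component_id']} outside chain {chain.id}")
        covered[s - 1:e] = True
        area[s - 1:e] += float(r["area"])
    ref = area.max() if area.max() > 0 else 1.0
    classes = []
    for a in area:
        pct = 100.0 * a / ref
        for threshold, label in _COVERAGE_BINS:
            if pct > threshold:
                classes.append(label)
                break
        else:
            classes.append("<=1")
    return CoverageMap(chain_id=chain.id, covered=covered, residue_area=area,
                       recovery_class=classes)


# ------------------------------------------------------------ digestion QC metrics

def missed_cleavage_rate(comp_df: pd.DataFrame) -> float:
    """Area % carried by specific peptides with >= 1 missed cleavage."""
    spec = comp_df[comp_df.specific]
    denom = float(spec["area"].sum())
    if denom <= 0:
        return float("nan")
    missed = float(spec.loc[spec.missed_cleavages >= 1, "area"].sum())
    return 100.0 * missed / denom


def nonspecific_rate(comp_df: pd.DataFrame) -> float:
    """Area % carried by semi-/non-specific peptides over all identified peptides."""
    denom = float(comp_df["area"].sum())
    if denom <= 0:
        return float("nan")
    nonspec = float(comp_df.loc[~comp_df.specific.astype(bool), "area"].sum())
    return 100.0 * nonspec / denom


# ------------------------------------------------------------------- Venn membership

def venn_membership(lab_peptides: dict[str, list[tuple[str, str, float]]],
                    ppm: float = 5.0) -> dict[frozenset, int]:
    """Region counts of the cross-laboratory peptide Venn diagram.

    Peptides are matched by (sequence, modification) identity with observed
    masses agreeing within ``ppm`` of the cross-lab median; charge state is
    ignored. Supports 2-4 laboratories.
    """
    if not 2 <= len(lab_peptides) <= 4:
        raise ValueError("Venn membership supports 2 to 4 laboratories")
    observations: dict[tuple[str, str], dict[str, float]] = {}
    for lab, peptides in lab_peptides.items():
        for seq, mod, mass in peptides:
            observations.setdefault((seq, mod), {})[lab] = mass
    regions: dict[frozenset, int] = {}
    for key, by_lab in observations.items():
        ref = float(np.median(list(by_lab.values())))
        labs = frozenset(lab for lab, m in by_lab.items()
                         if abs(m - ref) / ref * 1e6 <= ppm)
        if labs:
            regions[labs] = regions.get(labs, 0) + 1
        # labs whose observed mass disagrees with the consensus count alone
        for lab, m in by_lab.items():
            if lab not in labs:
                solo = frozenset({lab})
                regions[solo] = regions.get(solo, 0) + 1
    return regions


def write_coverage_csv(maps: list[CoverageMap], path: str | Path) -> Path:
    path = Path(path)
    pd.concat([m.to_frame() for m in maps], ignore_index=True).to_csv(path, index=False)
    return path
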