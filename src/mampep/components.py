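"""The target peptide workbook: components driving targeted MS1 quantitation.

A component is one peptide form (sequence x modification x site) with its
charge states, expected retention time and RT window. Components are the only
species the quantifier looks for — untargeted features, adducted species and
unknown modifications are excluded at this table level.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .digest import Peptide, STANDARD_RESIDUES
from .modifications import (
    PeptideForm,
    apply_modification,
    get_modification,
    modification_names,
    unmodified_form,
)

#: modification column values that denote the chemically unmodified peptide
UNMODIFIED_NAMES = ("", "unmodified", "unglycosylated")

CSV_COLUMNS = [
    "component_id", "sequence", "modification", "site_label", "mod_site",
    "attribute", "charges", "expected_rt_min", "rt_window_min",
    "include_in_rollup", "missed_cleavages", "specific", "chain_id", "start", "end",
]


@dataclass(frozen=True)
class ComponentEntry:
    sequence: str
    modification: str = ""  # '' / 'unmodified' / 'unglycosylated' / a registry name
    site_label: str = ""
    mod_site: str = ""  # 1-based chain coordinate(s), ';'-separated if ambiguous
    attribute: str = ""
    charges: tuple[int, ...] = (2,)
    expected_rt_min: float = 0.0
    rt_window_min: float = 1.5
    include_in_rollup: bool = True
    missed_cleavages: int = 0
    specific: bool = True
    chain_id: str = "peptide"
    start: int = 1
    end: int = 0

    def __post_init__(self) -> None:
        if not self.charges or any(z < 1 for z in self.charges):
            raise ValueError(f"{self.sequence}: charges must be >= 1")
        if self.rt_window_min <= 0:
            raise ValueError(f"{self.sequence}: RT window half-width must be > 0")
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)

    @property
    def component_id(self) -> str:
        mod = self.modification if self.modification else "unmodified"
        return f"{self.sequence}|{mod}|{self.site_label}"

    @property
    def is_modified(self) -> bool:
        return self.modification not in UNMODIFIED_NAMES

    def peptide(self) -> Peptide:
        return Peptide(chain_id=self.chain_id, start=self.start, end=self.end,
                       sequence=self.sequence, missed_cleavages=self.missed_cleavages,
                       specific=self.specific)

    def sites(self) -> frozenset[int]:
        if not self.mod_site:
            raise ValueError(f"{self.component_id}: no modification site recorded")
        return frozenset(int(s) for s in str(self.mod_site).split(";"))

    def form(self) -> PeptideForm:
        pep = self.peptide()
        if not self.is_modified:
            return unmodified_form(pep, self.site_label)
        sites = self.sites()
        anchor = min(s for s in sites if pep.spans(s))
        residue = self.sequence[anchor - self.start]
        spec = get_modification(self.modification, residue)
        site = anchor if len(sites) == 1 else sites
        return apply_modification(pep, spec.at(site), self.site_label)


def components_to_frame(components: list[ComponentEntry]) -> pd.DataFrame:
    rows = []
    for c in components:
        rows.append({
            "component_id": c.component_id, "sequence": c.sequence,
            "modification": c.modification, "site_label": c.site_label,
            "mod_site": c.mod_site, "attribute": c.attribute,
            "charges": ";".join(str(z) for z in c.charges),
            "expected_rt_min": c.expected_rt_min, "rt_window_min": c.rt_window_min,
            "include_in_rollup": c.include_in_rollup,
            "missed_cleavages": c.missed_cleavages, "specific": c.specific,
            "chain_id": c.chain_id, "start": c.start, "end": c.end,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_component_csv(components: list[ComponentEntry], path: str | Path) -> Path:
    path = Path(path)
    components_to_frame(components).to_csv(path, index=False)
    return path


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes")


def read_component_csv(path: str | Path) -> list[ComponentEntry]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(ComponentEntry(
            sequence=str(r["sequence"]),
            modification=str(r.get("modification", "")),
            site_label=str(r.get("site_label", "")),
            mod_site=str(r.get("mod_site", "")),
            attribute=str(r.get("attribute", "")),
            charges=tuple(int(z) for z in str(r["charges"]).split(";") if z),
            expected_rt_min=float(r["expected_rt_min"]),
            rt_window_min=float(r.get("rt_window_min", 1.5)),
            include_in_rollup=_parse_bool(r.get("include_in_rollup", True)),
            missed_cleavages=int(r.get("missed_cleavages", 0)),
            specific=_parse_bool(r.get("specific", True)),
            chain_id=str(r.get("chain_id", "peptide")),
            start=int(r.get("start", 1)),
            end=int(r.get("end", 0)),
        ))
    return out


_ADDUCT_TOKENS = ("adduct", "na+", "k+", "sodium", "potassium")


def validate_component_table(components: list[ComponentEntry], max_missed: int = 1,
                             gradient_min: float = 120.0):
    """Apply the workbook inclusion rules; returns (accepted, diagnostics).

    Rejected: entries above the missed-cleavage cap, Na+/K+ adducts, unknown
    modification names, invalid residues, expected RT outside the gradient.
    Diagnostics are (component_id, rule, message) triples; nothing is fatal.
    """
    known = modification_names()
    accepted, errors = [], []
    for c in components:
        problems = []
        mod_lower = c.modification.lower()
        if any(tok in mod_lower for tok in _ADDUCT_TOKENS):
            problems.append(("adduct_exclusion", f"adducted species {c.modification!r} excluded"))
        elif c.is_modified and c.modification not in known:
            problems.append(("unknown_modification", f"unknown modification {c.modification!r}"))
        if c.missed_cleavages > max_missed:
            problems.append(("missed_cleavage_cap",
                             f"{c.missed_cleavages} missed cleavages exceeds cap {max_missed}"))
        bad = [aa for aa in c.sequence if aa not in STANDARD_RESIDUES]
        if bad:
            problems.append(("invalid_sequence", f"non-standard residues {bad}"))
        if not (0.0 <= c.expected_rt_min <= gradient_min):
            problems.append(("rt_out_of_gradient",
                             f"expected RT {c.expected_rt_min} outside 0..{gradient_min} min"))
        if problems:
            errors.extend((c.component_id, rule, msg) for rule, msg in problems)
        else:
            accepted.append(c)
    return accepted, errors
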