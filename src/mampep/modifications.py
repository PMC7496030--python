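"""Peptide modifications: chemical degradations and N-glycans.

A modified peptide form is a :class:`Peptide` plus a :class:`ModificationSpec`.
Chemical modifications carry per-element composition deltas (e.g. deamidation
is -H -N +O, +0.98402 Da); glycans carry a monosaccharide composition whose
elemental sum is added to the peptide. Isobaric species (Asp isomerisation,
the A2Ga1G1F/A2G2F glycan pair) have a zero mass delta relative to their
partner and are marked ``rt_resolved``: they are distinguishable only by
retention time.

Sites are 1-based chain coordinates. Ambiguous sites (MS1 data cannot localise
a deamidation between nearby asparagines) are a set of candidate coordinates
and are reported at peptide level, never split between residues.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

from .chem import ElementalComposition, mz_for_charge, peptide_composition
from .constants import glycan_rows, modification_rows
from .digest import Peptide

#: Elemental compositions of glycosyl residues (dehydrated, as bonded).
_GLYCOSYL = {
    "Hex": ElementalComposition(C=6, H=10, O=5),
    "HexNAc": ElementalComposition(C=8, H=13, N=1, O=5),
    "Fuc": ElementalComposition(C=6, H=10, O=4),
    "NeuAc": ElementalComposition(C=11, H=17, N=1, O=8),
}


@dataclass(frozen=True)
class GlycanComposition:
    Hex: int = 0
    HexNAc: int = 0
    Fuc: int = 0
    NeuAc: int = 0

    def __post_init__(self) -> None:
        counts = (self.Hex, self.HexNAc, self.Fuc, self.NeuAc)
        if any(c < 0 for c in counts):
            raise ValueError("negative monosaccharide count")
        if sum(counts) == 0:
            raise ValueError("glycan needs at least one monosaccharide")

    def elemental(self) -> ElementalComposition:
        comp = ElementalComposition()
        for name, unit in _GLYCOSYL.items():
            comp = comp + getattr(self, name) * unit
        return comp

    @property
    def mass(self) -> float:
        return self.elemental().mass


@dataclass(frozen=True)
class ModificationSpec:
    """One modification: either an elemental delta or a glycan composition."""

    name: str
    target_residues: frozenset[str]
    position: str = "any"  # any | nterm | cterm_chain
    delta_elements: tuple[int, int, int, int, int] | None = None  # C H N O S
    glycan: GlycanComposition | None = None
    site: int | frozenset[int] | None = None
    rt_resolved: bool = False
    rt_offset_min: float = 0.0

    def __post_init__(self) -> None:
        if (self.delta_elements is None) == (self.glycan is None):
            raise ValueError(f"{self.name}: exactly one of elemental delta / glycan required")
        if isinstance(self.site, frozenset) and len(self.site) < 2:
            raise ValueError("ambiguous site set needs >= 2 candidate positions")

    @property
    def delta_mass(self) -> float:
        if self.glycan is not None:
            return self.glycan.mass
        deltas = dict(zip("CHNOS", self.delta_elements))
        masses = ElementalComposition(**{k: max(v, 0) for k, v in deltas.items()}).mass
        masses -= ElementalComposition(**{k: max(-v, 0) for k, v in deltas.items()}).mass
        return masses

    def at(self, site: int | frozenset[int] | set[int]) -> "ModificationSpec":
        if isinstance(site, set):
            site = frozenset(site)
        return replace(self, site=site)

    def candidate_sites(self) -> frozenset[int]:
        if self.site is None:
            raise ValueError(f"{self.name}: site not set")
        return self.site if isinstance(self.site, frozenset) else frozenset({self.site})


@lru_cache(maxsize=None)
def _chemical_registry() -> dict[tuple[str, str], ModificationSpec]:
    reg = {}
    for r in modification_rows():
        spec = ModificationSpec(
            name=r["name"],
            target_residues=frozenset(r["targets"]),
            position=r["position"],
            delta_elements=tuple(int(r[f"d{e}"]) for e in "CHNOS"),
            rt_resolved=bool(int(r["rt_resolved"])),
            rt_offset_min=float(r["rt_offset_min"]),
        )
        for res in spec.target_residues:
            reg[(spec.name, res)] = spec
    return reg


@lru_cache(maxsize=None)
def glycan_registry() -> dict[str, ModificationSpec]:
    reg = {}
    for r in glycan_rows():
        reg[r["name"]] = ModificationSpec(
            name=r["name"],
            target_residues=frozenset("N"),
            glycan=GlycanComposition(Hex=int(r["Hex"]), HexNAc=int(r["HexNAc"]),
                                     Fuc=int(r["Fuc"]), NeuAc=int(r["NeuAc"])),
            rt_resolved=bool(int(r["rt_resolved"])),
            rt_offset_min=float(r["rt_offset_min"]),
        )
    return reg


def modification_names() -> frozenset[str]:
    names = {name for name, _ in _chemical_registry()}
    return frozenset(names | set(glycan_registry()))


def get_modification(name: str, residue: str | None = None) -> ModificationSpec:
    """Look up a modification template (site unset) by name.

    Residue-dependent chemistries (succinimide is -NH3 from Asn but -H2O from
    Asp) need ``residue`` to disambiguate.
    """
    if name in glycan_registry():
        return glycan_registry()[name]
    chem = _chemical_registry()
    matches = [spec for (n, res), spec in chem.items() if n == name]
    if not matches:
        raise KeyError(f"unknown modification {name!r}")
    if residue is not None:
        for spec in matches:
            if residue in spec.target_residues:
                return spec
        raise ValueError(f"{name} does not target residue {residue!r}")
    if len({m.delta_elements for m in matches}) > 1:
        raise ValueError(f"{name} is residue-dependent; specify the residue")
    return matches[0]


@dataclass(frozen=True)
class PeptideForm:
    """A (possibly) modified peptide species, the unit the quantifier targets."""

    peptide: Peptide
    modification: ModificationSpec | None
    site_label: str = ""

    @property
    def is_modified(self) -> bool:
        return self.modification is not None

    @property
    def rt_resolved(self) -> bool:
        return self.modification.rt_resolved if self.modification else False

    @property
    def composition(self) -> ElementalComposition:
        base = peptide_composition(self.peptide.sequence)
        mod = self.modification
        if mod is None:
            return base
        if mod.glycan is not None:
            return base + mod.glycan.elemental()
        return base.shifted(dict(zip("CHNOS", mod.delta_elements)))

    @property
    def mass(self) -> float:
        return self.composition.mass

    def mz(self, z: int) -> float:
        return mz_for_charge(self.mass, z)

    @property
    def form_id(self) -> str:
        mod = self.modification.name if self.modification else "unmodified"
        return f"{self.peptide.sequence}|{mod}|{self.site_label}"


def unmodified_form(peptide: Peptide, site_label: str = "") -> PeptideForm:
    return PeptideForm(peptide=peptide, modification=None, site_label=site_label)


def apply_modification(peptide: Peptide, mod: ModificationSpec,
                       site_label: str = "") -> PeptideForm:
    """Attach a sited modification to a peptide, validating site and residue.

    The modification site(s) are 1-based chain coordinates and must lie within
    the peptide (for an ambiguous set: intersect it). N-terminal modifications
    must sit on the first residue of the peptide; chain C-terminal ones
    (Lys clipping) on its last residue.
    """
    sites = mod.candidate_sites()
    in_peptide = sorted(s for s in sites if peptide.spans(s))
    if not in_peptide:
        raise ValueError(
            f"{mod.name}: site(s) {sorted(sites)} outside peptide "
            f"{peptide.sequence} [{peptide.start}..{peptide.end}]")
    for s in in_peptide:
        residue = peptide.sequence[s - peptide.start]
        if residue not in mod.target_residues:
            raise ValueError(
                f"{mod.name}: residue {residue!r} at position {s} not in "
                f"targets {sorted(mod.target_residues)}")
    if mod.position == "nterm" and in_peptide[0] != peptide.start:
        raise ValueError(f"{mod.name} only valid at the peptide N-terminus")
    if mod.position == "cterm_chain" and in_peptide[-1] != peptide.end:
        raise ValueError(f"{mod.name} only valid at the chain C-terminus")
    return PeptideForm(peptide=peptide, modification=mod, site_label=site_label)
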