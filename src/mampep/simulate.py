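"""Synthetic LC-MS generator: ground-truth attribute tables and MS1 runs.

The generator emulates what the vendor acquisition produced in the original
multi-site setting: centroided MS1-only runs of a tryptic mAb digest on a
105-min gradient, with isotope envelopes over the listed charge states,
Gaussian elution peaks, per-laboratory retention-time drift (labs were seen
to differ by up to ~2 min), multiplicative log-normal intensity noise, and
triplicate digests per laboratory. Ground-truth presets reproduce the printed
reference tables (the four-laboratory IgG1 attribute panel and the 40 C
degradation series) as true modified fractions, so that the downstream
pipeline can be checked for exact recovery.

Every stochastic call derives its generator from ``(seed, lab, replicate)``;
identical inputs give byte-identical peak lists.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .chem import isotope_envelope, mz_for_charge
from .components import ComponentEntry, UNMODIFIED_NAMES
from .constants import ISOTOPE_SPACING, rt_coefficients, table_rows
from .digest import ProteinChain, TRYPSIN, digest, read_fasta
from .modifications import PeptideForm, glycan_registry
from .msio import Run, RunMetadata

# --------------------------------------------------------------------------- RT model

#: affine map of the summed retention score onto the usable gradient window
_RT_LOW_MIN, _RT_HIGH_MIN = 5.0, 100.0
_SCORE_SPAN = 160.0


def predict_rt(form: PeptideForm | str) -> float:
    """Deterministic retention time (minutes) of a peptide form.

    An additive per-residue hydrophobicity score is mapped affinely onto the
    [5, 100] min window of the gradient; modifications add their fixed offset
    (deamidation slightly later, oxidation earlier, isobaric species +0.8 min
    from their partner so they are chromatographically resolvable).
    """
    if isinstance(form, str):
        sequence, offset = form, 0.0
    else:
        sequence = form.peptide.sequence
        offset = form.modification.rt_offset_min if form.modification else 0.0
    coeffs = rt_coefficients()
    score = sum(coeffs[aa] for aa in sequence)
    rt = _RT_LOW_MIN + (_RT_HIGH_MIN - _RT_LOW_MIN) * min(max(score / _SCORE_SPAN, 0.0), 1.0)
    return float(min(max(rt + offset, _RT_LOW_MIN), _RT_HIGH_MIN))


# ------------------------------------------------------------------- charge heuristics

def default_charges(sequence: str, mass: float,
                    mz_range: tuple[float, float] = (200.0, 2000.0)) -> tuple[int, ...]:
    """Charge states for the workbook: short peptides 1-2+, long 2-3+, kept in range."""
    preferred = (1, 2) if len(sequence) < 15 else (2, 3)
    charges = tuple(z for z in preferred if mz_range[0] <= mz_for_charge(mass, z) <= mz_range[1])
    if charges:
        return charges
    for z in range(1, 7):
        if mz_range[0] <= mz_for_charge(mass, z) <= mz_range[1]:
            return (z,)
    raise ValueError(f"{sequence}: no charge state within the m/z range {mz_range}")


def charge_weights(sequence: str, charges: tuple[int, ...]) -> dict[int, float]:
    """Ionisation weight per listed charge, normalised to sum 1 per form."""
    base = {1: 0.4, 2: 0.6} if len(sequence) < 15 else {2: 0.6, 3: 0.4}
    raw = {z: base.get(z, 0.2) for z in charges}
    total = sum(raw.values())
    return {z: w / total for z, w in raw.items()}


# ------------------------------------------------------------------------ ground truth

@dataclass(frozen=True)
class SiteTopology:
    """Which peptides observe a site and where the site sits in the main peptide."""

    site_label: str
    sequences: tuple[str, ...]  # fully-cleaved peptide first, then missed-cleavage partners
    site_offset: str  # 1-based offset(s) within the main sequence, ';'-separated
    glyco: bool = False


@dataclass
class GroundTruth:
    """True attribute fractions, glycoform profiles and peptide loadings.

    ``site_fractions`` maps site label -> {modification name -> true modified
    fraction}; ``glyco_fractions`` maps site label -> glycoform profile
    (including the ``unglycosylated`` member) summing to 1. Loadings are
    arbitrary abundance units per fully-cleaved peptide; missed-cleavage forms
    are loaded at ``missed_fraction`` of their parents' mean loading.
    """

    loadings: dict[str, float]
    sites: dict[str, SiteTopology] = field(default_factory=dict)
    site_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    glyco_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    partners: dict[str, tuple[str, ...]] = field(default_factory=dict)
    missed_fraction: float = 0.15
    nonspecific_fraction: float = 0.0

    def __post_init__(self) -> None:
        for seq, loading in self.loadings.items():
            if loading <= 0:
                raise ValueError(f"loading for {seq} must be positive")
        for label, mods in self.site_fractions.items():
            total = 0.0
            for mod, frac in mods.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"{label}/{mod}: fraction {frac} outside [0, 1]")
                total += frac
            if total > 1.0 + 1e-9:
                raise ValueError(f"{label}: modified fractions sum to {total} > 1")
        for label, profile in self.glyco_fractions.items():
            if any(f < 0 for f in profile.values()):
                raise ValueError(f"{label}: negative glycoform fraction")
            total = sum(profile.values())
            if total <= 0:
                raise ValueError(f"{label}: empty glycoform profile")
            if abs(total - 1.0) > 1e-9:  # renormalise (printed tables round to ~100%)
                self.glyco_fractions[label] = {k: v / total for k, v in profile.items()}

    # -- lookups used by the simulator -------------------------------------------------
    def loading_for(self, comp: ComponentEntry) -> float:
        seq = comp.sequence
        if seq in self.loadings:
            return self.loadings[seq]
        if seq in self.partners:
            parents = self.partners[seq]
            return self.missed_fraction * float(np.mean([self.loadings[p] for p in parents]))
        if not comp.specific:
            for parent, loading in self.loadings.items():
                if seq in parent:
                    return self.nonspecific_fraction * loading
        raise ValueError(f"component {comp.component_id} references a peptide absent from truth")

    def fraction_for(self, comp: ComponentEntry) -> float:
        label = comp.site_label
        if label in self.glyco_fractions:
            name = comp.modification if comp.is_modified else "unglycosylated"
            return self.glyco_fractions[label].get(name, 0.0)
        if comp.is_modified:
            try:
                return self.site_fractions[label][comp.modification]
            except KeyError:
                raise ValueError(
                    f"component {comp.component_id} references a modification absent from truth"
                ) from None
        if label and label in self.site_fractions:
            return 1.0 - sum(self.site_fractions[label].values())
        return 1.0


# ------------------------------------------------------------------------- presets

def _toy_chains() -> list[ProteinChain]:
    from importlib import resources
    with resources.as_file(resources.files("mampep.data") / "toy_mab_synthetic.fasta") as p:
        return read_fasta(p)


def bundled_chains() -> list[ProteinChain]:
    """The synthetic IgG1-like heavy/light chain pair shipped with the package."""
    return _toy_chains()


def _digest_loadings(chains: list[ProteinChain], base_loading: float):
    loadings: dict[str, float] = {}
    partners: dict[str, tuple[str, ...]] = {}
    for chain in chains:
        zero = [p.sequence for p in digest(chain, TRYPSIN, max_missed=0, min_len=2)]
        for seq in zero:
            loadings[seq] = base_loading
        for pep in digest(chain, TRYPSIN, max_missed=1, min_len=2):
            if pep.missed_cleavages == 1:
                parts = _split_missed(pep.sequence, zero)
                if parts:
                    partners[pep.sequence] = parts
    return loadings, partners


def _split_missed(sequence: str, zero_missed: list[str]) -> tuple[str, ...]:
    for a in zero_missed:
        if sequence.startswith(a) and sequence[len(a):] in zero_missed:
            return (a, sequence[len(a):])
    return ()


def make_ground_truth(preset: str = "nist_table1", lab: str = "Ireland",
                      base_loading: float = 1.0, missed_fraction: float = 0.15,
                      nonspecific_fraction: float = 0.0) -> GroundTruth:
    """Build a validated GroundTruth from a named preset.

    ``nist_table1`` uses the four-laboratory IgG1 attribute panel (``lab``
    selects the column) over the bundled synthetic chains. A degradation-series
    cell is addressed as ``stability_table2:<protein>:<site>:<months>:<A|B>``,
    e.g. ``stability_table2:mAb6_LC:~N30:6:A``.
    """
    if preset == "nist_table1":
        return _table1_truth(lab, base_loading, missed_fraction, nonspecific_fraction)
    if preset.startswith("stability_table2:"):
        try:
            _, protein, site, months, site_code = preset.split(":")
        except ValueError:
            raise ValueError(
                "stability preset must be 'stability_table2:<protein>:<site>:<months>:<A|B>'"
            ) from None
        return _table2_truth(protein, site, float(months), site_code,
                             base_loading, missed_fraction)
    raise ValueError(f"unknown ground-truth preset {preset!r}")


def _table1_truth(lab, base_loading, missed_fraction, nonspecific_fraction) -> GroundTruth:
    rows = table_rows("nist_table1")
    if lab not in rows[0]:
        raise ValueError(f"unknown laboratory column {lab!r}")
    chains = _toy_chains()
    loadings, partners = _digest_loadings(chains, base_loading)
    sites: dict[str, SiteTopology] = {}
    site_fractions: dict[str, dict[str, float]] = {}
    glyco: dict[str, dict[str, float]] = {}
    for r in rows:
        label = r["site_label"]
        seqs = (r["sequence"],) + tuple(s for s in r["partners"].split(";") if s)
        if label not in sites:
            sites[label] = SiteTopology(label, seqs, r["site_offset"],
                                        glyco=r["mode"] == "profile")
        value = float(r[lab]) / 100.0
        if r["mode"] == "profile":
            name = r["modification"]
            glyco.setdefault(label, {})[name if name in glycan_registry() else "unglycosylated"] = value
        else:
            site_fractions.setdefault(label, {})[r["modification"]] = value
    site_fractions = {label: _printed_to_fractions(mods)
                      for label, mods in site_fractions.items()}
    return GroundTruth(loadings=loadings, sites=sites, site_fractions=site_fractions,
                       glyco_fractions=glyco, partners=partners,
                       missed_fraction=missed_fraction,
                       nonspecific_fraction=nonspecific_fraction)


def _printed_to_fractions(printed: dict[str, float]) -> dict[str, float]:
    """Convert reported pairwise values to species fractions of the peptide pool.

    A reported attribute value is mod / (mod + unmodified); when a peptide
    carries several modified forms those ratios are not fractions of the
    total. With odds r_i = p_i / (1 - p_i), fractions f_i = r_i / (1 + sum r)
    reproduce every printed ratio exactly (and reduce to f = p for a single
    modification).
    """
    odds = {}
    for mod, p in printed.items():
        if not 0.0 <= p < 1.0:
            raise ValueError(f"{mod}: reported value {p} outside [0, 1)")
        odds[mod] = p / (1.0 - p)
    denom = 1.0 + sum(odds.values())
    return {mod: r / denom for mod, r in odds.items()}


def _table2_truth(protein, site, months, site_code, base_loading, missed_fraction) -> GroundTruth:
    rows = [r for r in table_rows("stability_table2")
            if r["protein"] == protein and r["site_label"] == site]
    if not rows:
        raise ValueError(f"no degradation-series rows for {protein} {site}")
    cell = [r for r in rows
            if float(r["timepoint_months"]) == months and r["site"] == site_code]
    if not cell:
        raise ValueError(f"no cell for {protein} {site} at {months} months, site {site_code}")
    sequence = cell[0]["sequence"]
    label = f"{protein} {site}"
    fractions = _printed_to_fractions(
        {r["modification"]: float(r["mean"]) / 100.0 for r in cell})
    topo = SiteTopology(label, (sequence,), cell[0]["site_offset"])
    return GroundTruth(loadings={sequence: base_loading},
                       sites={label: topo},
                       site_fractions={label: fractions},
                       missed_fraction=missed_fraction)


# --------------------------------------------------------------- component generation

def build_component_table(truth: GroundTruth, chains: list[ProteinChain] | None = None,
                          rt_window_min: float = 1.5, narrow_window_min: float = 0.4,
                          mz_range: tuple[float, float] = (200.0, 2000.0),
                          include_plain_peptides: bool = True) -> list[ComponentEntry]:
    """Derive the target peptide workbook implied by a ground truth.

    Emits, per peptide in the truth, the unmodified component plus one
    component per modified form at its site, with charges, predicted RT and
    RT windows (isobaric RT-resolved forms get the narrow window). Peptides
    without attribute sites become plain coverage components when
    ``include_plain_peptides`` is set.
    """
    seq_to_site: dict[str, SiteTopology] = {}
    for topo in truth.sites.values():
        for seq in topo.sequences:
            seq_to_site[seq] = topo
    components: list[ComponentEntry] = []
    all_seqs = list(truth.loadings) + [s for s in truth.partners if s not in truth.loadings]
    for seq in all_seqs:
        topo = seq_to_site.get(seq)
        if topo is None and not include_plain_peptides:
            continue
        coords = _locate(seq, chains)
        missed = len(TRYPSIN.cleavage_points(seq))
        base = dict(sequence=seq, chain_id=coords[0], start=coords[1],
                    missed_cleavages=missed, specific=True)
        if topo is None:
            components.append(_entry(base, "", "", "", rt_window_min, mz_range))
            continue
        # main-sequence offsets -> chain coordinates of this peptide's copy of the site
        offsets = [int(x) for x in topo.site_offset.split(";")]
        main = topo.sequences[0]
        pos_in_seq = seq.find(main)
        if pos_in_seq < 0:  # partner that embeds the main peptide elsewhere
            pos_in_seq = 0
        mod_site = ";".join(str(coords[1] + pos_in_seq + off - 1) for off in offsets)
        label = topo.site_label
        if topo.glyco:
            profile = truth.glyco_fractions.get(label, {})
            names = [n for n in profile if n != "unglycosylated"] or list(glycan_registry())
            components.append(_entry(base, "unglycosylated", label, mod_site,
                                     rt_window_min, mz_range))
            for name in names:
                components.append(_entry(base, name, label, mod_site,
                                         rt_window_min, mz_range,
                                         narrow=glycan_registry()[name].rt_resolved,
                                         narrow_window=narrow_window_min))
        else:
            components.append(_entry(base, "", label, mod_site, rt_window_min, mz_range))
            for mod_name in truth.site_fractions.get(label, {}):
                components.append(_entry(base, mod_name, label, mod_site,
                                         rt_window_min, mz_range,
                                         narrow_window=narrow_window_min))
    return components


def _locate(seq: str, chains: list[ProteinChain] | None) -> tuple[str, int]:
    if chains:
        for chain in chains:
            pos = chain.sequence.find(seq)
            if pos >= 0:
                return chain.id, pos + 1
    return "peptide", 1


def _entry(base: dict, modification: str, label: str, mod_site: str,
           rt_window: float, mz_range, narrow: bool | None = None,
           narrow_window: float = 0.4) -> ComponentEntry:
    comp = ComponentEntry(**base, modification=modification, site_label=label,
                          mod_site=mod_site, attribute=(f"{label} + {modification}"
                                                        if modification else label),
                          expected_rt_min=0.0)
    form = comp.form()
    if narrow is None:
        narrow = form.rt_resolved
    charges = default_charges(comp.sequence, form.mass, mz_range)
    from dataclasses import replace
    return replace(comp, charges=charges, expected_rt_min=predict_rt(form),
                   rt_window_min=narrow_window if narrow else rt_window)


# ----------------------------------------------------------------------- simulation

class ScenarioConfig(BaseModel):
    """Study conditions for a simulated multi-laboratory experiment."""

    labs: int = Field(default=1, ge=1)
    replicates: int = Field(default=3, ge=1,
                            description="independent digests per laboratory")
    rt_drift_min: float | list[float] = 0.0
    noise_cv: float = Field(default=0.02, ge=0.0)
    gradient_min: float = Field(default=105.0, gt=0)
    scan_interval_s: float = Field(default=1.0, gt=0)
    elution_sigma_min: float = Field(default=0.15, gt=0)
    mz_range: tuple[float, float] = (200.0, 2000.0)
    base_intensity: float = Field(default=1.0e6, gt=0)
    min_intensity: float = Field(default=1.0, ge=0)
    n_isotopologues: int = Field(default=4, ge=3)
    seed: int

    @model_validator(mode="after")
    def _check(self):
        if isinstance(self.rt_drift_min, list) and len(self.rt_drift_min) < self.labs:
            raise ValueError("per-lab drift list shorter than lab count")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("invalid m/z range")
        return self

    def drift_for(self, lab: int) -> float:
        if isinstance(self.rt_drift_min, list):
            return self.rt_drift_min[lab]
        return lab * self.rt_drift_min


def simulate_run(truth: GroundTruth, components: list[ComponentEntry],
                 scenario: ScenarioConfig, lab: int = 0, replicate: int = 0,
                 sample: str = "sample", timepoint: float = 0.0) -> Run:
    """Simulate one centroided MS1 run of a digest under the given scenario.

    Each component's form contributes, per listed charge state and per
    isotopologue, a Gaussian elution peak centred at its predicted RT plus the
    lab's drift, sampled on the scan grid and multiplied by log-normal noise
    of the configured CV. The noiseless XIC area of a form is exactly
    proportional to loading x fraction (charge and isotopologue weights each
    sum to their envelope totals, which the quantifier corrects for).
    """
    rng = np.random.default_rng([abs(scenario.seed) % (2**31), lab, replicate])
    dt_min = scenario.scan_interval_s / 60.0
    rts = np.arange(0.0, scenario.gradient_min, dt_min)
    sigma = scenario.elution_sigma_min
    noise_sigma = float(np.sqrt(np.log1p(scenario.noise_cv ** 2)))
    drift = scenario.drift_for(lab)

    scan_chunks: list[np.ndarray] = []
    mz_chunks: list[np.ndarray] = []
    int_chunks: list[np.ndarray] = []
    for comp in components:
        loading = truth.loading_for(comp)
        fraction = truth.fraction_for(comp)
        amp0 = scenario.base_intensity * loading * fraction
        if amp0 <= 0:
            continue
        form = comp.form()
        mass = form.mass
        apex = predict_rt(form) + drift
        lo = np.searchsorted(rts, apex - 5 * sigma)
        hi = np.searchsorted(rts, apex + 5 * sigma)
        if hi <= lo:
            continue
        window = rts[lo:hi]
        profile = np.exp(-((window - apex) ** 2) / (2 * sigma ** 2))
        envelope = isotope_envelope(form.composition, scenario.n_isotopologues,
                                    normalize=False).abundances
        weights = charge_weights(comp.sequence, comp.charges)
        for z in comp.charges:
            for j, p_iso in enumerate(envelope):
                mz = mz_for_charge(mass + j * ISOTOPE_SPACING, z)
                if not (scenario.mz_range[0] <= mz <= scenario.mz_range[1]):
                    continue
                y = amp0 * weights[z] * p_iso * profile
                if scenario.noise_cv > 0:
                    y = y * rng.lognormal(mean=-noise_sigma ** 2 / 2.0,
                                          sigma=noise_sigma, size=y.size)
                keep = y >= scenario.min_intensity
                if not np.any(keep):
                    continue
                scan_chunks.append(np.arange(lo, hi)[keep])
                mz_chunks.append(np.full(int(keep.sum()), mz))
                int_chunks.append(y[keep])

    mz_arrays: list[np.ndarray] = [np.empty(0) for _ in range(rts.size)]
    int_arrays: list[np.ndarray] = [np.empty(0) for _ in range(rts.size)]
    if scan_chunks:
        scan_all = np.concatenate(scan_chunks)
        mz_all = np.concatenate(mz_chunks)
        int_all = np.concatenate(int_chunks)
        order = np.lexsort((mz_all, scan_all))
        scan_all, mz_all, int_all = scan_all[order], mz_all[order], int_all[order]
        bounds = np.searchsorted(scan_all, np.arange(rts.size + 1))
        for i in range(rts.size):
            if bounds[i + 1] > bounds[i]:
                mz_arrays[i] = mz_all[bounds[i]:bounds[i + 1]]
                int_arrays[i] = int_all[bounds[i]:bounds[i + 1]]
    meta = RunMetadata(lab=f"lab{lab}", replicate=replicate, sample=sample,
                       timepoint=timepoint)
    return Run(rt_minutes=rts, mz_arrays=mz_arrays, intensity_arrays=int_arrays,
               metadata=meta)


def simulate_study(truth: GroundTruth, components: list[ComponentEntry],
                   scenario: ScenarioConfig, sample: str = "sample",
                   timepoint: float = 0.0) -> list[Run]:
    """All labs x replicates of a scenario, in deterministic order."""
    return [
        simulate_run(truth, components, scenario, lab=lab, replicate=rep,
                     sample=sample, timepoint=timepoint)
        for lab in range(scenario.labs)
        for rep in range(scenario.replicates)
    ]
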