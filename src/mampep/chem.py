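"""Elemental compositions, monoisotopic masses, m/z and isotope envelopes.

Everything downstream (the synthetic generator and the targeted quantifier)
keys on the numbers computed here, so the same constants file serves both —
a deliberate self-consistency: a 5 ppm extraction window only works if the
generator and the quantifier agree on the m/z of every peptide form.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    ELEMENTS,
    ISOTOPE_SPACING,
    PROTON_MASS,
    WATER_COMPOSITION,
    isotope_table,
    monoisotopic_element_masses,
    residue_compositions,
)


@dataclass(frozen=True)
class ElementalComposition:
    """CHNOS atom counts. Supports addition/subtraction and scalar scaling."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition {self.as_tuple()}")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.C, self.H, self.N, self.O, self.S)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition(*(k * a for a in self.as_tuple()))

    __rmul__ = __mul__

    def shifted(self, deltas: dict[str, int]) -> "ElementalComposition":
        """Composition after applying a (possibly negative) per-element delta."""
        counts = {el: getattr(self, el) + deltas.get(el, 0) for el in ELEMENTS}
        for el, n in counts.items():
            if n < 0:
                raise ValueError(f"modification would give negative {el} count")
        return ElementalComposition(**counts)

    @property
    def mass(self) -> float:
        masses = monoisotopic_element_masses()
        return sum(n * masses[el] for el, n in zip(ELEMENTS, self.as_tuple()))

    def monoisotopic_fraction(self) -> float:
        """Share of the all-light isotopologue in the full envelope (closed form)."""
        table = isotope_table()
        frac = 1.0
        for el, n in zip(ELEMENTS, self.as_tuple()):
            frac *= table[el][0][1] ** n
        return frac


WATER = ElementalComposition(*WATER_COMPOSITION)


def peptide_composition(sequence: str) -> ElementalComposition:
    """Composition of a free peptide: sum of residue compositions plus water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = residue_compositions()
    comp = WATER
    for i, aa in enumerate(sequence, start=1):
        try:
            comp = comp + ElementalComposition(*table[aa])
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i}") from None
    return comp


def mono_mass(sequence_or_composition) -> float:
    """Monoisotopic mass (Da) of a peptide sequence or an ElementalComposition."""
    if isinstance(sequence_or_composition, ElementalComposition):
        return sequence_or_composition.mass
    return peptide_composition(sequence_or_composition).mass


def mz_for_charge(mass: float, z: int) -> float:
    """Positive-mode electrospray m/z: (M + z*proton) / z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopologue abundances at ~1.0034 Da spacing above the monoisotope."""

    mass_offsets: np.ndarray  # Da above the monoisotopic mass
    abundances: np.ndarray


def _element_distribution(element: str) -> np.ndarray:
    """Single-atom abundance vector indexed by nominal mass excess (0, 1, 2 ...)."""
    rows = isotope_table()[element]
    base = rows[0][0]
    size = int(round(rows[-1][0] - base)) + 1
    dist = np.zeros(size)
    for mass, ab in rows:
        dist[int(round(mass - base))] += ab
    return dist


def isotope_envelope(composition: ElementalComposition, n_peaks: int = 5,
                     normalize: bool = True) -> IsotopePattern:
    """First ``n_peaks`` isotopologue abundances of a composition.

    Computed by convolving per-element single-atom distributions, exponentiated
    by atom count via binary exponentiation. With ``normalize`` the returned
    abundances sum to 1 over the returned peaks; without it they are absolute
    probabilities (summing to <= 1 when the envelope is truncated).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    # guard bins beyond n_peaks so truncation does not distort absolute values
    width = n_peaks
    env = np.zeros(width)
    env[0] = 1.0
    for el, count in zip(ELEMENTS, composition.as_tuple()):
        if count == 0:
            continue
        single = _element_distribution(el)
        power = _convolve_power(single, count, width)
        env = np.convolve(env, power)[:width]
    if normalize:
        total = env.sum()
        if total > 0:
            env = env / total
    offsets = np.arange(width) * ISOTOPE_SPACING
    return IsotopePattern(mass_offsets=offsets, abundances=env)


def _convolve_power(dist: np.ndarray, count: int, width: int) -> np.ndarray:
    """dist convolved with itself ``count`` times, truncated to ``width`` bins."""
    result = np.zeros(width)
    result[0] = 1.0
    base = dist[:width].copy()
    k = count
    while k:
        if k & 1:
            result = np.convolve(result, base)[:width]
        base = np.convolve(base, base)[:width]
        k >>= 1
    return result
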