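"""Versioned physical constants loaded from the CSV tables shipped with the package.

All masses are monoisotopic and in Daltons. The CSV files under ``mampep/data``
are the single source of truth for residue compositions, isotope abundances,
modification deltas, glycan compositions and retention coefficients.
"""
from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

#: Mass of a proton (charge carrier in positive electrospray), Da.
PROTON_MASS = 1.007276

#: Mass spacing between successive isotopologue peaks, Da (13C-12C difference;
#: the dominant heavy-isotope channel for peptides).
ISOTOPE_SPACING = 1.0033548378

ELEMENTS = ("C", "H", "N", "O", "S")


def _data_rows(filename: str) -> list[dict[str, str]]:
    text = resources.files("mampep.data").joinpath(filename).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines))


@lru_cache(maxsize=None)
def residue_compositions() -> dict[str, tuple[int, int, int, int, int]]:
    """Map residue letter -> (C, H, N, O, S) counts of the bonded residue."""
    return {
        r["aa"]: tuple(int(r[e]) for e in ELEMENTS)  # type: ignore[return-value]
        for r in _data_rows("residues.csv")
    }


@lru_cache(maxsize=None)
def isotope_table() -> dict[str, list[tuple[float, float]]]:
    """Map element -> [(isotope mass, abundance), ...] ordered light to heavy."""
    table: dict[str, list[tuple[float, float]]] = {}
    for r in _data_rows("isotopes.csv"):
        table.setdefault(r["element"], []).append((float(r["mass"]), float(r["abundance"])))
    return table


@lru_cache(maxsize=None)
def monoisotopic_element_masses() -> dict[str, float]:
    return {el: rows[0][0] for el, rows in isotope_table().items()}


@lru_cache(maxsize=None)
def rt_coefficients() -> dict[str, float]:
    return {r["aa"]: float(r["coeff"]) for r in _data_rows("rt_coefficients.csv")}


def modification_rows() -> list[dict[str, str]]:
    return _data_rows("modifications.csv")


def glycan_rows() -> list[dict[str, str]]:
    return _data_rows("glycans.csv")


def table_rows(name: str) -> list[dict[str, str]]:
    """Rows of a bundled reference table (``nist_table1`` or ``stability_table2``)."""
    return _data_rows(f"{name}.csv")


#: Water, used to close a peptide chain: H2O.
WATER_COMPOSITION = (0, 2, 0, 1, 0)
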