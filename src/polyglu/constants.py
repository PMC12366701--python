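"""Pinned physical constants and residue chemistry.

All monoisotopic masses and natural isotopic abundances are read from the
bundled ``data/isotopes.json`` table so that every mass printed by this
package is bit-stable across platforms and library versions.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

__all__ = [
    "ELEMENTS",
    "HEAVY",
    "PROTON",
    "ELECTRON",
    "MONO",
    "WATER",
    "RESIDUE_FORMULAS",
    "GLU_RESIDUE",
    "constants_checksum",
]


def _load() -> dict:
    with resources.files("polyglu.data").joinpath("isotopes.json").open("rb") as fh:
        return json.load(fh)


_TABLE = _load()

#: element -> list of (monoisotopic mass, natural abundance), principal isotope first
ELEMENTS: dict[str, list[tuple[float, float]]] = {
    el: [(m, a) for m, a in rows] for el, rows in _TABLE["elements"].items()
}
#: explicit heavy-isotope labels usable as composition keys
HEAVY: dict[str, float] = dict(_TABLE["heavy"])
PROTON: float = _TABLE["proton"]
ELECTRON: float = _TABLE["electron"]

#: principal (monoisotopic) mass per composition key
MONO: dict[str, float] = {el: rows[0][0] for el, rows in ELEMENTS.items()}
MONO.update(HEAVY)

WATER: dict[str, int] = {"H": 2, "O": 1}

# residue (= amino acid minus water) formulas for the 20 standard residues
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

GLU_RESIDUE = RESIDUE_FORMULAS["E"]

STANDARD_RESIDUES = frozenset(RESIDUE_FORMULAS)


def constants_checksum() -> str:
    """SHA-256 of the bundled isotope table (recorded in every report)."""
    with resources.files("polyglu.data").joinpath("isotopes.json").open("rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
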