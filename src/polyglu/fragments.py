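"""Theoretical b/y fragment ladders for linear and branched peptidoforms.

Cleavage is modeled on the main chain only: the genetic peptide backbone
plus, for the y-series, the appended extension chain (its units behave like
extra C-terminal residues).  A branch chain rides along intact — every
fragment that contains the branch-point residue carries the full branch-chain
mass.  This mirrors how polyglutamylated tubulin spectra are read: the b/y
ladder of the main chain localizes the added mass, and the isobaric
extension-vs-branch ambiguity at MS1 is resolved by the ions that separate
the candidate attachment points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .constants import HEAVY, MONO, PROTON, RESIDUE_FORMULAS, WATER
from .mass import ElementalComposition, composition, glu_unit_composition, mono_mass
from .tails import Peptidoform

__all__ = ["FragmentIon", "by_ladder", "discriminating_ions", "ladder_table"]

C13_DELTA = HEAVY["13C"] - MONO["C"]


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" | "y"
    index: int
    charge: int
    composition: tuple[tuple[str, int], ...] = field(repr=False)
    mz: float
    contains_sites: frozenset = frozenset()  # branch residue numbers and/or "ext"
    heavy_isotope_offset: int = 0  # number of 13C in the satellite (0 = monoisotopic)
    low_confidence: bool = False  # b1 ions are rarely observed

    @property
    def key(self) -> tuple:
        return (self.series, self.index, self.charge, self.heavy_isotope_offset)

    @property
    def annotation(self) -> str:
        sat = f"+{self.heavy_isotope_offset}x13C" if self.heavy_isotope_offset else ""
        z = f"{self.charge}+" if self.charge > 1 else "+"
        tags = ",".join(sorted(map(str, self.contains_sites)))
        return f"{self.series}{self.index}{sat} [{z}]" + (f" ({tags})" if tags else "")


def _segment_composition(
    p: Peptidoform, lo: int, hi: int, with_water: bool
) -> tuple[ElementalComposition, set]:
    """Composition of main-chain positions lo..hi (0-based, genetic residues
    then extension units), plus branch chains attached inside the segment."""
    n_pep = len(p.peptide)
    comp = ElementalComposition(WATER) if with_water else ElementalComposition()
    sites: set = set()
    branch_map = p.branch_map
    for i in range(lo, hi):
        if i < n_pep:
            comp += RESIDUE_FORMULAS[p.peptide[i]]
            pos = p.start + i
            if pos in branch_map:
                sites.add(pos)
                for unit in branch_map[pos]:
                    comp += glu_unit_composition(unit)
        else:
            comp += glu_unit_composition(p.extension[i - n_pep])
            sites.add("ext")
    return comp, sites


def by_ladder(
    p: Peptidoform,
    max_charge: int = 1,
    c13_satellites: int = 0,
    include_extension_b: bool = False,
) -> list[FragmentIon]:
    """All main-chain b/y fragment ions of a peptidoform.

    For a main chain of N positions (genetic residues + extension units)
    there are N-1 cleavage sites; cut ``i`` yields ``b_i`` and ``y_{N-i}``.
    y-ions run through the appended chain (y1 is the last added Glu of an
    extended form); b-ions are restricted to the genetic sequence unless
    ``include_extension_b`` is set.  ``c13_satellites`` additionally emits
    +1/+2 13C isotopologue masses, which are routinely used to read long
    Glu-rich fragments whose monoisotopic peak is weak.
    """
    if len(p.peptide) < 2:
        raise ValueError("peptide must have length >= 2")
    if not 0 <= c13_satellites <= 2:
        raise ValueError("c13_satellites must be 0, 1 or 2")
    n_pep = len(p.peptide)
    n_total = n_pep + len(p.extension)
    ions: list[FragmentIon] = []
    for cut in range(1, n_total):
        # b fragment: positions [0, cut), neutral = residues (no water)
        if cut < n_pep or include_extension_b:
            comp, sites = _segment_composition(p, 0, cut, with_water=False)
            ions.extend(
                _charge_states(
                    "b", cut, comp, sites, max_charge, c13_satellites, low_confidence=cut == 1
                )
            )
        # y fragment: positions [cut, N), neutral = residues + water
        comp, sites = _segment_composition(p, cut, n_total, with_water=True)
        ions.extend(_charge_states("y", n_total - cut, comp, sites, max_charge, c13_satellites))
    return ions


def _charge_states(
    series: str,
    index: int,
    comp: ElementalComposition,
    sites: set,
    max_charge: int,
    c13: int,
    low_confidence: bool = False,
) -> Iterable[FragmentIon]:
    base = mono_mass(comp)
    frozen = comp.frozen()
    for z in range(1, max_charge + 1):
        for sat in range(c13 + 1):
            m = base + sat * C13_DELTA
            yield FragmentIon(
                series=series,
                index=index,
                charge=z,
                composition=frozen,
                mz=(m + z * PROTON) / z,
                contains_sites=frozenset(sites),
                heavy_isotope_offset=sat,
                low_confidence=low_confidence,
            )


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


def discriminating_ions(
    a: Peptidoform,
    b: Peptidoform,
    tol_ppm: float = 20.0,
    max_charge: int = 1,
    precursor_tol_ppm: float = 1.0,
) -> list[tuple[FragmentIon | None, FragmentIon | None]]:
    """Fragment ions that distinguish two MS1-isobaric peptidoforms.

    Ladders are compared by (series, index, charge, satellite); a pair whose
    m/z differ by more than ``tol_ppm``, or an ion present in only one
    ladder, discriminates.  Empty result means the forms are indistinguishable
    at the fragment level.  Raises for inputs that are not isobaric at MS1.
    """
    ma, mb = mono_mass(composition(a)), mono_mass(composition(b))
    if _ppm(ma, mb) > precursor_tol_ppm:
        raise ValueError(
            f"peptidoforms are not isobaric at MS1 ({ma:.5f} vs {mb:.5f} Da); "
            "discriminating-ion analysis applies to same-precursor candidates"
        )
    la = {ion.key: ion for ion in by_ladder(a, max_charge=max_charge)}
    lb = {ion.key: ion for ion in by_ladder(b, max_charge=max_charge)}
    out: list[tuple[FragmentIon | None, FragmentIon | None]] = []
    for key in sorted(la.keys() | lb.keys()):
        ia, ib = la.get(key), lb.get(key)
        if ia is None or ib is None:
            out.append((ia, ib))
        elif _ppm(ia.mz, ib.mz) > tol_ppm:
            out.append((ia, ib))
    return out


def ladder_table(ions: Sequence[FragmentIon]) -> "pandas.DataFrame":  # noqa: F821
    """Ladder as a DataFrame (series, index, z, m/z, annotation) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "series": [i.series for i in ions],
            "index": [i.index for i in ions],
            "z": [i.charge for i in ions],
            "mz": [round(i.mz, 5) for i in ions],
            "annotation": [i.annotation for i in ions],
        }
    )
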