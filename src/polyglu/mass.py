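"""Elemental compositions, monoisotopic masses, adduct m/z, isotope envelopes,
and the 18O linkage-retention model.

Compositions are plain element->count mappings whose keys are the light
elements (C, H, N, O, S, Na) plus *explicit* heavy-isotope slots (``2H``,
``13C``, ``18O``).  A heavy key means the substitution has already been
applied: a D5 glutamate residue is ``C5 H2 (2H)5 N O3``.  Explicit heavy
atoms contribute a fixed mass shift and no isotopic spread; the natural
elements are convolved from the pinned abundance table.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping

from .constants import ELEMENTS, GLU_RESIDUE, HEAVY, MONO, PROTON, ELECTRON, RESIDUE_FORMULAS, WATER
from .tails import GluUnit, Peptidoform

__all__ = [
    "ElementalComposition",
    "peptide_composition",
    "glu_unit_composition",
    "composition",
    "mono_mass",
    "mz",
    "neutral_mass",
    "envelope",
    "envelope_under_retention",
    "o18_retention",
    "expected_o18_shift",
]

ADDUCTS = ("protonated", "deprotonated", "sodiated")

#: mass difference 18O - 16O, the per-label envelope shift
O18_SHIFT = HEAVY["18O"] - MONO["O"]


class ElementalComposition(Counter):
    """Charge-free elemental composition; supports +, - and scalar * via Counter."""

    def frozen(self) -> tuple[tuple[str, int], ...]:
        return tuple(sorted((k, v) for k, v in self.items() if v))

    def hill(self) -> str:
        parts = []
        for el in ("C", "13C", "H", "2H", "N", "O", "18O", "S", "Na"):
            n = self.get(el, 0)
            if n:
                parts.append(f"{el}{n if n > 1 else ''}")
        return "".join(parts)


def _validated(comp: Mapping[str, int]) -> ElementalComposition:
    out = ElementalComposition()
    for k, v in comp.items():
        if k not in MONO:
            raise ValueError(f"unknown element or isotope {k!r}")
        if v < 0:
            raise ValueError(f"negative count for {k}")
        if v:
            out[k] = v
    return out


def glu_unit_composition(unit: GluUnit) -> ElementalComposition:
    """Residue composition (C5H7NO3 net) of one added glutamate unit,
    with the label's isotopic substitutions applied."""
    c = ElementalComposition(GLU_RESIDUE)
    if unit.label == "D5":
        c["H"] -= 5
        c["2H"] += 5
    elif unit.label == "O18":
        c["O"] -= 1
        c["18O"] += 1
    return c


def peptide_composition(sequence: str) -> ElementalComposition:
    """Residue compositions plus one water for an unmodified linear peptide."""
    comp = ElementalComposition(WATER)
    for aa in sequence:
        try:
            comp += RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    return comp


def composition(p: Peptidoform, o18_retained: int | None = None) -> ElementalComposition:
    """Elemental composition of a peptidoform.

    Each added Glu unit contributes its residue composition (amide bond
    formation releases one water, so no extra water per unit).  If
    ``o18_retained`` is given, only that many of the 18O labels are kept and
    the rest are reverted to 16O — the composition of one outcome of the
    :func:`o18_retention` distribution.
    """
    comp = peptide_composition(p.peptide)
    for unit in p.all_units:
        comp += glu_unit_composition(unit)
    if o18_retained is not None:
        n_labels = comp.get("18O", 0)
        if not (0 <= o18_retained <= n_labels):
            raise ValueError(f"retained count {o18_retained} outside 0..{n_labels}")
        lost = n_labels - o18_retained
        comp["18O"] -= lost
        comp["O"] += lost
    return _validated(comp)


def mono_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da (explicit heavy isotopes at their exact mass)."""
    return sum(MONO[k] * v for k, v in comp.items() if v)


def mz(mass: float, z: int, mode: str = "protonated") -> float:
    """m/z of an adduct ion.

    ``protonated``: (M + z*H+)/z; ``deprotonated``: (M - z*H+)/z;
    ``sodiated``: (M + z*(Na - e-))/z.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mode == "protonated":
        return (mass + z * PROTON) / z
    if mode == "deprotonated":
        return (mass - z * PROTON) / z
    if mode == "sodiated":
        return (mass + z * (MONO["Na"] - ELECTRON)) / z
    raise ValueError(f"unknown adduct mode {mode!r}; expected one of {ADDUCTS}")


#: integer mass numbers for the low-resolution (unit resolution) reading
_MASS_NUMBER = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "Na": 23, "2H": 2, "13C": 13, "18O": 18}


def low_res_mz(comp: Mapping[str, int], z: int = 1, mode: str = "protonated") -> float:
    """Unit-resolution ESI-MS reading of an ion, quoted to one decimal place.

    Low-resolution spectrometers resolve only the nominal mass; the
    conventional printed value is the ion's nominal m/z (sum of mass
    numbers, +-1 per proton or +23 per sodium).
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    nominal = sum(_MASS_NUMBER[k] * v for k, v in comp.items() if v)
    if mode == "protonated":
        nominal += z
    elif mode == "deprotonated":
        nominal -= z
    elif mode == "sodiated":
        nominal += 23 * z
    else:
        raise ValueError(f"unknown adduct mode {mode!r}")
    return round(nominal / z, 1)


def neutral_mass(observed_mz: float, z: int, mode: str = "protonated") -> float:
    """Invert :func:`mz` for the neutral monoisotopic mass."""
    if mode == "protonated":
        return observed_mz * z - z * PROTON
    if mode == "deprotonated":
        return observed_mz * z + z * PROTON
    if mode == "sodiated":
        return observed_mz * z - z * (MONO["Na"] - ELECTRON)
    raise ValueError(f"unknown adduct mode {mode!r}")


# ---------------------------------------------------------------------------
# isotope envelopes


def _convolve(a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]], prune: float):
    out: dict[int, list[float]] = {}
    for i, (pa, ma) in a.items():
        for j, (pb, mb) in b.items():
            p = pa * pb
            if p <= 0.0:
                continue
            cell = out.setdefault(i + j, [0.0, 0.0])
            cell[0] += p
            cell[1] += p * (ma + mb)
    if out:
        top = max(c[0] for c in out.values())
        out = {k: c for k, c in out.items() if c[0] >= prune * top}
    return {k: (p, m / p) for k, (p, m) in out.items()}


def _element_dist(el: str, n: int, prune: float) -> dict[int, tuple[float, float]]:
    """Isotopologue distribution of n atoms of one element on the
    nominal-mass-offset grid: offset -> (probability, expected mass delta)."""
    rows = ELEMENTS[el]
    base = rows[0][0]
    single = {round(m - base): (a, m - base) for m, a in rows}
    result: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    power = single
    while n:
        if n & 1:
            result = _convolve(result, power, prune * 1e-3)
        n >>= 1
        if n:
            power = _convolve(power, power, prune * 1e-3)
    return result


def envelope(
    comp: Mapping[str, int], prune: float = 1e-6
) -> list[tuple[float, float]]:
    """Theoretical isotope envelope of a composition.

    Per-element isotope distributions are convolved and aggregated on the
    nominal-mass grid (isotopic fine structure is deliberately collapsed);
    each bin carries its abundance-weighted expected mass.  Peaks below
    ``prune`` relative abundance (of the tallest peak) are removed and the
    remainder renormalized to sum to 1.

    Returns a list of ``(mass, abundance)`` sorted by mass.
    """
    if not (0 <= prune < 1):
        raise ValueError("prune must be in [0, 1)")
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for el, count in comp.items():
        if not count or el in HEAVY or el == "Na" and len(ELEMENTS["Na"]) == 1:
            continue
        if el in ELEMENTS and len(ELEMENTS[el]) > 1:
            dist = _convolve(dist, _element_dist(el, count, prune), prune * 1e-3)
    base = mono_mass(comp)
    if dist:
        top = max(p for p, _ in dist.values())
        dist = {k: v for k, v in dist.items() if v[0] >= prune * top}
    total = sum(p for p, _ in dist.values())
    peaks = sorted((base + dm, p / total) for k, (p, dm) in dist.items())
    return peaks


def envelope_under_retention(
    p: Peptidoform,
    retention: Mapping[int, float],
    prune: float = 1e-6,
    merge_tol: float = 0.005,
) -> list[tuple[float, float]]:
    """Mixture envelope over a retained-18O-count distribution.

    Each retained count contributes the envelope of the corresponding
    composition weighted by its probability; peaks closer than ``merge_tol``
    Da are merged (abundance-weighted mean mass).
    """
    peaks: list[tuple[float, float]] = []
    for retained, w in retention.items():
        if w <= 0:
            continue
        for m, a in envelope(composition(p, o18_retained=retained), prune=prune):
            peaks.append((m, a * w))
    peaks.sort()
    merged: list[list[float]] = []
    for m, a in peaks:
        if merged and m - merged[-1][0] <= merge_tol:
            tot = merged[-1][1] + a
            merged[-1][0] = (merged[-1][0] * merged[-1][1] + m * a) / tot
            merged[-1][1] = tot
        else:
            merged.append([m, a])
    total = sum(a for _, a in merged)
    return [(m, a / total) for m, a in merged]


# ---------------------------------------------------------------------------
# 18O retention


def _labeled_gamma_bonds(units: Iterable[GluUnit]) -> int:
    return sum(1 for u in units if u.label == "O18" and u.linkage_to_next == "gamma")


def o18_retention(p: Peptidoform) -> dict[int, float]:
    """Distribution of the number of retained 18O labels after bond formation.

    The gamma-18O label sits on the gamma-carboxyl.  When a chain bond is
    formed *through* a labeled gamma-carboxyl, the two carboxylate oxygens
    are chemically equivalent and the label leaves with the water with
    probability 1/2.  Bonds through alpha-carboxyls (elongation chemistry)
    never touch the gamma label, and the branch-initiation bond consumes the
    substrate residue's own gamma-carboxyl, not an incoming label's.  Losses
    across bonds are independent, so the retained count is
    ``m - Binomial(g, 1/2)`` for ``m`` labels and ``g`` labeled gamma bonds.
    """
    m = sum(1 for u in p.all_units if u.label == "O18")
    if m == 0:
        raise ValueError("peptidoform carries no 18O units")
    g = _labeled_gamma_bonds(p.all_units)
    dist: dict[int, float] = {}
    for lost in range(g + 1):
        dist[m - lost] = math.comb(g, lost) * 0.5**g
    return dist


def expected_o18_shift(p: Peptidoform) -> float:
    """Expected MS1 mass shift relative to the all-16O form, under retention."""
    dist = o18_retention(p)
    return O18_SHIFT * sum(k * w for k, w in dist.items())
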