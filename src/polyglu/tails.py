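"""Tubulin C-terminal tails, truncation variants, and glutamylated peptidoforms.

The central object is the :class:`Peptidoform`: a proteolytic peptide from a
tubulin tail plus a modification topology — an *extension* chain of glutamate
units appended to the C-terminal alpha-carboxyl of the main polypeptide,
and/or lateral *branch* chains attached through the gamma-carboxyl of
internal glutamate residues (isopeptide bonds).  Residue positions are always
full-length mature-isoform numbers (so the alpha-tubulin branch hotspots
E445/E446/E447 are addressable directly); peptide-local indices are never
exposed.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from Bio import SeqIO

from .constants import STANDARD_RESIDUES

__all__ = [
    "TailSequence",
    "TailVariant",
    "GluUnit",
    "Peptidoform",
    "VARIANT_KINDS",
    "make_variant",
    "enumerate_peptidoforms",
    "load_tails",
    "glu_chain",
]

#: truncation depth by variant kind; Tyr / native_beta are identities
VARIANT_KINDS: dict[str, int] = {
    "Tyr": 0,
    "dTyr": 1,
    "d2": 2,
    "d3": 3,
    "native_beta": 0,
    "beta_d2": 2,
    "beta_d3": 3,
}

_ALPHA_KINDS = {"Tyr", "dTyr", "d2", "d3"}


@dataclass(frozen=True)
class TailSequence:
    """A tubulin isoform C-terminal tail with full-length numbering.

    ``numbering_offset`` is defined so that 1-based tail position ``i``
    corresponds to full-length residue ``i + numbering_offset``.
    """

    isoform_id: str
    sequence: str
    numbering_offset: int
    chain_class: str  # "alpha" | "beta"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("tail sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues in tail: {sorted(bad)}")
        if self.chain_class not in ("alpha", "beta"):
            raise ValueError(f"unknown chain class {self.chain_class!r}")

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.sequence)

    def residue_number(self, local_index: int) -> int:
        """Full-length residue number of 1-based tail position."""
        return local_index + self.numbering_offset


@dataclass(frozen=True)
class TailVariant:
    """An enzymatic C-terminal truncation of a tail (e.g. detyrosination)."""

    base: TailSequence
    variant_kind: str
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        if self.variant_kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.variant_kind!r}")
        if not self.sequence:
            object.__setattr__(
                self, "sequence", _truncate(self.base.sequence, VARIANT_KINDS[self.variant_kind])
            )
        if not self.base.sequence.startswith(self.sequence):
            raise ValueError("variant sequence must be a prefix of the base tail")

    @property
    def last_residue(self) -> int:
        return self.base.numbering_offset + len(self.sequence)

    @property
    def numbering_offset(self) -> int:
        return self.base.numbering_offset


def _truncate(seq: str, n: int) -> str:
    if n >= len(seq):
        raise ValueError(f"cannot remove {n} residues from a {len(seq)}-residue tail")
    return seq[: len(seq) - n] if n else seq


def make_variant(base: TailSequence, kind: str) -> TailVariant:
    """Derive a truncation variant (Tyr/dTyr/d2/d3, native_beta/beta_d2/beta_d3).

    Raises ``ValueError`` for an unknown kind, a kind inconsistent with the
    chain class, or a truncation longer than the tail.
    """
    if kind not in VARIANT_KINDS:
        raise ValueError(f"unknown variant kind {kind!r}")
    expected = "alpha" if kind in _ALPHA_KINDS else "beta"
    if base.chain_class != expected:
        raise ValueError(f"variant {kind!r} applies to {expected}-tubulin tails")
    return TailVariant(base=base, variant_kind=kind)


@dataclass(frozen=True)
class GluUnit:
    """One added glutamate unit.

    ``label`` selects the isotopic species (light, perdeuterated D5, or
    gamma-18O).  ``linkage_to_next`` records which carboxyl of *this* unit
    forms the amide bond to the following unit in the chain: ``alpha`` for
    main-chain-like elongation, ``gamma`` for isopeptide elongation, and
    ``none`` for the terminal unit.
    """

    label: str = "light"
    linkage_to_next: str = "alpha"

    def __post_init__(self) -> None:
        if self.label not in ("light", "D5", "O18"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.linkage_to_next not in ("alpha", "gamma", "none"):
            raise ValueError(f"unknown linkage {self.linkage_to_next!r}")


def glu_chain(n: int, label: str = "light", linkage: str = "alpha") -> tuple[GluUnit, ...]:
    """A chain of ``n`` identically labeled units; within-chain bonds are
    ``linkage`` and the terminal unit carries ``linkage_to_next='none'``."""
    if n == 0:
        return ()
    units = [GluUnit(label=label, linkage_to_next=linkage) for _ in range(n - 1)]
    units.append(GluUnit(label=label, linkage_to_next="none"))
    return tuple(units)


@dataclass(frozen=True)
class Peptidoform:
    """A peptide plus glutamylation topology in full-length coordinates."""

    peptide: str
    start: int  # full-length residue number of the first peptide residue
    extension: tuple[GluUnit, ...] = ()
    branches: tuple[tuple[int, tuple[GluUnit, ...]], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.peptide) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        object.__setattr__(self, "branches", tuple(sorted(self.branches)))
        for pos, units in self.branches:
            if not (self.start <= pos <= self.end):
                raise ValueError(f"branch position {pos} outside peptide {self.start}-{self.end}")
            if self.residue_at(pos) != "E":
                raise ValueError(f"branch position {pos} is {self.residue_at(pos)}, not Glu")
            if not units:
                raise ValueError(f"empty branch chain at {pos}")
        if self.extension and self.extension[-1].linkage_to_next != "none":
            raise ValueError("terminal extension unit must have linkage 'none'")

    @property
    def end(self) -> int:
        return self.start + len(self.peptide) - 1

    def residue_at(self, pos: int) -> str:
        return self.peptide[pos - self.start]

    @property
    def branch_map(self) -> dict[int, tuple[GluUnit, ...]]:
        return dict(self.branches)

    @property
    def total_added_glu(self) -> int:
        return len(self.extension) + sum(len(u) for _, u in self.branches)

    @property
    def all_units(self) -> tuple[GluUnit, ...]:
        units = list(self.extension)
        for _, chain in self.branches:
            units.extend(chain)
        return tuple(units)

    @property
    def label_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(u.label for u in self.all_units))

    def topology(self) -> str:
        """Human-readable topology: 'unmodified', 'extension', 'branch@445', ..."""
        parts = []
        if self.extension:
            parts.append("extension")
        for pos, _ in self.branches:
            parts.append(f"branch@{pos}")
        return "+".join(parts) if parts else "unmodified"

    def canonical(self) -> str:
        """Canonical text serialization, e.g. ``PEPTIDE/431+ext[E:D5,E:D5]+br@445[E:light]``."""
        s = f"{self.peptide}/{self.start}"
        if self.extension:
            s += "+ext[" + ",".join(f"E:{u.label}" for u in self.extension) + "]"
        for pos, units in self.branches:
            s += f"+br@{pos}[" + ",".join(f"E:{u.label}" for u in units) + "]"
        return s

    @classmethod
    def from_canonical(cls, text: str) -> "Peptidoform":
        head, *mods = text.split("+")
        pep, start = head.split("/")
        extension: tuple[GluUnit, ...] = ()
        branches = []
        for mod in mods:
            m = re.fullmatch(r"(ext|br@(\d+))\[([^\]]*)\]", mod)
            if not m:
                raise ValueError(f"bad peptidoform segment {mod!r}")
            labels = [tok.split(":")[1] for tok in m.group(3).split(",") if tok]
            if len(set(labels)) == 1:
                chain = glu_chain(len(labels), label=labels[0])
            else:
                chain = tuple(
                    GluUnit(label=l, linkage_to_next="alpha" if i < len(labels) - 1 else "none")
                    for i, l in enumerate(labels)
                )
            if m.group(1) == "ext":
                extension = chain
            else:
                branches.append((int(m.group(2)), chain))
        return cls(peptide=pep, start=int(start), extension=extension, branches=tuple(branches))


def enumerate_peptidoforms(
    peptide: str,
    start: int,
    max_total_glu: int,
    allowed_sites: Sequence[int] = (),
    label: str = "light",
    allow_extension: bool = True,
    within_chain_linkage: str = "alpha",
) -> list[Peptidoform]:
    """All peptidoforms with 0..max_total_glu added Glu partitioned across the
    extension and the allowed branch sites.

    Deterministic order: by total added Glu, extension count first (descending
    extension share), then branch sites ascending.  Raises if an allowed site
    is not a Glu inside the peptide.
    """
    if max_total_glu < 0:
        raise ValueError("max_total_glu must be >= 0")
    for pos in allowed_sites:
        idx = pos - start
        if not (0 <= idx < len(peptide)) or peptide[idx] != "E":
            raise ValueError(f"allowed site {pos} is not a Glu residue of the peptide")
    sites = sorted(allowed_sites)
    bins = (1 if allow_extension else 0) + len(sites)
    out: list[Peptidoform] = []
    for total in range(max_total_glu + 1):
        if bins == 0:
            if total == 0:
                out.append(Peptidoform(peptide=peptide, start=start))
            continue
        for cuts in itertools.combinations(range(total + bins - 1), bins - 1):
            # stars-and-bars composition of `total` into `bins` ordered parts
            parts = []
            prev = -1
            for c in cuts:
                parts.append(c - prev - 1)
                prev = c
            parts.append(total + bins - 2 - prev)
            if allow_extension:
                ext_n, branch_ns = parts[0], parts[1:]
            else:
                ext_n, branch_ns = 0, parts
            branches = tuple(
                (pos, glu_chain(n, label=label, linkage=within_chain_linkage))
                for pos, n in zip(sites, branch_ns)
                if n > 0
            )
            out.append(
                Peptidoform(
                    peptide=peptide,
                    start=start,
                    extension=glu_chain(ext_n, label=label, linkage=within_chain_linkage),
                    branches=branches,
                )
            )
    # extension-first within each total, then branch sites ascending
    out.sort(
        key=lambda p: (
            p.total_added_glu,
            -len(p.extension),
            tuple((pos, len(units)) for pos, units in p.branches),
        )
    )
    return out


def load_tails() -> dict[str, TailSequence]:
    """Load the bundled tubulin C-tail fixtures (sequence + numbering manifest)."""
    data = resources.files("polyglu.data")
    with data.joinpath("tails_manifest.json").open() as fh:
        manifest = json.load(fh)["tails"]
    tails: dict[str, TailSequence] = {}
    with data.joinpath("tails.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            meta = manifest[rec.id]
            seq = str(rec.seq)
            tails[rec.id] = TailSequence(
                isoform_id=rec.id,
                sequence=seq,
                numbering_offset=meta["last_residue"] - len(seq),
                chain_class=meta["chain_class"],
            )
    return tails
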