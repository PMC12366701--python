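"""In-silico proteolysis producing the C-terminal tubulin tail peptides.

Two rule sets cover the workflow: ``trypsin_lysC`` (cleave after K always —
LysC is blind to the proline rule — and after R unless followed by P) for
alpha-tails, and ``aspN`` (cleave N-terminal to D; an E-inclusive mode is
available since tubulin tails are Glu-rich) for beta-tails.  Added
posttranslational Glu chains are never cleavage substrates: digestion runs
on the genetically encoded sequence and chains are attached to peptidoforms
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["DigestRule", "DigestPeptide", "digest", "cleavage_sites", "cterm_peptide"]

ENZYMES = ("trypsin_lysC", "aspN")


@dataclass(frozen=True)
class DigestRule:
    enzyme: str = "trypsin_lysC"
    max_missed_cleavages: int = 0
    min_length: int = 1
    aspn_cleave_glu: bool = False  # E-inclusive AspN specificity

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}; expected one of {ENZYMES}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class DigestPeptide:
    """A proteolytic peptide with half-open local coordinates [start, end)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0


def cleavage_sites(sequence: str, rule: DigestRule) -> list[int]:
    """Cut positions (between sequence[i-1] and sequence[i]), ascending."""
    sites: list[int] = []
    n = len(sequence)
    if rule.enzyme == "trypsin_lysC":
        for i in range(1, n):
            prev, cur = sequence[i - 1], sequence[i]
            if prev == "K" or (prev == "R" and cur != "P"):
                sites.append(i)
    else:  # aspN
        targets = "DE" if rule.aspn_cleave_glu else "D"
        for i in range(1, n):
            if sequence[i] in targets:
                sites.append(i)
    return sites


def digest(sequence: str, rule: DigestRule) -> list[DigestPeptide]:
    """All peptides up to the missed-cleavage limit, with coordinates.

    Zero-missed-cleavage products tile the sequence exactly; a peptide with
    ``m`` missed cleavages spans ``m`` internal cut sites.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bounds = [0] + cleavage_sites(sequence, rule) + [len(sequence)]
    out: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + rule.max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            if end - start >= rule.min_length:
                out.append(
                    DigestPeptide(
                        sequence=sequence[start:end],
                        start=start,
                        end=end,
                        missed_cleavages=j - i - 1,
                    )
                )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def cterm_peptide(peptides: Sequence[DigestPeptide]) -> DigestPeptide:
    """The fully cleaved peptide containing the sequence C-terminus."""
    if not peptides:
        raise ValueError("empty digest")
    last = max(p.end for p in peptides)
    terminal = [p for p in peptides if p.end == last]
    return min(terminal, key=lambda p: p.end - p.start)
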