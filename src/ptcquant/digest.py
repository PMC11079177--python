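"""In-silico proteolysis with fully specific cleavage rules.

Peptide coordinates are 1-based inclusive: a peptide covering residues 4-7
of its parent has ``start=4, end=7`` and ``sequence == parent[3:7]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .variants import STANDARD_AA

__all__ = [
    "ProteaseRule",
    "Peptide",
    "TRYPSIN",
    "TRYPSIN_STRICT",
    "CHYMOTRYPSIN",
    "CHYMOTRYPSIN_HIGH_SPECIFICITY",
    "PROTEASES",
    "cleavage_points",
    "digest",
    "site_spanning_peptides",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Position-independent cleavage rule.

    The bond C-terminal to a residue in ``cleave_after`` is cut unless the
    following residue is in ``suppress_before``.
    """

    name: str
    cleave_after: frozenset[str]
    suppress_before: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError(f"protease {self.name!r}: empty cleave_after set")


# Conventional Mascot-style trypsin: after K/R, not before P.
TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
#: Trypsin without the proline exception.
TRYPSIN_STRICT = ProteaseRule("trypsin-strict", frozenset("KR"))
# Chymotrypsin, low-specificity rule: after the bulky hydrophobics F/W/Y/L/M.
CHYMOTRYPSIN = ProteaseRule("chymotrypsin", frozenset("FWYLM"), frozenset("P"))
CHYMOTRYPSIN_HIGH_SPECIFICITY = ProteaseRule(
    "chymotrypsin-high-specificity", frozenset("FWY"), frozenset("P")
)

PROTEASES: dict[str, ProteaseRule] = {
    p.name: p
    for p in (TRYPSIN, TRYPSIN_STRICT, CHYMOTRYPSIN, CHYMOTRYPSIN_HIGH_SPECIFICITY)
}


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    parent_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: coordinates {self.start}-{self.end} "
                f"inconsistent with length {len(self.sequence)}"
            )
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")

    def spans(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end


def cleavage_points(sequence: str, protease: ProteaseRule) -> list[int]:
    """1-based positions i such that the bond after residue i is cut.

    The C-terminus is never listed; the returned positions partition the
    sequence into the fully cleaved (0-missed) peptides.
    """
    pts = []
    for i in range(1, len(sequence)):  # bond between residue i and i+1
        if sequence[i - 1] in protease.cleave_after and sequence[i] not in protease.suppress_before:
            pts.append(i)
    return pts


def digest(
    sequence: str,
    protease: ProteaseRule,
    max_missed: int = 1,
    parent_id: str = "",
) -> list[Peptide]:
    """Fully specific digest with 0..``max_missed`` missed cleavages.

    Returns peptides ordered by start position, then by missed-cleavage
    count.  The 0-missed peptides tile the parent exactly.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = sorted(set(sequence) - STANDARD_AA)
    if bad:
        raise ValueError(f"sequence contains non-standard residue(s): {', '.join(bad)}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")

    # Fragment boundaries: [0, cut_1, ..., cut_k, len]
    bounds = [0] + cleavage_points(sequence, protease) + [len(sequence)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            start, end = bounds[i] + 1, bounds[j]
            peptides.append(
                Peptide(
                    sequence=sequence[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=m,
                    parent_id=parent_id,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def site_spanning_peptides(peptides: list[Peptide], residue_index: int) -> list[Peptide]:
    """Peptides whose 1-based inclusive span covers ``residue_index``.

    Only these peptides carry the identity of the residue at the site and
    are therefore informative for readthrough quantification.  Order is
    preserved; an out-of-range index yields an empty list with a warning.
    """
    out = [p for p in peptides if p.spans(residue_index)]
    if not out:
        warnings.warn(
            f"no peptide spans residue {residue_index}", stacklevel=2
        )
    return out
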