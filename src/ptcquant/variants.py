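"""Proteins with premature termination codons and their readthrough variants.

A premature termination codon (PTC) is an in-frame stop codon (UGA, UAG or
UAA) upstream of the natural stop. During drug-induced stop-codon readthrough
a near-cognate tRNA decodes the stop, inserting one amino acid and letting
translation continue to the natural terminus.  This module represents the
protein-level outcome: a full-length sequence whose PTC residue is replaced
by each candidate amino acid in turn.

Residue indexing is **1-based** throughout the package, matching the standard
variant nomenclature (e.g. G542X is residue 542; its Cys readthrough product
is G542C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "STANDARD_AA",
    "PTC_PLACEHOLDER",
    "ProteinRecord",
    "PtcSite",
    "ReadthroughVariant",
    "near_cognate_amino_acids",
    "apply_readthrough",
    "truncated_sequence",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Placeholder used at an unresolved PTC position in a full-length template.
PTC_PLACEHOLDER = "*"

STOP_CODONS = frozenset({"UGA", "UAG", "UAA"})

_BASES = "ACGU"

# Standard (cytosolic) genetic code, RNA alphabet; stops map to "*".
GENETIC_CODE: dict[str, str] = {}
_CODE_BY_AA = {
    "F": ("UUU", "UUC"),
    "L": ("UUA", "UUG", "CUU", "CUC", "CUA", "CUG"),
    "I": ("AUU", "AUC", "AUA"),
    "M": ("AUG",),
    "V": ("GUU", "GUC", "GUA", "GUG"),
    "S": ("UCU", "UCC", "UCA", "UCG", "AGU", "AGC"),
    "P": ("CCU", "CCC", "CCA", "CCG"),
    "T": ("ACU", "ACC", "ACA", "ACG"),
    "A": ("GCU", "GCC", "GCA", "GCG"),
    "Y": ("UAU", "UAC"),
    "H": ("CAU", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAU", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAU", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("UGU", "UGC"),
    "W": ("UGG",),
    "R": ("CGU", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGU", "GGC", "GGA", "GGG"),
    "*": ("UAA", "UAG", "UGA"),
}
for _aa, _codons in _CODE_BY_AA.items():
    for _c in _codons:
        GENETIC_CODE[_c] = _aa
del _aa, _codons, _c

#: Amino acids validated as UGA readthrough insertions in full-length channel
#: pull-downs: arginine, cysteine and tryptophan.
OBSERVED_UGA_AMINO_ACIDS = frozenset("RCW")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates.

    The alphabet is the 20 standard residues plus ``*`` marking an
    unresolved PTC position in a full-length template.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        allowed = STANDARD_AA | {PTC_PLACEHOLDER}
        bad = sorted(set(self.sequence) - allowed)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {', '.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, index: int) -> str:
        """Residue at 1-based ``index``."""
        if not 1 <= index <= len(self.sequence):
            raise IndexError(
                f"residue index {index} outside 1..{len(self.sequence)}"
            )
        return self.sequence[index - 1]


@dataclass(frozen=True)
class PtcSite:
    """Location and identity of a premature termination codon.

    ``native_aa`` is the residue encoded at this position in the wild-type
    protein (e.g. R for R1162X); ``stop_codon`` is the in-frame stop created
    by the nonsense mutation.
    """

    residue_index: int
    stop_codon: str
    native_aa: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1 (1-based)")
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(
                f"unknown stop codon {self.stop_codon!r}; expected one of "
                f"{sorted(STOP_CODONS)}"
            )
        if self.native_aa not in STANDARD_AA:
            raise ValueError(f"native_aa {self.native_aa!r} is not a standard residue")

    def validate_against(self, protein: ProteinRecord) -> None:
        if self.residue_index > len(protein):
            raise IndexError(
                f"PTC index {self.residue_index} outside protein "
                f"{protein.id!r} (length {len(protein)})"
            )


@dataclass(frozen=True)
class ReadthroughVariant:
    """A full-length readthrough product with one amino acid at the PTC site.

    ``label`` follows missense nomenclature: native residue, 1-based index,
    incorporated residue (R1162C).
    """

    protein: ProteinRecord
    site: PtcSite
    incorporated_aa: str
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.incorporated_aa not in STANDARD_AA:
            raise ValueError(
                f"incorporated_aa {self.incorporated_aa!r} is not a standard residue"
            )
        self.site.validate_against(self.protein)
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.site.native_aa}{self.site.residue_index}{self.incorporated_aa}",
            )

    @property
    def sequence(self) -> str:
        """Base sequence with the PTC residue set to ``incorporated_aa``."""
        i = self.site.residue_index
        return (
            self.protein.sequence[: i - 1]
            + self.incorporated_aa
            + self.protein.sequence[i:]
        )


def near_cognate_amino_acids(stop_codon: str, mode: str = "single-mismatch") -> frozenset[str]:
    """Candidate amino acids inserted at a stop codon by near-cognate tRNAs.

    Parameters
    ----------
    stop_codon
        One of UGA, UAG, UAA.
    mode
        ``"single-mismatch"`` returns the amino acids encoded by every codon
        differing from the stop at exactly one nucleotide position (stop
        codons excluded) — the full near-cognate decoding set.
        ``"observed-UGA"`` returns the experimentally validated UGA insertion
        set {R, C, W}; it is only defined for UGA.

    Returns
    -------
    frozenset of one-letter amino-acid codes.
    """
    if stop_codon not in STOP_CODONS:
        raise ValueError(
            f"unknown stop codon {stop_codon!r}; expected one of {sorted(STOP_CODONS)}"
        )
    if mode == "observed-UGA":
        if stop_codon != "UGA":
            raise ValueError('mode "observed-UGA" is only valid for the UGA stop codon')
        return OBSERVED_UGA_AMINO_ACIDS
    if mode != "single-mismatch":
        raise ValueError(f"unknown enumeration mode {mode!r}")
    out = set()
    for pos in range(3):
        for base in _BASES:
            if base == stop_codon[pos]:
                continue
            codon = stop_codon[:pos] + base + stop_codon[pos + 1 :]
            aa = GENETIC_CODE[codon]
            if aa != "*":
                out.add(aa)
    return frozenset(out)


def apply_readthrough(protein: ProteinRecord, site: PtcSite, aa: str) -> ReadthroughVariant:
    """Substitute ``aa`` at the PTC site, yielding a full-length variant."""
    site.validate_against(protein)
    if aa not in STANDARD_AA:
        raise ValueError(f"{aa!r} is not a standard residue")
    return ReadthroughVariant(protein=protein, site=site, incorporated_aa=aa)


def truncated_sequence(protein: ProteinRecord, site: PtcSite) -> str:
    """Sequence of the truncated product terminating at the PTC.

    Translation stops at the PTC, so the product ends at residue
    ``residue_index - 1``.
    """
    site.validate_against(protein)
    return protein.sequence[: site.residue_index - 1]
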