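"""Monoisotopic peptide masses and precursor m/z.

Residue masses come from pyteomics' standard monoisotopic table; the search
conventions used throughout are fixed cysteine carbamidomethylation
(+57.021464 Da, iodoacetamide alkylation) and variable methionine oxidation
(+15.994915 Da).  Average masses are not used anywhere: precursor windows
and target lists are defined for high-resolution Orbitrap survey scans.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

from .variants import STANDARD_AA

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MASS",
    "ModificationSpec",
    "CARBAMIDOMETHYL",
    "OXIDATION_MET",
    "DEFAULT_MODS",
    "monoisotopic_mass",
    "mz",
    "neutral_mass",
    "mod_state_label",
]

#: Monoisotopic mass of H2O (Da).
WATER = 18.0105646863
#: Mass of a proton (Da).
PROTON = 1.00727646688

#: Monoisotopic residue masses for the 20 standard amino acids (Da).
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_AA}


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable post-translational/chemical modification.

    Fixed modifications apply to every instance of ``target_residue``;
    variable modifications apply to 0..n instances, where n is the number of
    target residues in the peptide.
    """

    name: str
    target_residue: str
    delta_mass: float
    fixed: bool

    def __post_init__(self) -> None:
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError("delta_mass must be finite")


CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", "C", 57.021464, fixed=True)
OXIDATION_MET = ModificationSpec("oxidation", "M", 15.994915, fixed=False)

#: The default search-convention modification set.
DEFAULT_MODS: tuple[ModificationSpec, ...] = (CARBAMIDOMETHYL, OXIDATION_MET)


def monoisotopic_mass(
    peptide: str,
    mods: tuple[ModificationSpec, ...] | list[ModificationSpec] = (),
    n_variable_applied: int = 0,
) -> float:
    """Neutral monoisotopic mass of ``peptide`` in Da.

    mass = sum of residue masses + water + fixed-mod deltas
           + ``n_variable_applied`` x variable-mod delta.

    At most one variable modification spec may be supplied; supplying the
    same fixed modification twice (which would double-count its delta) is an
    error, as is applying a variable modification to more residues than the
    peptide contains.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = sorted(set(peptide) - STANDARD_AA)
    if bad:
        raise ValueError(f"unknown residue(s): {', '.join(bad)}")

    fixed_targets: set[str] = set()
    variable: list[ModificationSpec] = []
    total = sum(RESIDUE_MASS[aa] for aa in peptide) + WATER
    for spec in mods:
        if spec.fixed:
            if spec.target_residue in fixed_targets:
                raise ValueError(
                    f"fixed modification on {spec.target_residue!r} specified twice"
                )
            fixed_targets.add(spec.target_residue)
            total += spec.delta_mass * peptide.count(spec.target_residue)
        else:
            variable.append(spec)

    if n_variable_applied:
        if len(variable) != 1:
            raise ValueError(
                "n_variable_applied requires exactly one variable modification spec"
            )
        spec = variable[0]
        n_targets = peptide.count(spec.target_residue)
        if n_variable_applied > n_targets:
            raise ValueError(
                f"cannot apply {spec.name} to {n_variable_applied} residues; "
                f"peptide has only {n_targets} {spec.target_residue!r}"
            )
        if n_variable_applied < 0:
            raise ValueError("n_variable_applied must be >= 0")
        total += n_variable_applied * spec.delta_mass
    return total


def mz(mass: float, charge: int) -> float:
    """Mass-to-charge ratio of the [M + charge·H]^charge+ ion."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    """Neutral mass recovered from an observed m/z and charge."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return charge * mz_value - charge * PROTON


def mod_state_label(n_oxidation: int = 0) -> str:
    """Canonical modification-state label used in target lists and PSM tables.

    Fixed carbamidomethylation is implied and not part of the label; the
    label records only the variable oxidized-Met count (empty string for the
    unmodified form).
    """
    if n_oxidation < 0:
        raise ValueError("n_oxidation must be >= 0")
    return "" if n_oxidation == 0 else f"oxidation x{n_oxidation}"
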