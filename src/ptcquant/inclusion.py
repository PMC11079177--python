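"""Targeted precursor inclusion lists and detectability audits.

An inclusion (targeted mass) list is the set of precursor m/z / charge
targets the instrument preferentially selects for fragmentation.  The list
built here is *non-exclusive* in two senses: the instrument may still pick
other ions, and rows violating instrument constraints are retained with
explanatory flags rather than dropped — so a design review can see exactly
which variant/protease combinations are invisible and why.

The central audit reproduces a real protease blind spot: when the residue
preceding a PTC context is a tryptic cleavage site and the incorporated
amino acid is itself K/R, the fully cleaved site-spanning tryptic peptide
can fall below the peak-list mass floor (500 Da) and the variant evades
detection; switching to chymotrypsin extends the spanning peptide past the
floor and restores detectability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .digest import Peptide, ProteaseRule, digest, site_spanning_peptides
from .mass import DEFAULT_MODS, ModificationSpec, mod_state_label, monoisotopic_mass, mz
from .variants import ReadthroughVariant

__all__ = [
    "InstrumentSettings",
    "TargetIon",
    "DetectabilityReport",
    "FLAG_MASS_BELOW_PEAKLIST_MIN",
    "FLAG_MASS_ABOVE_PEAKLIST_MAX",
    "FLAG_MZ_OUT_OF_SURVEY_WINDOW",
    "FLAG_NO_SITE_SPANNING_PEPTIDE",
    "build_inclusion_list",
    "detectability_audit",
]

FLAG_MASS_BELOW_PEAKLIST_MIN = "mass_below_peaklist_min"
FLAG_MASS_ABOVE_PEAKLIST_MAX = "mass_above_peaklist_max"
FLAG_MZ_OUT_OF_SURVEY_WINDOW = "mz_out_of_survey_window"
FLAG_NO_SITE_SPANNING_PEPTIDE = "no_site_spanning_peptide"


@dataclass(frozen=True)
class InstrumentSettings:
    """Acquisition and peak-list constraints a target must satisfy.

    Defaults correspond to an Orbitrap shotgun setup: survey scans over
    m/z 300-1400, precursors above charge 5 excluded, peak lists restricted
    to 500-6000 Da, precursor/fragment tolerances of 10 ppm / 0.6 Da.
    """

    survey_mz_min: float = 300.0
    survey_mz_max: float = 1400.0
    max_charge: int = 5
    peaklist_mass_min: float = 500.0
    peaklist_mass_max: float = 6000.0
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.6

    def __post_init__(self) -> None:
        if self.survey_mz_min >= self.survey_mz_max:
            raise ValueError("survey window: min must be < max")
        if self.peaklist_mass_min >= self.peaklist_mass_max:
            raise ValueError("peak-list mass window: min must be < max")
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_charge < 1:
            raise ValueError("max_charge must be >= 1")

    def flags_for(self, mass: float, mz_value: float) -> frozenset[str]:
        """Constraint violations for a neutral mass / observed m/z pair."""
        out = set()
        if mass < self.peaklist_mass_min:
            out.add(FLAG_MASS_BELOW_PEAKLIST_MIN)
        if mass > self.peaklist_mass_max:
            out.add(FLAG_MASS_ABOVE_PEAKLIST_MAX)
        if not self.survey_mz_min <= mz_value <= self.survey_mz_max:
            out.add(FLAG_MZ_OUT_OF_SURVEY_WINDOW)
        return frozenset(out)


@dataclass(frozen=True)
class TargetIon:
    """One row of the inclusion list.

    ``peptide``/``charge``/``mz`` are ``None`` only for the synthetic row
    recording a variant with no site-spanning peptide at all.
    """

    variant_label: str
    peptide: Peptide | None
    charge: int | None
    mz: float | None
    mod_state: str
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DetectabilityReport:
    """Audit verdict for one variant under one protease.

    ``detectable`` is true iff at least one site-spanning peptide /
    charge / modification-state combination violates no instrument
    constraint; otherwise ``reasons`` names the limiting constraint(s) of
    the least-violating candidate.
    """

    variant_label: str
    protease: str
    best_peptide: Peptide | None
    detectable: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def _mod_states(
    peptide: Peptide,
    mods: tuple[ModificationSpec, ...],
    max_variable: int,
):
    """Yield (mod_state_label, n_variable) for every enumerated mod form."""
    variable = [m for m in mods if not m.fixed]
    if not variable:
        yield mod_state_label(0), 0
        return
    spec = variable[0]
    n_targets = peptide.sequence.count(spec.target_residue)
    for n in range(min(n_targets, max_variable) + 1):
        yield mod_state_label(n), n


def build_inclusion_list(
    variants: list[ReadthroughVariant],
    protease: ProteaseRule,
    settings: InstrumentSettings | None = None,
    charges: tuple[int, ...] = (2, 3),
    max_missed: int = 1,
    mods: tuple[ModificationSpec, ...] = DEFAULT_MODS,
    max_variable: int = 2,
) -> list[TargetIon]:
    """Targeted precursor list covering every readthrough variant.

    Each variant's full-length sequence is digested, only PTC-site-spanning
    peptides are kept, modification states and charges are expanded, and
    every row is checked against ``settings``.  Rows identical in
    (sequence, mod state, charge) across variants are merged, with the
    contributing variant labels joined by "/".  Flagged rows are retained.
    """
    if not variants:
        raise ValueError("empty variant list")
    settings = settings or InstrumentSettings()
    if any(z < 1 or z > settings.max_charge for z in charges):
        raise ValueError(
            f"charges must lie in 1..{settings.max_charge} (got {sorted(charges)})"
        )

    merged: dict[tuple[str, str, int], TargetIon] = {}
    no_span_rows: list[TargetIon] = []
    for variant in variants:
        peps = digest(
            variant.sequence, protease, max_missed=max_missed, parent_id=variant.label
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spanning = site_spanning_peptides(peps, variant.site.residue_index)
        if not spanning:
            no_span_rows.append(
                TargetIon(
                    variant_label=variant.label,
                    peptide=None,
                    charge=None,
                    mz=None,
                    mod_state="",
                    flags=frozenset({FLAG_NO_SITE_SPANNING_PEPTIDE}),
                )
            )
            continue
        for pep in spanning:
            for state, n_ox in _mod_states(pep, mods, max_variable):
                mass = monoisotopic_mass(pep.sequence, mods, n_ox)
                for z in charges:
                    key = (pep.sequence, state, z)
                    if key in merged:
                        prev = merged[key]
                        labels = prev.variant_label.split("/")
                        if variant.label not in labels:
                            labels.append(variant.label)
                        merged[key] = TargetIon(
                            variant_label="/".join(labels),
                            peptide=prev.peptide,
                            charge=prev.charge,
                            mz=prev.mz,
                            mod_state=prev.mod_state,
                            flags=prev.flags,
                        )
                        continue
                    mz_value = mz(mass, z)
                    merged[key] = TargetIon(
                        variant_label=variant.label,
                        peptide=pep,
                        charge=z,
                        mz=mz_value,
                        mod_state=state,
                        flags=settings.flags_for(mass, mz_value),
                    )
    rows = list(merged.values()) + no_span_rows
    rows.sort(key=lambda t: (t.variant_label, t.mz if t.mz is not None else -1.0))
    return rows


def detectability_audit(
    variant: ReadthroughVariant,
    proteases: list[ProteaseRule],
    settings: InstrumentSettings | None = None,
    charges: tuple[int, ...] | None = None,
    max_missed: int = 0,
    mods: tuple[ModificationSpec, ...] = DEFAULT_MODS,
    max_variable: int = 2,
) -> list[DetectabilityReport]:
    """Audit whether each protease can reveal the variant at all.

    The audit defaults to complete digestion (``max_missed=0``): detection
    must not depend on missed-cleavage forms, which are substoichiometric
    byproducts whose yield is not under the designer's control.  Charges
    default to 1..max_charge — the audit asks whether *any* admissible
    charge state works, not which charges the target list should carry.
    """
    if not proteases:
        raise ValueError("at least one protease is required")
    settings = settings or InstrumentSettings()
    if charges is None:
        charges = tuple(range(1, settings.max_charge + 1))

    reports = []
    for protease in proteases:
        peps = digest(
            variant.sequence, protease, max_missed=max_missed, parent_id=variant.label
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spanning = site_spanning_peptides(peps, variant.site.residue_index)
        if not spanning:
            reports.append(
                DetectabilityReport(
                    variant_label=variant.label,
                    protease=protease.name,
                    best_peptide=None,
                    detectable=False,
                    reasons=(FLAG_NO_SITE_SPANNING_PEPTIDE,),
                )
            )
            continue
        best: tuple[int, Peptide, frozenset[str]] | None = None
        for pep in spanning:
            # Flags common to every charge/mod state of this peptide are its
            # limiting constraints; a peptide is usable if some combination
            # is flag-free.
            per_combo = []
            for state, n_ox in _mod_states(pep, mods, max_variable):
                mass = monoisotopic_mass(pep.sequence, mods, n_ox)
                for z in charges:
                    per_combo.append(settings.flags_for(mass, mz(mass, z)))
            pep_best = min(per_combo, key=len)
            if best is None or len(pep_best) < best[0]:
                best = (len(pep_best), pep, pep_best)
        assert best is not None
        n_flags, pep, flags = best
        reports.append(
            DetectabilityReport(
                variant_label=variant.label,
                protease=protease.name,
                best_peptide=pep,
                detectable=n_flags == 0,
                reasons=tuple(sorted(flags)),
            )
        )
    return reports
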