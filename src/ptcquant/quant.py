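"""Spectral-count quantification of readthrough amino-acid incorporation.

The estimator is deliberately simple, mirroring common spectral-counting
practice:

    relative abundance of variant a
        = spectral counts of site-spanning peptides carrying a
        / total spectral counts of site-spanning peptides over the
          enumeration set (default {R, C, W} for UGA)

Counts are *uncorrected* for per-peptide detectability differences (ionization
efficiency, length, charge); when detectabilities are unequal the estimate is
biased toward the better-detected variant, and reports state this.

Fractions are computed per replicate and then averaged (means +/- s.e.m.
across independent experiments); pooled-count estimation is available as an
option.  Uncertainty comes from a percentile bootstrap; when raw counts are
available, a hierarchical (two-stage) bootstrap additionally resamples
spectral counts within each drawn replicate, which restores near-nominal
interval coverage at the small replicate numbers (3-4) typical of these
experiments.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import ProteaseRule, digest, site_spanning_peptides
from .variants import ReadthroughVariant

__all__ = [
    "PsmRecord",
    "VariantCountTable",
    "AbundanceEstimate",
    "assign_peptides_to_variants",
    "relative_abundance",
    "pooled_abundance",
    "aggregate_replicates",
]

PSM_COLUMNS = ["sample_id", "replicate", "peptide_sequence", "mod_state", "spectral_count"]

_NON_RESIDUE = re.compile(r"[^A-Za-z]")


@dataclass(frozen=True)
class PsmRecord:
    """One row of a spectral-count export."""

    sample_id: str
    replicate: int
    peptide_sequence: str
    mod_state: str
    spectral_count: int

    def __post_init__(self) -> None:
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be >= 0")
        if not self.peptide_sequence:
            raise ValueError("empty peptide sequence")


@dataclass
class VariantCountTable:
    """Summed site-spanning spectral counts per (replicate, incorporated aa).

    ``counts`` is a replicate x amino-acid integer DataFrame.  ``exclusions``
    tallies PSMs that carried no variant information (non-spanning matches or
    sequences matching no theoretical peptide).  Counts are raw and
    uncorrected for detectability.
    """

    counts: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class AbundanceEstimate:
    """Replicate-aggregated incorporation fraction for one amino acid."""

    incorporated_aa: str
    fraction: float
    sem: float
    ci_low: float
    ci_high: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.fraction <= self.ci_high + 1e-12):
            raise ValueError("fraction must lie within [ci_low, ci_high]")


def _strip_mods(sequence: str) -> str:
    """Bare residue string: inline mod annotations removed, uppercased."""
    return _NON_RESIDUE.sub("", sequence).upper()


def _psm_frame(psms) -> pd.DataFrame:
    if isinstance(psms, pd.DataFrame):
        missing = [c for c in PSM_COLUMNS if c not in psms.columns]
        if missing:
            raise ValueError(f"PSM table missing column(s): {', '.join(missing)}")
        return psms
    return pd.DataFrame([vars(p) for p in psms], columns=PSM_COLUMNS)


def assign_peptides_to_variants(
    psms,
    variants: list[ReadthroughVariant],
    protease: ProteaseRule,
    max_missed: int = 1,
) -> VariantCountTable:
    """Tally spectral counts of site-spanning peptides per variant.

    A PSM contributes iff its bare sequence exactly matches a theoretical
    site-spanning peptide (0..``max_missed`` missed cleavages) of exactly one
    variant.  Modified and unmodified forms of one sequence are summed.
    Non-spanning or unmatched PSMs are excluded and tallied in the exclusion
    report.  I and L are *not* equated.

    ``psms`` may be a list of :class:`PsmRecord` or a DataFrame with the
    documented PSM columns.
    """
    if not variants:
        raise ValueError("empty variant list")
    sites = {(v.protein.id, v.site.residue_index) for v in variants}
    if len(sites) > 1:
        raise ValueError(f"variants must share one PTC site; got {sorted(sites)}")
    aas = [v.incorporated_aa for v in variants]
    if len(set(aas)) != len(aas):
        raise ValueError("duplicate incorporated amino acids among variants")

    spanning_map: dict[str, str] = {}  # peptide sequence -> incorporated aa
    nonspanning: set[str] = set()
    for v in variants:
        peps = digest(v.sequence, protease, max_missed=max_missed, parent_id=v.label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            span = site_spanning_peptides(peps, v.site.residue_index)
        span_seqs = {p.sequence for p in span}
        nonspanning.update(p.sequence for p in peps if p.sequence not in span_seqs)
        for seq in span_seqs:
            if seq in spanning_map and spanning_map[seq] != v.incorporated_aa:
                raise ValueError(
                    f"peptide {seq!r} matches site-spanning digests of more than "
                    "one variant; assignment is ambiguous"
                )
            spanning_map[seq] = v.incorporated_aa

    frame = _psm_frame(psms)
    replicates = sorted(frame["replicate"].unique())
    counts = pd.DataFrame(0, index=replicates, columns=sorted(set(aas)), dtype=int)
    counts.index.name = "replicate"
    exclusions = {"non_spanning": 0, "unmatched": 0}
    for row in frame.itertuples(index=False):
        seq = _strip_mods(row.peptide_sequence)
        sc = int(row.spectral_count)
        if sc < 0:
            raise ValueError("negative spectral count")
        aa = spanning_map.get(seq)
        if aa is not None:
            counts.loc[row.replicate, aa] += sc
        elif seq in nonspanning:
            exclusions["non_spanning"] += 1
        else:
            exclusions["unmatched"] += 1
    return VariantCountTable(counts=counts, exclusions=exclusions)


def relative_abundance(counts: VariantCountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-replicate incorporation fractions.

    fraction(aa) = count(aa) / total counts over the enumeration set, per
    replicate.  Replicates with zero total are dropped with a warning; an
    all-zero table is an error (the ratio is undefined).
    """
    frame = counts.counts if isinstance(counts, VariantCountTable) else counts
    totals = frame.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if len(zero) == len(frame):
        raise ValueError("all replicates have zero total counts; fractions undefined")
    if zero:
        warnings.warn(
            f"dropping replicate(s) with zero total counts: {zero}", stacklevel=2
        )
    kept = frame.loc[totals > 0]
    return kept.div(kept.sum(axis=1), axis=0)


def pooled_abundance(counts: VariantCountTable | pd.DataFrame) -> pd.Series:
    """Fractions from counts pooled over replicates (alternative mode)."""
    frame = counts.counts if isinstance(counts, VariantCountTable) else counts
    pooled = frame.sum(axis=0)
    total = pooled.sum()
    if total == 0:
        raise ValueError("zero total counts; fractions undefined")
    return pooled / total


def aggregate_replicates(
    fractions: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    counts: pd.DataFrame | None = None,
    ci_level: float = 0.95,
) -> list[AbundanceEstimate]:
    """Mean +/- s.e.m. across replicates with a bootstrap confidence interval.

    Replicates are resampled with replacement (percentile method).  If the
    raw count table is supplied via ``counts``, each drawn replicate's counts
    are additionally resampled multinomially at its observed depth — a
    two-stage bootstrap that accounts for counting noise and keeps interval
    coverage near nominal when only 3-4 replicates exist.  Without counts,
    the plain percentile bootstrap over replicate fractions is used (it is
    degenerate, correctly, when all replicates are identical).
    """
    if fractions.empty:
        raise ValueError("no replicates to aggregate")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    frac = fractions.to_numpy(dtype=float)
    n_rep, n_aa = frac.shape
    mean = frac.mean(axis=0)
    sem = frac.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else np.zeros(n_aa)

    idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
    if counts is not None:
        counts = counts.loc[fractions.index, fractions.columns]
        depths = counts.sum(axis=1).to_numpy()
        draws = rng.multinomial(depths[idx], frac[idx]).astype(float)
        boot = (draws / draws.sum(axis=2, keepdims=True)).mean(axis=1)
    else:
        boot = frac[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.percentile(boot, 100 * alpha, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha), axis=0)

    return [
        AbundanceEstimate(
            incorporated_aa=aa,
            fraction=float(mean[j]),
            sem=float(sem[j]),
            ci_low=float(min(lo[j], mean[j])),
            ci_high=float(max(hi[j], mean[j])),
            n_replicates=n_rep,
        )
        for j, aa in enumerate(fractions.columns)
    ]
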