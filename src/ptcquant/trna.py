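"""Comparative tRNA microarrays to absolute per-codon tRNA fractions.

A comparative microarray hybridizes a sample tRNA pool against a reference
pool (two fluorescence channels) on probes complementary to full-length
tRNAs.  Spike-in probes — in-vitro transcripts added in equal amounts to
both pools — absorb the channel scale factors.  The per-isoacceptor
comparative ratios are anchored to an absolute reference abundance table
(fraction of total tRNA in the reference cell line), split across the codons
each isoacceptor reads in proportion to a codon-usage index, summed per
codon and normalized to 100%.

Wobble decoding rules are never inferred here: codon pairing comes entirely
from the user-supplied decoding map.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SIGNAL_COLUMNS",
    "normalize_by_spikeins",
    "to_absolute",
    "isoacceptor_to_codon",
    "summarize_codon_table",
    "compare_cell_models",
]

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["probe", "replicate", "sample_signal", "reference_signal", "is_spikein"]


def _check_columns(frame: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} missing column(s): {', '.join(missing)}")


def normalize_by_spikeins(signals: pd.DataFrame, min_spikeins: int = 3) -> pd.DataFrame:
    """Spike-in-normalized comparative ratios per isoacceptor and replicate.

    ratio(probe) = (sample/reference) / median over spike-ins of
    (sample/reference), computed within each replicate.  Probes with a
    non-positive signal in either channel are dropped (count logged) rather
    than imputed; at least ``min_spikeins`` usable spike-ins are required per
    replicate.  Spike-in rows are excluded from the output.
    """
    _check_columns(signals, SIGNAL_COLUMNS, "array signal table")
    usable = (signals["sample_signal"] > 0) & (signals["reference_signal"] > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropping %d probe row(s) with non-positive signal", n_dropped)
    frame = signals.loc[usable].copy()
    frame["channel_ratio"] = frame["sample_signal"] / frame["reference_signal"]

    out = []
    for rep, group in frame.groupby("replicate"):
        spike = group.loc[group["is_spikein"].astype(bool), "channel_ratio"]
        if len(spike) < min_spikeins:
            raise ValueError(
                f"replicate {rep}: only {len(spike)} usable spike-in(s); "
                f"need >= {min_spikeins}"
            )
        scale = spike.median()
        probes = group.loc[~group["is_spikein"].astype(bool)]
        out.append(
            pd.DataFrame(
                {
                    "isoacceptor": probes["probe"].to_numpy(),
                    "replicate": rep,
                    "ratio": (probes["channel_ratio"] / scale).to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def to_absolute(ratios: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Anchor comparative ratios to the reference absolute abundance table.

    absolute(isoacceptor) = ratio x reference fraction, renormalized per
    replicate so the sample's isoacceptor fractions sum to 100%.
    """
    _check_columns(ratios, ["isoacceptor", "replicate", "ratio"], "ratio table")
    _check_columns(reference, ["isoacceptor", "fraction"], "reference table")
    ref = reference.set_index("isoacceptor")["fraction"]
    missing = sorted(set(ratios["isoacceptor"]) - set(ref.index))
    if missing:
        raise ValueError(
            f"isoacceptor(s) absent from reference table: {', '.join(map(str, missing))}"
        )
    frame = ratios.copy()
    frame["fraction"] = frame["ratio"] * ref.loc[frame["isoacceptor"]].to_numpy()
    frame["fraction"] = (
        100.0
        * frame["fraction"]
        / frame.groupby("replicate")["fraction"].transform("sum")
    )
    return frame[["isoacceptor", "replicate", "fraction"]]


def isoacceptor_to_codon(absolute: pd.DataFrame, decoding_map: pd.DataFrame) -> pd.DataFrame:
    """Apportion isoacceptor fractions to codons and sum per codon.

    Each isoacceptor's fraction is split across the codons it reads,
    proportionally to the codons' usage-index weights; contributions from
    multiple isoacceptors reading one codon are summed; the per-replicate
    codon fractions are renormalized to 100%.
    """
    _check_columns(absolute, ["isoacceptor", "replicate", "fraction"], "abundance table")
    _check_columns(decoding_map, ["isoacceptor", "codon", "usage_weight"], "decoding map")
    if (decoding_map["usage_weight"] < 0).any():
        raise ValueError("usage weights must be >= 0")
    weight_sums = decoding_map.groupby("isoacceptor")["usage_weight"].sum()
    zero = weight_sums[weight_sums == 0].index.tolist()
    if zero:
        raise ValueError(
            "isoacceptor(s) with all-zero usage weights: " + ", ".join(map(str, zero))
        )
    missing = sorted(set(absolute["isoacceptor"]) - set(weight_sums.index))
    if missing:
        raise ValueError(
            f"decoding map does not cover isoacceptor(s): {', '.join(map(str, missing))}"
        )

    dmap = decoding_map.copy()
    dmap["share"] = dmap["usage_weight"] / weight_sums.loc[dmap["isoacceptor"]].to_numpy()
    joined = absolute.merge(dmap[["isoacceptor", "codon", "share"]], on="isoacceptor")
    joined["fraction"] = joined["fraction"] * joined["share"]
    codon = (
        joined.groupby(["replicate", "codon"], as_index=False)["fraction"].sum()
    )
    codon["fraction"] = (
        100.0 * codon["fraction"] / codon.groupby("replicate")["fraction"].transform("sum")
    )
    return codon[["codon", "replicate", "fraction"]]


def summarize_codon_table(codon_table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.e.m. of per-codon fractions across replicates."""
    _check_columns(codon_table, ["codon", "replicate", "fraction"], "codon table")
    g = codon_table.groupby("codon")["fraction"]
    out = g.agg(mean="mean", sem="sem", n_replicates="count").reset_index()
    out["sem"] = out["sem"].fillna(0.0)
    return out


def compare_cell_models(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    codons_of_interest: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-codon two-sample comparison of two cell models.

    Welch's t-test on replicate-level codon fractions.  When
    ``codons_of_interest`` names a small a-priori set (e.g. the Arg/Cys/Trp
    decoders relevant to UGA readthrough), tests are reported uncorrected;
    when all codons are tested, a Bonferroni correction is applied.  The
    chosen policy is recorded in the ``correction`` column.
    """
    for t, name in ((table_a, "table A"), (table_b, "table B")):
        _check_columns(t, ["codon", "replicate", "fraction"], name)
        if t["replicate"].nunique() < 2:
            raise ValueError(f"{name}: need >= 2 replicates for a two-sample test")

    codons = sorted(set(table_a["codon"]) & set(table_b["codon"]))
    if codons_of_interest is not None:
        codons = [c for c in codons if c in codons_of_interest]
        correction = "none (a-priori codon set)"
        n_tests = 1
    else:
        correction = "bonferroni"
        n_tests = len(codons)

    rows = []
    for codon in codons:
        a = table_a.loc[table_a["codon"] == codon, "fraction"].to_numpy(dtype=float)
        b = table_b.loc[table_b["codon"] == codon, "fraction"].to_numpy(dtype=float)
        diff = a.mean() - b.mean()
        sem_diff = float(np.sqrt(stats.sem(a) ** 2 + stats.sem(b) ** 2))
        if np.allclose(a, a[0]) and np.allclose(b, b[0]):
            # degenerate: no within-group variance
            p = 1.0 if np.isclose(diff, 0.0) else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "codon": codon,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "diff": diff,
                "sem_diff": sem_diff,
                "pvalue": p,
                "pvalue_adjusted": min(1.0, p * n_tests),
                "correction": correction,
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["pvalue_adjusted"] < alpha
    return out
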