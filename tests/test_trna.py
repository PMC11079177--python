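"""Comparative-array normalization, codon conversion and model comparison."""

import numpy as np
import pandas as pd
import pytest

from ptcquant.trna import (
    compare_cell_models,
    isoacceptor_to_codon,
    normalize_by_spikeins,
    summarize_codon_table,
    to_absolute,
)


def signal_rows(entries):
    return pd.DataFrame(
        entries, columns=["probe", "replicate", "sample_signal", "reference_signal", "is_spikein"]
    )


def test_spikein_scale_cancels():
    sig = signal_rows(
        [("S1", 1, 20, 10, True), ("S2", 1, 40, 20, True), ("S3", 1, 60, 30, True),
         ("tRNA-A", 1, 8, 4, False)]
    )
    out = normalize_by_spikeins(sig)
    assert out.loc[0, "ratio"] == pytest.approx(1.0)


def test_spikein_median_example():
    sig = signal_rows(
        [("S1", 1, 18, 10, True), ("S2", 1, 20, 10, True), ("S3", 1, 22, 10, True),
         ("tRNA-A", 1, 10, 10, False)]
    )
    out = normalize_by_spikeins(sig)
    assert out.loc[0, "ratio"] == pytest.approx(0.5)


def test_too_few_spikeins_and_dropped_probes():
    sig = signal_rows(
        [("S1", 1, 20, 10, True), ("S2", 1, 0, 10, True), ("S3", 1, 30, 15, True),
         ("tRNA-A", 1, 8, 4, False)]
    )
    with pytest.raises(ValueError, match="spike-in"):
        normalize_by_spikeins(sig)


def test_to_absolute_identity_and_forced_case():
    ref = pd.DataFrame({"isoacceptor": list("ABCD"), "fraction": [25.0] * 4})
    ratios = pd.DataFrame({"isoacceptor": list("ABCD"), "replicate": 1, "ratio": [1.0] * 4})
    out = to_absolute(ratios, ref)
    assert np.allclose(out["fraction"], 25.0)
    ratios.loc[0, "ratio"] = 2.0
    out = to_absolute(ratios, ref)
    by_iso = out.set_index("isoacceptor")["fraction"]
    assert by_iso["A"] == pytest.approx(40.0)
    assert by_iso["B"] == pytest.approx(20.0)
    assert out["fraction"].sum() == pytest.approx(100.0)


def test_to_absolute_missing_isoacceptor():
    ref = pd.DataFrame({"isoacceptor": ["A"], "fraction": [100.0]})
    ratios = pd.DataFrame({"isoacceptor": ["A", "B"], "replicate": 1, "ratio": [1.0, 1.0]})
    with pytest.raises(ValueError, match="absent from reference"):
        to_absolute(ratios, ref)


def test_usage_weight_split_and_summation():
    absolute = pd.DataFrame(
        {"isoacceptor": ["I1", "I2"], "replicate": [1, 1], "fraction": [10.0, 90.0]}
    )
    dmap = pd.DataFrame(
        [("I1", "AAA", 3), ("I1", "AAG", 1), ("I2", "AAA", 1)],
        columns=["isoacceptor", "codon", "usage_weight"],
    )
    out = isoacceptor_to_codon(absolute, dmap).set_index("codon")["fraction"]
    # I1 splits 10% as 7.5/2.5; I2 contributes 90% to AAA; total renormalized (already 100)
    assert out["AAA"] == pytest.approx(97.5)
    assert out["AAG"] == pytest.approx(2.5)


def test_zero_weight_isoacceptor_rejected():
    absolute = pd.DataFrame({"isoacceptor": ["I1"], "replicate": [1], "fraction": [100.0]})
    dmap = pd.DataFrame(
        [("I1", "AAA", 0), ("I1", "AAG", 0)],
        columns=["isoacceptor", "codon", "usage_weight"],
    )
    with pytest.raises(ValueError, match="all-zero usage weights"):
        isoacceptor_to_codon(absolute, dmap)


def test_codon_table_sums_to_100(decoding_fixture):
    dmap, reference, _ = decoding_fixture
    rng = np.random.default_rng(5)
    ratios = pd.DataFrame(
        {
            "isoacceptor": np.tile(reference["isoacceptor"], 3),
            "replicate": np.repeat([1, 2, 3], len(reference)),
            "ratio": rng.uniform(0.5, 2.0, 3 * len(reference)),
        }
    )
    codon = isoacceptor_to_codon(to_absolute(ratios, reference), dmap)
    sums = codon.groupby("replicate")["fraction"].sum()
    assert np.allclose(sums, 100.0, atol=1e-6)


def test_summary_sem():
    table = pd.DataFrame(
        {"codon": ["AAA"] * 2, "replicate": [1, 2], "fraction": [40.0, 60.0]}
    )
    out = summarize_codon_table(table)
    assert out.loc[0, "mean"] == pytest.approx(50.0)
    assert out.loc[0, "sem"] == pytest.approx(10.0)


def test_compare_identical_tables_nothing_significant():
    table = pd.DataFrame(
        {
            "codon": ["AAA", "AAA", "CCC", "CCC"],
            "replicate": [1, 2, 1, 2],
            "fraction": [60.0, 61.0, 40.0, 39.0],
        }
    )
    out = compare_cell_models(table, table)
    assert np.allclose(out["diff"], 0.0)
    assert not out["significant"].any()


def test_compare_flags_large_shift():
    rng = np.random.default_rng(0)
    rows_a, rows_b = [], []
    for rep in range(1, 4):
        for codon, mean in (("AAA", 50.0), ("CCC", 50.0)):
            rows_a.append({"codon": codon, "replicate": rep, "fraction": mean + rng.normal(0, 1)})
            shift = 15.0 if codon == "AAA" else 0.0  # ~15 within-group s.d.
            rows_b.append({"codon": codon, "replicate": rep, "fraction": mean + shift + rng.normal(0, 1)})
    out = compare_cell_models(
        pd.DataFrame(rows_a), pd.DataFrame(rows_b), codons_of_interest={"AAA", "CCC"}
    ).set_index("codon")
    assert bool(out.loc["AAA", "significant"])
    assert not bool(out.loc["CCC", "significant"])


def test_compare_requires_replicates():
    one = pd.DataFrame({"codon": ["AAA"], "replicate": [1], "fraction": [100.0]})
    with pytest.raises(ValueError, match="replicates"):
        compare_cell_models(one, one)
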