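"""Spectral-count assignment, relative abundance and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptcquant.digest import CHYMOTRYPSIN
from ptcquant.quant import (
    PsmRecord,
    aggregate_replicates,
    assign_peptides_to_variants,
    pooled_abundance,
    relative_abundance,
)
from ptcquant.synth import SimulationConfig, simulate_psm_table


def make_psm(seq, count, replicate=1):
    return PsmRecord("s", replicate, seq, "", count)


@pytest.fixture()
def chymo_peptides(blindspot):
    """Site-spanning chymotryptic peptide per incorporated amino acid."""
    from ptcquant.inclusion import detectability_audit

    _, _, variants = blindspot
    return {
        aa: detectability_audit(v, [CHYMOTRYPSIN])[0].best_peptide.sequence
        for aa, v in variants.items()
    }


def test_worked_assignment_example(blindspot, chymo_peptides):
    _, _, variants = blindspot
    psms = [
        make_psm(chymo_peptides["R"], 5),
        make_psm(chymo_peptides["C"], 13),
        make_psm(chymo_peptides["W"], 2),
    ]
    table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
    assert table.counts.loc[1].to_dict() == {"C": 13, "R": 5, "W": 2}
    fractions = relative_abundance(table)
    assert fractions.loc[1].to_dict() == pytest.approx({"C": 0.65, "R": 0.25, "W": 0.10})


def test_non_spanning_and_unmatched_psms_excluded(blindspot, chymo_peptides):
    _, site, variants = blindspot
    from ptcquant.digest import digest

    downstream = next(
        p.sequence
        for p in digest(variants["C"].sequence, CHYMOTRYPSIN, 1)
        if p.start > site.residue_index
    )
    psms = [
        make_psm(chymo_peptides["C"], 4),
        make_psm(downstream, 9),
        make_psm("QQQQQQQQ", 1),
    ]
    table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
    assert table.counts.loc[1, "C"] == 4
    assert table.exclusions == {"non_spanning": 1, "unmatched": 1}


def test_mod_states_summed_and_annotations_stripped(blindspot, chymo_peptides):
    _, _, variants = blindspot
    seq = chymo_peptides["C"]
    annotated = seq.replace("C", "C[+57.021]")
    psms = [make_psm(seq, 3), make_psm(annotated, 2)]
    table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
    assert table.counts.loc[1, "C"] == 5


def test_duplicate_amino_acids_rejected(blindspot):
    _, _, variants = blindspot
    with pytest.raises(ValueError):
        assign_peptides_to_variants([], [variants["C"], variants["C"]], CHYMOTRYPSIN)


def test_single_support_and_all_zero():
    counts = pd.DataFrame({"C": [7], "R": [0], "W": [0]}, index=[1])
    fr = relative_abundance(counts)
    assert fr.loc[1].to_dict() == {"C": 1.0, "R": 0.0, "W": 0.0}
    with pytest.raises(ValueError):
        relative_abundance(pd.DataFrame({"C": [0], "R": [0]}, index=[1]))


def test_zero_total_replicate_dropped_with_warning():
    counts = pd.DataFrame({"C": [5, 0], "R": [5, 0]}, index=[1, 2])
    with pytest.warns(UserWarning):
        fr = relative_abundance(counts)
    assert list(fr.index) == [1]


@given(
    table=st.lists(
        st.lists(st.integers(0, 50), min_size=3, max_size=3), min_size=1, max_size=6
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_fractions_sum_to_one(table):
    counts = pd.DataFrame(table, columns=["C", "R", "W"])
    if counts.to_numpy().sum() == 0:
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fr = relative_abundance(counts)
    assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)


def test_permutation_invariance():
    counts = pd.DataFrame({"C": [13], "R": [5], "W": [2]}, index=[1])
    forward = relative_abundance(counts)
    swapped = relative_abundance(counts[["W", "C", "R"]])
    for aa in "CRW":
        assert forward.loc[1, aa] == swapped.loc[1, aa]


def test_identical_replicates_degenerate():
    fractions = pd.DataFrame({"C": [0.6, 0.6], "R": [0.4, 0.4]}, index=[1, 2])
    for est in aggregate_replicates(fractions, n_boot=200, seed=0):
        assert est.sem == 0.0
        assert est.ci_low == est.ci_high == est.fraction


def test_two_replicate_sem_is_half_difference():
    fractions = pd.DataFrame(
        {"C": [0.6, 0.7], "R": [0.3, 0.2], "W": [0.1, 0.1]}, index=[1, 2]
    )
    ests = {e.incorporated_aa: e for e in aggregate_replicates(fractions, seed=1)}
    assert ests["C"].fraction == pytest.approx(0.65)
    assert ests["C"].sem == pytest.approx(0.05)
    assert ests["R"].sem == pytest.approx(0.05)
    assert ests["W"].sem == pytest.approx(0.0)
    assert sum(e.fraction for e in ests.values()) == pytest.approx(1.0, abs=1e-9)


def test_two_stage_bootstrap_widens_ci():
    """Counting noise broadens the interval relative to replicate-only resampling."""
    counts = pd.DataFrame({"C": [26, 27], "R": [10, 9], "W": [4, 4]}, index=[1, 2])
    fractions = relative_abundance(counts)
    plain = aggregate_replicates(fractions, n_boot=500, seed=7)
    staged = aggregate_replicates(fractions, n_boot=500, seed=7, counts=counts)
    for p, s in zip(plain, staged):
        assert (s.ci_high - s.ci_low) >= (p.ci_high - p.ci_low)


def test_detectability_bias_direction(blindspot):
    """Unequal per-variant detection weights bias the uncorrected estimator
    toward the better-detected variant."""
    _, _, variants = blindspot
    config = SimulationConfig(
        seed=11,
        n_replicates=2,
        depth_mean=5e4,
        detectability_weights={"C": 3.0, "R": 1.0, "W": 1.0},
    )
    psms, truth = simulate_psm_table(config, list(variants.values()), CHYMOTRYPSIN)
    table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
    pooled = pooled_abundance(table)
    assert pooled["C"] > truth["theta"]["C"] + 0.05


def test_pooled_mode(blindspot, chymo_peptides):
    _, _, variants = blindspot
    psms = [
        make_psm(chymo_peptides["C"], 10, replicate=1),
        make_psm(chymo_peptides["R"], 10, replicate=2),
    ]
    table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
    pooled = pooled_abundance(table)
    assert pooled["C"] == pooled["R"] == pytest.approx(0.5)
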