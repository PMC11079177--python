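"""Ground-truth generators: determinism, constraint satisfaction, recovery."""

import numpy as np
import pandas as pd
import pytest

from ptcquant.digest import CHYMOTRYPSIN, TRYPSIN
from ptcquant.quant import assign_peptides_to_variants, pooled_abundance
from ptcquant.synth import (
    SimulationConfig,
    invert_codon_table,
    simulate_comparative_arrays,
    simulate_functional_measurements,
    simulate_protein_with_ptc,
    simulate_psm_table,
)
from ptcquant.trna import isoacceptor_to_codon, normalize_by_spikeins, to_absolute


def test_context_embedding_and_determinism():
    protein, site = simulate_protein_with_ptc(30, 20, context="RSVS_", seed=7)
    assert protein.sequence[15:20] == "RSVS*"
    assert site.residue_index == 20
    again, _ = simulate_protein_with_ptc(30, 20, context="RSVS_", seed=7)
    assert again.sequence == protein.sequence
    other, _ = simulate_protein_with_ptc(30, 20, context="RSVS_", seed=8)
    assert other.sequence != protein.sequence


def test_context_validation():
    with pytest.raises(ValueError):
        simulate_protein_with_ptc(5, 3, context="K" * 10 + "_", seed=0)
    with pytest.raises(ValueError):
        simulate_protein_with_ptc(30, 20, context="RSVS", seed=0)  # no site marker
    with pytest.raises(ValueError):
        simulate_protein_with_ptc(30, 2, context="RSVS_", seed=0)  # does not fit


def test_psm_table_law_of_large_numbers(blindspot):
    _, _, variants = blindspot
    config = SimulationConfig(seed=5, n_replicates=1, depth_mean=1e5)
    psms, truth = simulate_psm_table(config, list(variants.values()), CHYMOTRYPSIN)
    table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
    pooled = pooled_abundance(table)
    for aa, theta in truth["theta"].items():
        assert pooled[aa] == pytest.approx(theta, abs=0.01)


def test_blindspot_coupling_zeroes_arg_counts(blindspot):
    """Under trypsin the Arg variant is audited undetectable, so its counts
    are zero no matter how large its true proportion."""
    _, _, variants = blindspot
    config = SimulationConfig(
        seed=5,
        n_replicates=3,
        depth_mean=1000,
        true_proportions={"C": 0.3, "R": 0.6, "W": 0.1},
    )
    psms, truth = simulate_psm_table(config, list(variants.values()), TRYPSIN)
    assert not truth["detectable"]["R"]
    assert truth["expected_proportions"]["R"] == 0.0
    table = assign_peptides_to_variants(psms, list(variants.values()), TRYPSIN)
    assert (table.counts["R"] == 0).all()
    assert table.counts[["C", "W"]].to_numpy().sum() > 0


def test_psm_table_deterministic(blindspot):
    _, _, variants = blindspot
    config = SimulationConfig(seed=9)
    a, _ = simulate_psm_table(config, list(variants.values()), CHYMOTRYPSIN)
    b, _ = simulate_psm_table(config, list(variants.values()), CHYMOTRYPSIN)
    assert a.to_csv(sep="\t") == b.to_csv(sep="\t")


def test_overdispersion_increases_replicate_variance(blindspot):
    _, _, variants = blindspot
    base = SimulationConfig(seed=3, n_replicates=30, depth_mean=200)
    over = SimulationConfig(seed=3, n_replicates=30, depth_mean=200, overdispersion=10.0)
    def rep_var(cfg):
        psms, _ = simulate_psm_table(cfg, list(variants.values()), CHYMOTRYPSIN)
        table = assign_peptides_to_variants(psms, list(variants.values()), CHYMOTRYPSIN)
        fr = table.counts.div(table.counts.sum(axis=1), axis=0)
        return fr["C"].var()
    assert rep_var(over) > rep_var(base)


def test_noiseless_array_round_trip(decoding_fixture):
    dmap, reference, codon_true = decoding_fixture
    signals, truth = simulate_comparative_arrays(
        codon_true, dmap, reference, noise_cv=0.0, n_replicates=2, seed=0
    )
    codon = isoacceptor_to_codon(
        to_absolute(normalize_by_spikeins(signals), reference), dmap
    )
    merged = codon.merge(codon_true, on="codon", suffixes=("", "_true"))
    assert np.allclose(merged["fraction"], merged["fraction_true"], atol=1e-6)


def test_array_determinism_and_noise(decoding_fixture):
    dmap, reference, codon_true = decoding_fixture
    a, _ = simulate_comparative_arrays(codon_true, dmap, reference, 0.1, 3, seed=2)
    b, _ = simulate_comparative_arrays(codon_true, dmap, reference, 0.1, 3, seed=2)
    pd.testing.assert_frame_equal(a, b)
    c, _ = simulate_comparative_arrays(codon_true, dmap, reference, 0.1, 3, seed=3)
    assert not a.equals(c)


def test_inconsistent_codon_table_rejected(decoding_fixture):
    dmap, _, codon_true = decoding_fixture
    # Cys-GCA reads UGU/UGC at fixed 11:13; demanding an inverted ratio is
    # unreachable by any isoacceptor assignment.
    broken = codon_true.copy()
    ugu = broken["codon"] == "UGU"
    ugc = broken["codon"] == "UGC"
    broken.loc[ugu, "fraction"], broken.loc[ugc, "fraction"] = (
        codon_true.loc[ugc, "fraction"].to_numpy(),
        codon_true.loc[ugu, "fraction"].to_numpy(),
    )
    with pytest.raises(ValueError, match="inconsistent"):
        invert_codon_table(broken, dmap)


def test_functional_measurement_generator():
    truth = pd.DataFrame(
        {
            "construct_id": ["WT", "G542W"],
            "readout": ["isc", "isc"],
            "value": [100.0, 20.0],
        }
    )
    out = simulate_functional_measurements(truth, n_replicates=3, cv=0.0, seed=1)
    assert len(out) == 6
    assert np.allclose(
        out.loc[out["construct_id"] == "G542W", "value"], 20.0
    )
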