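import pandas as pd
import pytest

from ptcquant import apply_readthrough
from ptcquant.synth import R1162X_CONTEXT, simulate_protein_with_ptc
from ptcquant.trna import isoacceptor_to_codon


@pytest.fixture(scope="session")
def blindspot():
    """Synthetic protein embedding the Arg-S-V-S-[PTC] tryptic blind-spot
    context, with its three UGA readthrough variants."""
    protein, site = simulate_protein_with_ptc(
        length=60, site_index=30, context=R1162X_CONTEXT, seed=3
    )
    variants = {aa: apply_readthrough(protein, site, aa) for aa in "RCW"}
    return protein, site, variants


@pytest.fixture(scope="session")
def decoding_fixture():
    """Small consistent decoding map + reference + true codon table."""
    dmap = pd.DataFrame(
        [
            ("Arg-UCU", "AGA", 22),
            ("Arg-UCU", "AGG", 12),
            ("Cys-GCA", "UGU", 11),
            ("Cys-GCA", "UGC", 13),
            ("Trp-CCA", "UGG", 13),
            ("Gly-GCC", "GGC", 22),
            ("Gly-GCC", "GGU", 16),
            ("Ser-GCU", "AGC", 19),
        ],
        columns=["isoacceptor", "codon", "usage_weight"],
    )
    reference = pd.DataFrame(
        {
            "isoacceptor": ["Arg-UCU", "Cys-GCA", "Trp-CCA", "Gly-GCC", "Ser-GCU"],
            "fraction": [20.0, 15.0, 10.0, 30.0, 25.0],
        }
    )
    iso_true = pd.DataFrame(
        {
            "isoacceptor": reference["isoacceptor"],
            "replicate": 1,
            "fraction": [25.0, 10.0, 15.0, 30.0, 20.0],
        }
    )
    codon_true = isoacceptor_to_codon(iso_true, dmap).drop(columns="replicate")
    return dmap, reference, codon_true
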