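"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised against data whose truth is known:
proteins with a chosen local PTC context, spectral-count (PSM) tables drawn
from true incorporation proportions, two-channel comparative array signals
derived from a known codon table, and functional readouts.

What the generators emulate — and what they do not: spectral counts follow a
Poisson-total multinomial (optionally Dirichlet-overdispersed across
replicates); all counts for a variant land on its best detectable
site-spanning peptide.  Real data additionally contain co-eluting
interference, charge-state and retention effects, and misassigned spectra;
parameter recovery here therefore demonstrates estimator correctness, not
robustness to those artifacts.  Detectability bias is modeled explicitly via
per-variant weights so the (uncorrected) estimator's bias can be
demonstrated.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .digest import ProteaseRule
from .inclusion import InstrumentSettings, detectability_audit
from .quant import PSM_COLUMNS
from .trna import isoacceptor_to_codon
from .variants import (
    PTC_PLACEHOLDER,
    ProteinRecord,
    PtcSite,
    ReadthroughVariant,
    STANDARD_AA,
)

__all__ = [
    "SimulationConfig",
    "R1162X_CONTEXT",
    "simulate_protein_with_ptc",
    "simulate_psm_table",
    "simulate_comparative_arrays",
    "simulate_functional_measurements",
]

#: Local context emulating the tryptic blind spot at an Arg...Ser-Val-Ser-[PTC]
#: stretch: the nearest upstream K/R sits 4 residues before the PTC, so the
#: fully cleaved tryptic peptide of the Arg readthrough product is the
#: 447 Da SVSR, below the 500 Da peak-list floor, while flanking Phe residues
#: give chymotrypsin a detectable spanning peptide.
R1162X_CONTEXT = "FAGQRSVS_NVTDAEKAF"

#: Default true incorporation proportions used by the generators — the
#: package's convention for a realistic UGA readthrough mixture (Cys-major,
#: Arg-intermediate, Trp-minor).
DEFAULT_TRUE_PROPORTIONS = {"C": 0.65, "R": 0.25, "W": 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the spectral-count generator.

    ``depth_mean`` is the expected total site-spanning spectral counts per
    replicate; ``detectability_weights`` multiply the true proportions to
    model unequal per-variant detection efficiency (uniform by default);
    ``overdispersion`` is an optional Dirichlet concentration factor — lower
    values give more between-replicate variability than pure counting noise
    (``None`` disables it).
    """

    seed: int = 0
    true_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PROPORTIONS)
    )
    n_replicates: int = 4
    depth_mean: float = 40.0
    detectability_weights: dict[str, float] | None = None
    array_noise_cv: float = 0.1
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.true_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"true proportions must sum to 1 (got {total})")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.detectability_weights is not None and any(
            w <= 0 for w in self.detectability_weights.values()
        ):
            raise ValueError("detectability weights must be positive")
        if self.array_noise_cv < 0:
            raise ValueError("array_noise_cv must be >= 0")


def simulate_protein_with_ptc(
    length: int,
    site_index: int,
    context: str = "RSVS_",
    seed: int = 0,
    stop_codon: str = "UGA",
    native_aa: str = "R",
    protein_id: str = "SYN1",
) -> tuple[ProteinRecord, PtcSite]:
    """Random protein with a declared PTC and a chosen local context.

    ``context`` is a residue string with exactly one ``_`` marking the PTC
    position; it is embedded so the ``_`` lands at ``site_index`` and the
    remaining positions are filled with residues drawn uniformly from the
    20-letter alphabet.  The PTC position itself carries the ``*``
    placeholder until a readthrough amino acid is applied.
    """
    if not 1 <= site_index <= length:
        raise ValueError(f"site_index {site_index} outside 1..{length}")
    if context.count("_") != 1:
        raise ValueError("context must contain exactly one '_' marking the PTC")
    if len(context) > length:
        raise ValueError(
            f"context (length {len(context)}) longer than protein (length {length})"
        )
    offset = context.index("_")
    start = site_index - offset  # 1-based position of context[0]
    if start < 1 or start + len(context) - 1 > length:
        raise ValueError("context does not fit around site_index within the protein")
    bad = set(context.replace("_", "")) - STANDARD_AA
    if bad:
        raise ValueError(f"context contains non-standard residue(s): {sorted(bad)}")

    rng = np.random.default_rng(seed)
    alphabet = sorted(STANDARD_AA)
    residues = list(rng.choice(alphabet, size=length))
    for i, ch in enumerate(context):
        residues[start - 1 + i] = PTC_PLACEHOLDER if ch == "_" else ch
    protein = ProteinRecord(id=protein_id, sequence="".join(residues))
    site = PtcSite(residue_index=site_index, stop_codon=stop_codon, native_aa=native_aa)
    return protein, site


def simulate_psm_table(
    config: SimulationConfig,
    variants: list[ReadthroughVariant],
    protease: ProteaseRule,
    settings: InstrumentSettings | None = None,
    sample_id: str = "sim",
) -> tuple[pd.DataFrame, dict]:
    """Spectral-count table drawn from known incorporation proportions.

    Per replicate the total count is Poisson(``depth_mean``) and is split
    over variants multinomially with probabilities proportional to
    theta(aa) x weight(aa), restricted to variants the detectability audit
    passes under ``protease`` — a variant whose every site-spanning peptide
    violates an instrument constraint receives zero counts regardless of its
    true proportion, reproducing the protease blind spot.  Counts are
    attached to each variant's best site-spanning peptide sequence.

    Returns the PSM table and a ground-truth record (theta, weights,
    detectability, the effective sampled proportions and per-replicate
    depths).
    """
    if not variants:
        raise ValueError("empty variant list")
    settings = settings or InstrumentSettings()
    theta = config.true_proportions
    missing = [v.incorporated_aa for v in variants if v.incorporated_aa not in theta]
    if missing:
        raise ValueError(
            f"no true proportion given for variant amino acid(s): {missing}"
        )
    weights = config.detectability_weights or {}

    peptide_of: dict[str, str] = {}
    detectable: dict[str, bool] = {}
    for v in variants:
        report = detectability_audit(v, [protease], settings=settings)[0]
        detectable[v.incorporated_aa] = report.detectable
        if report.best_peptide is not None:
            peptide_of[v.incorporated_aa] = report.best_peptide.sequence

    aas = [v.incorporated_aa for v in variants]
    raw = np.array(
        [
            theta[aa] * weights.get(aa, 1.0) * (1.0 if detectable[aa] else 0.0)
            for aa in aas
        ]
    )
    if raw.sum() == 0:
        raise ValueError(
            "no variant is detectable under the given protease; nothing to simulate"
        )
    p = raw / raw.sum()

    rng = np.random.default_rng(config.seed)
    rows = []
    depths = []
    for rep in range(1, config.n_replicates + 1):
        n = int(rng.poisson(config.depth_mean))
        depths.append(n)
        p_rep = p
        if config.overdispersion is not None:
            alpha = np.where(p > 0, p * config.overdispersion, 0.0)
            draw = np.zeros_like(p)
            pos = alpha > 0
            draw[pos] = rng.dirichlet(alpha[pos])
            p_rep = draw
        counts = rng.multinomial(n, p_rep) if n > 0 else np.zeros(len(p), dtype=int)
        for aa, c in zip(aas, counts):
            if c > 0:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "replicate": rep,
                        "peptide_sequence": peptide_of[aa],
                        "mod_state": "",
                        "spectral_count": int(c),
                    }
                )
    psms = pd.DataFrame(rows, columns=PSM_COLUMNS)
    truth = {
        "theta": dict(theta),
        "weights": {aa: weights.get(aa, 1.0) for aa in aas},
        "detectable": detectable,
        "expected_proportions": {aa: float(p[i]) for i, aa in enumerate(aas)},
        "depth_per_replicate": depths,
        "seed": config.seed,
    }
    return psms, truth


def _lognormal_noise(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise draw with unit mean at the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def invert_codon_table(
    codon_table: pd.DataFrame, decoding_map: pd.DataFrame
) -> pd.Series:
    """Isoacceptor fractions consistent with a codon table under a decoding map.

    Solves the non-negative least-squares problem share-matrix @ f = codon
    fractions; a residual beyond numerical tolerance means no isoacceptor
    assignment can produce the requested codon table under this map.
    """
    isos = sorted(decoding_map["isoacceptor"].unique())
    codons = sorted(codon_table["codon"].unique())
    weight_sums = decoding_map.groupby("isoacceptor")["usage_weight"].sum()
    a = np.zeros((len(codons), len(isos)))
    codon_ix = {c: i for i, c in enumerate(codons)}
    for row in decoding_map.itertuples(index=False):
        if row.codon not in codon_ix:
            continue
        a[codon_ix[row.codon], isos.index(row.isoacceptor)] = (
            row.usage_weight / weight_sums.loc[row.isoacceptor]
        )
    target = codon_table.set_index("codon")["fraction"].loc[codons].to_numpy(dtype=float)
    sol, residual = nnls(a, target)
    if residual > 1e-6 * max(1.0, np.linalg.norm(target)):
        raise ValueError(
            "codon table is inconsistent with every isoacceptor assignment "
            f"under the decoding map (NNLS residual {residual:.3g})"
        )
    return pd.Series(sol, index=isos, name="fraction")


def simulate_comparative_arrays(
    true_codon_table: pd.DataFrame,
    decoding_map: pd.DataFrame,
    reference: pd.DataFrame,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    sample_gain: float = 1500.0,
    reference_gain: float = 1000.0,
    n_spikeins: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Two-channel comparative array signals realizing a known codon table.

    The codon table is inverted to per-isoacceptor fractions (error if the
    decoding map admits no consistent assignment), and fluorescence signals
    are formed per replicate as gain x fraction with log-normal
    multiplicative noise at ``noise_cv``.  Spike-in probes are present at a
    common concentration in both channels, so the channel-gain ratio cancels
    downstream.  Returns the signal table and a ground-truth record.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_spikeins < 3:
        raise ValueError("need at least 3 spike-in probes")
    f_sample = invert_codon_table(true_codon_table, decoding_map)
    ref = reference.set_index("isoacceptor")["fraction"]
    missing = sorted(set(f_sample.index) - set(ref.index))
    if missing:
        raise ValueError(f"reference table missing isoacceptor(s): {missing}")
    ref = 100.0 * ref / ref.sum()
    f_sample = 100.0 * f_sample / f_sample.sum()

    rng = np.random.default_rng(seed)
    spike_conc = 5.0  # arbitrary common concentration units
    rows = []
    for rep in range(1, n_replicates + 1):
        for iso in f_sample.index:
            rows.append(
                {
                    "probe": iso,
                    "replicate": rep,
                    "sample_signal": sample_gain
                    * (f_sample[iso] / 100.0)
                    * _lognormal_noise(rng, noise_cv),
                    "reference_signal": reference_gain
                    * (ref[iso] / 100.0)
                    * _lognormal_noise(rng, noise_cv),
                    "is_spikein": False,
                }
            )
        for k in range(1, n_spikeins + 1):
            rows.append(
                {
                    "probe": f"SPIKE{k}",
                    "replicate": rep,
                    "sample_signal": sample_gain
                    * (spike_conc / 100.0)
                    * _lognormal_noise(rng, noise_cv),
                    "reference_signal": reference_gain
                    * (spike_conc / 100.0)
                    * _lognormal_noise(rng, noise_cv),
                    "is_spikein": True,
                }
            )
    signals = pd.DataFrame(rows)
    abs_truth = pd.DataFrame(
        {
            "isoacceptor": np.tile(f_sample.index, n_replicates),
            "replicate": np.repeat(np.arange(1, n_replicates + 1), len(f_sample)),
            "fraction": np.tile(f_sample.to_numpy(), n_replicates),
        }
    )
    truth = {
        "isoacceptor_fractions": f_sample,
        "codon_table": isoacceptor_to_codon(abs_truth, decoding_map),
        "seed": seed,
    }
    return signals, truth


def simulate_functional_measurements(
    true_values: pd.DataFrame,
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy per-replicate functional readouts from true construct values.

    ``true_values`` has columns construct_id, readout, value (e.g. pm_density,
    isc, mrna_level in WT-relative units); each is replicated with
    log-normal multiplicative noise at ``cv``.
    """
    for col in ("construct_id", "readout", "value"):
        if col not in true_values.columns:
            raise ValueError(f"true_values missing column {col!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for row in true_values.itertuples(index=False):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "construct_id": row.construct_id,
                    "readout": row.readout,
                    "replicate": rep,
                    "value": row.value * _lognormal_noise(rng, cv),
                }
            )
    return pd.DataFrame(rows)
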