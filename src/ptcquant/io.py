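"""Readers, writers and the pipeline orchestrator.

File dialects: FASTA for proteins; TSV (UTF-8, tab, "." decimal) for
peptides, PSM tables and abundance outputs; CSV for inclusion lists, array
signals, reference abundances, decoding maps and codon tables; YAML for the
pipeline configuration and ground-truth records.  The PSM TSV is a minimal,
documented dialect of search-engine spectral-count exports with columns
``sample_id, replicate, peptide_sequence, mod_state, spectral_count``.

Every table written by :func:`run_pipeline` starts with a comment line
carrying the configuration hash, so reruns with an unchanged configuration
are byte-identical and traceable.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .digest import PROTEASES, Peptide, digest, site_spanning_peptides
from .inclusion import InstrumentSettings, TargetIon, build_inclusion_list, detectability_audit
from .quant import (
    PSM_COLUMNS,
    aggregate_replicates,
    assign_peptides_to_variants,
    relative_abundance,
)
from .trna import (
    isoacceptor_to_codon,
    normalize_by_spikeins,
    summarize_codon_table,
    to_absolute,
)
from .variants import (
    PTC_PLACEHOLDER,
    ProteinRecord,
    PtcSite,
    STANDARD_AA,
    apply_readthrough,
    near_cognate_amino_acids,
)

__all__ = [
    "read_fasta",
    "read_ptc_sites",
    "read_psm_table",
    "write_peptides_tsv",
    "inclusion_to_frame",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA into validated records (sequences uppercased)."""
    records = []
    allowed = STANDARD_AA | {PTC_PLACEHOLDER}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - allowed)
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains illegal residue(s) "
                f"{', '.join(bad)}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_ptc_sites(path: str | Path) -> dict[str, PtcSite]:
    """PTC site sidecar: CSV or YAML with id, residue_index, stop_codon, native_aa."""
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rows = data if isinstance(data, list) else data.get("sites", [])
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    sites = {}
    for row in rows:
        sites[str(row["id"])] = PtcSite(
            residue_index=int(row["residue_index"]),
            stop_codon=str(row["stop_codon"]).upper().replace("T", "U"),
            native_aa=str(row["native_aa"]).upper(),
        )
    if not sites:
        raise ValueError(f"{path}: no PTC sites found")
    return sites


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read the documented PSM TSV dialect, validating columns and counts."""
    frame = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: PSM table missing column(s): {', '.join(missing)}")
    frame["replicate"] = frame["replicate"].astype(int)
    frame["spectral_count"] = frame["spectral_count"].astype(int)
    if (frame["spectral_count"] < 0).any():
        raise ValueError(f"{path}: negative spectral counts")
    return frame


def peptides_to_frame(peptides: list[Peptide]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent_id": p.parent_id,
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "missed_cleavages": p.missed_cleavages,
            }
            for p in peptides
        ]
    )


def write_peptides_tsv(peptides: list[Peptide], path: str | Path, header: str = "") -> None:
    _write_frame(peptides_to_frame(peptides), path, sep="\t", header=header)


def inclusion_to_frame(targets: list[TargetIon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_label": t.variant_label,
                "peptide": t.peptide.sequence if t.peptide else "",
                "start": t.peptide.start if t.peptide else "",
                "end": t.peptide.end if t.peptide else "",
                "mod_state": t.mod_state,
                "charge": t.charge if t.charge else "",
                "mz": round(t.mz, 5) if t.mz is not None else "",
                "flags": ";".join(sorted(t.flags)),
            }
            for t in targets
        ]
    )


def _write_frame(frame: pd.DataFrame, path: str | Path, sep: str = ",", header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        frame.to_csv(fh, sep=sep, index=False)


@dataclass
class PipelineConfig:
    """Declarative description of one end-to-end run.

    Only the FASTA/site inputs are mandatory; quantification and tRNA
    conversion stages run when their input paths are present.
    """

    fasta: str
    sites: str
    outdir: str = "ptcquant_out"
    protein_id: str | None = None
    enumeration_mode: str = "observed-UGA"
    protease: str = "trypsin"
    audit_proteases: tuple[str, ...] = ("trypsin", "chymotrypsin")
    max_missed: int = 1
    charges: tuple[int, ...] = (2, 3)
    seed: int = 0
    n_boot: int = 2000
    psm_tsv: str | None = None
    array_signals: str | None = None
    array_reference: str | None = None
    decoding_map: str | None = None
    instrument: dict = field(default_factory=dict)

    def validate(self) -> None:
        for attr in ("fasta", "sites"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{attr}: {p} does not exist")
        for attr in ("psm_tsv", "array_signals", "array_reference", "decoding_map"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{attr}: {p} does not exist")
        if self.protease not in PROTEASES:
            raise ValueError(
                f"unknown protease {self.protease!r}; known: {sorted(PROTEASES)}"
            )
        if self.array_signals and not (self.array_reference and self.decoding_map):
            raise ValueError(
                "tRNA conversion requires array_signals, array_reference and "
                "decoding_map together"
            )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("audit_proteases", "charges"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enumerate -> digest -> inclusion/audit -> quantify (-> tRNA).

    The configuration is validated before any stage runs; each output table
    carries the configuration hash in a leading comment line.  Returns a
    bundle of output paths and in-memory results.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"ptcquant v{__version__} config_hash={config.hash()} seed={config.seed}"

    def stage(name):
        logger.info("stage: %s", name)

    # --- enumerate ----------------------------------------------------------
    stage("enumerate")
    proteins = {p.id: p for p in read_fasta(config.fasta)}
    sites = read_ptc_sites(config.sites)
    pid = config.protein_id or next(iter(sites))
    if pid not in proteins:
        raise ValueError(f"protein {pid!r} not present in {config.fasta}")
    if pid not in sites:
        raise ValueError(f"no PTC site declared for protein {pid!r}")
    protein, site = proteins[pid], sites[pid]
    aa_set = sorted(near_cognate_amino_acids(site.stop_codon, config.enumeration_mode))
    variants = [apply_readthrough(protein, site, aa) for aa in aa_set]

    # --- digest -------------------------------------------------------------
    stage("digest")
    protease = PROTEASES[config.protease]
    all_peps: list[Peptide] = []
    for v in variants:
        peps = digest(v.sequence, protease, max_missed=config.max_missed, parent_id=v.label)
        all_peps.extend(site_spanning_peptides(peps, site.residue_index))
    write_peptides_tsv(all_peps, outdir / "site_spanning_peptides.tsv", header=tag)

    # --- inclusion list & audit --------------------------------------------
    stage("inclusion")
    settings = InstrumentSettings(**config.instrument)
    targets = build_inclusion_list(
        variants,
        protease,
        settings=settings,
        charges=tuple(config.charges),
        max_missed=config.max_missed,
    )
    _write_frame(inclusion_to_frame(targets), outdir / "inclusion_list.csv", header=tag)
    audit_rules = [PROTEASES[name] for name in config.audit_proteases]
    reports = []
    for v in variants:
        reports.extend(detectability_audit(v, audit_rules, settings=settings))
    audit_frame = pd.DataFrame(
        [
            {
                "variant_label": r.variant_label,
                "protease": r.protease,
                "best_peptide": r.best_peptide.sequence if r.best_peptide else "",
                "detectable": r.detectable,
                "reasons": ";".join(r.reasons),
            }
            for r in reports
        ]
    )
    _write_frame(audit_frame, outdir / "detectability_audit.csv", header=tag)

    results: dict = {
        "variants": variants,
        "inclusion_list": targets,
        "audit": reports,
        "outdir": str(outdir),
        "config_hash": config.hash(),
    }

    # --- quantify -----------------------------------------------------------
    if config.psm_tsv:
        stage("quantify")
        psms = read_psm_table(config.psm_tsv)
        table = assign_peptides_to_variants(
            psms, variants, protease, max_missed=config.max_missed
        )
        fractions = relative_abundance(table)
        estimates = aggregate_replicates(
            fractions, n_boot=config.n_boot, seed=config.seed, counts=table.counts
        )
        est_frame = pd.DataFrame(
            [
                {
                    "incorporated_aa": e.incorporated_aa,
                    "fraction": e.fraction,
                    "sem": e.sem,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n_replicates": e.n_replicates,
                }
                for e in estimates
            ]
        )
        _write_frame(
            est_frame,
            outdir / "incorporation_abundance.tsv",
            sep="\t",
            header=tag + " | spectral counts uncorrected for per-peptide detectability",
        )
        results["abundance"] = estimates
        results["fractions"] = fractions
        results["count_table"] = table

    # --- tRNA conversion ----------------------------------------------------
    if config.array_signals:
        stage("trna-convert")
        signals = pd.read_csv(config.array_signals, comment="#")
        reference = pd.read_csv(config.array_reference, comment="#")
        dmap = pd.read_csv(config.decoding_map, comment="#")
        ratios = normalize_by_spikeins(signals)
        absolute = to_absolute(ratios, reference)
        codon_table = isoacceptor_to_codon(absolute, dmap)
        _write_frame(codon_table, outdir / "codon_abundance.csv", header=tag)
        _write_frame(
            summarize_codon_table(codon_table),
            outdir / "codon_abundance_summary.csv",
            header=tag,
        )
        results["codon_table"] = codon_table

    # --- run log ------------------------------------------------------------
    log = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": [
            s
            for s, on in (
                ("enumerate", True),
                ("digest", True),
                ("inclusion", True),
                ("quantify", bool(config.psm_tsv)),
                ("trna-convert", bool(config.array_signals)),
            )
            if on
        ],
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return results
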