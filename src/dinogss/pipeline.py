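"""End-to-end pipeline: simulate or load inputs, run every stage, write reports.

Outputs (TSV with a header and a provenance comment line, plus
``summary.json``) are written into the configured output directory:
``chains.tsv``, ``arrays.tsv``, ``families.tsv``, ``census.tsv``,
``stop_codons.tsv``, ``motifs.tsv``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coding_stats import infer_stop_codon, polyA_motif_scan, stop_codon_table
from .repeat_census import (
    ClusterParams,
    GENOMIC_CLUSTER_PARAMS,
    classify_repetitiveness,
    feature_census,
    greedy_overlap_cluster,
    read_feature_labels,
    sample_fraction,
)
from .seq_core import Source, read_fasta
from .sl_scan import (
    SLConfig,
    classify_chain_counts,
    dedupe_and_trim,
    find_canonical_sl,
    scan_relict_chain,
)
from .synthetic_data import generate_cds_set, generate_gss_reads, generate_sl_ests
from .tandem_arrays import annotate_arrays, estimate_family_fraction, group_families

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    With input FASTA paths left unset, the corresponding synthetic default
    data set is generated (sizes chosen to keep a full default run on a
    single CPU in the minutes range).
    """

    outdir: str | Path = "dinogss_out"
    seed: int = 0
    dna_pg: float = 114.9
    est_fasta: str | Path | None = None
    gss_fasta: str | Path | None = None
    cds_fasta: str | Path | None = None
    n_ests: int = 300
    n_gss_reads: int = 400
    n_cds: int = 200
    sl: SLConfig = field(default_factory=SLConfig)
    cluster: ClusterParams = field(default_factory=lambda: GENOMIC_CLUSTER_PARAMS)
    min_p: int = 20
    max_p: int = 300
    divergent_floor: float = 0.85

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "sl" in raw and isinstance(raw["sl"], dict):
            raw["sl"] = SLConfig(**raw["sl"])
        if "cluster" in raw and isinstance(raw["cluster"], dict):
            raw["cluster"] = ClusterParams(**raw["cluster"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.est_fasta is not None:
        if not Path(cfg.est_fasta).exists():
            raise FileNotFoundError(f"EST FASTA not found: {cfg.est_fasta}")
        ests = read_fasta(cfg.est_fasta, source=Source.EST)
    else:
        ests, _ = generate_sl_ests(cfg.n_ests, cfg=cfg.sl, seed=cfg.seed)
    if cfg.gss_fasta is not None:
        if not Path(cfg.gss_fasta).exists():
            raise FileNotFoundError(f"GSS FASTA not found: {cfg.gss_fasta}")
        reads = read_fasta(cfg.gss_fasta, source=Source.GSS)
    else:
        reads, _ = generate_gss_reads(cfg.n_gss_reads, seed=cfg.seed + 1)
    if cfg.cds_fasta is not None:
        if not Path(cfg.cds_fasta).exists():
            raise FileNotFoundError(f"CDS FASTA not found: {cfg.cds_fasta}")
        cds = read_fasta(cfg.cds_fasta, source=Source.CDS)
    else:
        cds, _ = generate_cds_set(cfg.n_cds, seed=cfg.seed + 2)
    return ests, reads, cds


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = f"# dinogss {__version__} seed={cfg.seed} config={cfg.digest()}"
    ests, reads, cds = _load_or_simulate(cfg)

    # --- spliced-leader stage -------------------------------------------
    matches = {}
    for rec in ests:
        m = find_canonical_sl(rec, cfg.sl)
        if m is not None:
            matches[rec.id] = m
    sl_records = [r for r in ests if r.id in matches]
    uniques = dedupe_and_trim(sl_records, matches)
    chains = [scan_relict_chain(r, cfg.sl) for r in uniques]
    chain_rows = []
    for rec, chain in zip(uniques, chains):
        m = matches[rec.id]
        chain_rows.append(
            {
                "id": rec.id,
                "sl_start": m.interval.start,
                "sl_identity": round(m.identity, 4),
                "k": chain.k,
                "identities": ",".join(f"{x:.3f}" for x in chain.identities),
            }
        )
    _write_tsv(pd.DataFrame(chain_rows), outdir / "chains.tsv", provenance)
    depth_table, _rank_table = (
        classify_chain_counts(chains) if chains else (pd.DataFrame(), pd.DataFrame())
    )

    # --- tandem arrays ---------------------------------------------------
    arrays = []
    for rec in reads:
        arrays.extend(
            annotate_arrays(rec, cfg.min_p, cfg.max_p, cfg.divergent_floor)
        )
    array_rows = [
        {
            "record_id": a.record_id,
            "start": a.span.start,
            "end": a.span.end,
            "unit_length": a.unit_length,
            "n_units": a.n_units,
            "mean_identity": round(
                sum(a.per_unit_identity) / len(a.per_unit_identity), 4
            ),
            "unit_consensus": a.unit_consensus,
        }
        for a in arrays
    ]
    _write_tsv(pd.DataFrame(array_rows), outdir / "arrays.tsv", provenance)
    total_bp = sum(len(r.seq) for r in reads)
    families = group_families(arrays)
    family_rows = []
    for fam in families:
        fam.estimated_fraction = estimate_family_fraction(fam, None, total_bp)
        family_rows.append(
            {
                "family_id": fam.family_id,
                "unit_length": len(fam.unit_consensus),
                "n_arrays": len(fam.arrays),
                "estimated_pct_of_sample": round(fam.estimated_fraction, 2),
                "unit_consensus": fam.unit_consensus,
            }
        )
    _write_tsv(pd.DataFrame(family_rows), outdir / "families.tsv", provenance)

    # --- repeat census ---------------------------------------------------
    clusters = greedy_overlap_cluster(reads, cfg.cluster)
    categories = classify_repetitiveness(clusters)
    spans_by_read: dict[str, list] = {}
    for a in arrays:
        spans_by_read.setdefault(a.record_id, []).append(a.span)
    annotations: dict[str, set[str]] = {}
    for rec in reads:
        labels = read_feature_labels(rec, spans_by_read.get(rec.id))
        if categories[rec.id] != "unique":
            labels.add(categories[rec.id])
        annotations[rec.id] = labels
    census = feature_census(reads, annotations)
    _write_tsv(census.table.round(2), outdir / "census.tsv", provenance)

    # --- coding statistics ----------------------------------------------
    codons = [c for c in (infer_stop_codon(r.seq) for r in cds) if c is not None]
    stop_table = stop_codon_table({"cds_set": codons}) if codons else pd.DataFrame()
    _write_tsv(stop_table, outdir / "stop_codons.tsv", provenance)
    motifs = polyA_motif_scan(cds, window=60)
    motif_df = pd.DataFrame(
        [
            {
                "motif": m.motif,
                "observed": m.observed,
                "expected": round(m.expected, 3),
                "p_value": m.p_value,
                "p_adjusted": m.p_adjusted,
                "significant": m.significant,
            }
            for m in motifs[:200]
        ]
    )
    _write_tsv(motif_df, outdir / "motifs.tsv", provenance)

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.digest(),
        "n_ests": len(ests),
        "n_sl_ests": len(sl_records),
        "n_unique_sl_transcripts": len(uniques),
        "relict_depth_histogram": {
            int(row["k"]): int(row["count"]) for _, row in depth_table.iterrows()
        }
        if not depth_table.empty
        else {},
        "n_gss_reads": len(reads),
        "gss_total_bp": total_bp,
        "n_clusters": len(clusters),
        "n_repeat_families": len(families),
        "family_pct_of_sample": {
            fam.family_id: round(fam.estimated_fraction, 2) for fam in families
        },
        "pct_repetitive_reads": round(
            100.0
            * sum(1 for c in categories.values() if c != "unique")
            / max(len(reads), 1),
            2,
        ),
        "n_cds": len(cds),
        "stop_codon_counts": {s: codons.count(s) for s in ("TAA", "TAG", "TGA")},
        "n_significant_polyA_motifs": sum(1 for m in motifs if m.significant),
        "genome_sample_pct": sample_fraction(total_bp, cfg.dna_pg),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
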