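"""End-to-end orchestration: assemble -> map -> cluster -> props ->
compare, with every report written as a commented TSV plus a run
manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .assembly import assemble_reads, Contig
from .config import PipelineConfig
from .errors import FormatError
from .evidence import (coverage_augmentation, filter_min_samples,
                       merge_evidence, select_group_specific,
                       strategy_overlap, summarize_length_bins)
from .io import (read_abundance, read_fasta, read_identifications)
from .matching import ContigClass, cluster_greedy, map_contig
from .properties import (aliphatic_index_reported, average_mass_kda,
                         format_mw_kda, is_tryptic)

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    reference_fasta: str | Path
    library_tsv: str | Path
    denovo_tsv: str | Path
    abundance_tsv: Optional[str | Path] = None


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} "
                 + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
                 + "\n")
        df.to_csv(fh, sep="\t", index=False)


def map_contigs(contigs: list[Contig], db, config: PipelineConfig):
    """Map each contig, caching by sequence (contigs recur across
    samples)."""
    cache: dict[str, tuple] = {}
    out = []
    for c in contigs:
        if c.sequence not in cache:
            cache[c.sequence] = map_contig(
                c.sequence, db, config.map_identity_min,
                config.il_equivalent)
        aln, cls = cache[c.sequence]
        out.append((c, aln, cls))
    return out


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs,
                 outdir: str | Path, per_group: bool = False) -> Path:
    """Execute all stages in order and write the report directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    db = read_fasta(inputs.reference_fasta)
    library_hits = read_identifications(inputs.library_tsv, "library")
    reads = read_identifications(inputs.denovo_tsv, "denovo")
    abundance = None
    if inputs.abundance_tsv is not None:
        abundance = read_abundance(inputs.abundance_tsv)
    else:
        log.warning("no abundance table: all tiers will be 'unknown'")

    # --- assemble ---
    contigs = assemble_reads(reads, k=config.kmer_size,
                             min_len=config.min_contig_len)
    _write_tsv(pd.DataFrame(
        [{"sample_id": c.sample_id, "sequence": c.sequence,
          "support_reads": c.support_reads,
          "mean_confidence": round(c.mean_confidence, 4)}
         for c in contigs]),
        outdir / "contigs.tsv", "assemble",
        {"k": config.kmer_size, "min_len": config.min_contig_len})

    # --- map ---
    contig_hits = map_contigs(contigs, db, config)
    _write_tsv(pd.DataFrame(
        [{"sample_id": c.sample_id, "sequence": c.sequence,
          "class": cls.value,
          "accession": aln.target_accession if aln else "",
          "identity_pct": round(aln.identity_pct, 2) if aln else "",
          "target_start": aln.target_start if aln else "",
          "target_end": aln.target_end if aln else ""}
         for c, aln, cls in contig_hits]),
        outdir / "hits.tsv", "map",
        {"min_identity": config.map_identity_min})

    # --- cluster (library peptides + contigs, strategy-tagged ids) ---
    members: list[tuple[str, str]] = []
    member_strategy: dict[str, str] = {}
    for seq in sorted({h.sequence for h in library_hits}):
        mid = f"lib:{seq}"
        members.append((mid, seq))
        member_strategy[mid] = "library"
    for seq in sorted({c.sequence for c in contigs}):
        mid = f"dn:{seq}"
        members.append((mid, seq))
        member_strategy[mid] = "denovo"
    clusters = cluster_greedy(members, config.cluster_identity_min,
                              config.il_equivalent)
    _write_tsv(pd.DataFrame(
        [{"centroid_id": cl.centroid_id, "centroid": cl.centroid,
          "size": len(cl.members), "members": ";".join(cl.members)}
         for cl in clusters]),
        outdir / "clusters.tsv", "cluster",
        {"min_identity": config.cluster_identity_min})

    # --- contig properties ---
    _write_tsv(pd.DataFrame(
        [{"sequence": seq, "tryptic": "+" if is_tryptic(seq) else "-",
          "mw_kda": format_mw_kda(average_mass_kda(seq)),
          "length_aa": len(seq),
          "aliphatic_index": aliphatic_index_reported(seq)}
         for seq in sorted({c.sequence for c in contigs})]),
        outdir / "props.tsv", "props", {})

    # --- compare ---
    evidence = merge_evidence(library_hits, contig_hits, db, config,
                              abundance=abundance)
    kept = filter_min_samples(evidence, config, per_group=per_group)
    _write_tsv(pd.DataFrame(
        [{"accession": e.accession, "length_aa": e.length_aa,
          "strategies": "+".join(sorted(e.strategies)),
          "Sz": e.samples_case, "Cnt": e.samples_control,
          "tier": e.tier, "ptp_count": e.ptp_count,
          "group_specific": int(e.group_specific),
          "library_aa": len(e.covered_library),
          "denovo_aa": len(e.covered_denovo),
          "noncanonical_aa": len(e.covered_noncanonical)}
         for e in evidence]),
        outdir / "evidence.tsv", "compare", {
            "min_samples": config.min_samples_detected,
            "per_group": per_group})

    overlap = strategy_overlap(kept, clusters, member_strategy)
    _write_tsv(pd.DataFrame(
        [{"level": level, **counts}
         for level, counts in overlap.items()]),
        outdir / "overlap.tsv", "compare",
        {"min_samples": config.min_samples_detected})

    _write_tsv(pd.DataFrame(
        [{"accession": e.accession, "tier": e.tier,
          "strategies": "+".join(sorted(e.strategies))} for e in evidence]),
        outdir / "tiers.tsv", "compare", {})

    _write_tsv(pd.DataFrame(
        [{"accession": acc} for acc in select_group_specific(evidence,
                                                             config)]),
        outdir / "group_specific.tsv", "compare", {
            "min_case": config.group_specific_min_case,
            "max_control": config.group_specific_max_control})

    _write_tsv(coverage_augmentation(evidence, db),
               outdir / "coverage_augmentation.tsv", "compare", {})

    bins = summarize_length_bins(evidence, db)
    _write_tsv(pd.DataFrame(
        [{"bin_lo": lo, "bin_hi": hi,
          "library": bins["hist"]["library"][k],
          "denovo": bins["hist"]["denovo"][k]}
         for k, (lo, hi) in enumerate(bins["bins"])]),
        outdir / "length_bins.tsv", "compare", {})
    _write_tsv(pd.DataFrame(
        [{"length_aa": L, "coverage_pct": round(cov, 2),
          "strategy": s} for L, cov, s in bins["scatter"]]),
        outdir / "coverage_points.tsv", "compare", {})

    manifest = {
        "tool": "dualprot", "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {k: _sha256(v) for k, v in (
            ("reference_fasta", inputs.reference_fasta),
            ("library_tsv", inputs.library_tsv),
            ("denovo_tsv", inputs.denovo_tsv),
        )} | ({"abundance_tsv": _sha256(inputs.abundance_tsv)}
              if inputs.abundance_tsv else {}),
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return outdir
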