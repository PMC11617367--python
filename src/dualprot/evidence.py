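"""Merging both identification strategies into per-protein evidence.

For every reference protein this module accumulates:

* ``covered_library`` — residues covered by exact library-peptide matches;
* ``covered_denovo`` — residues covered by canonical (100% identity)
  contig alignments;
* ``covered_noncanonical`` — matched residues of noncanonical-variant
  contig alignments (mismatched and gapped columns excluded);
* per-group sample counts (Sz = cases, Cnt = controls), an abundance
  tier, the set of detecting strategies, a proteotypic-peptide count and
  the group-specific flag.

Downstream summaries reproduce the shapes of the published report:
strategy overlap (proteins and peptide clusters), abundance tiers,
group-specific selection, length-binned identification counts and
coverage augmentation by noncanonical contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import collapse_il, round_half_up
from .assembly import Contig
from .config import PipelineConfig
from .errors import FormatError
from .io import AbundanceTable, PeptideHit, ReferenceProtein
from .matching import Alignment, Cluster, ContigClass, count_proteotypic

TIERS = ("high", "mid", "low", "unknown")


@dataclass
class ProteinEvidence:
    accession: str
    length_aa: int
    covered_library: set[int] = field(default_factory=set)
    covered_denovo: set[int] = field(default_factory=set)
    covered_noncanonical: set[int] = field(default_factory=set)
    samples_case: int = 0      # Sz
    samples_control: int = 0   # Cnt
    strategies: set[str] = field(default_factory=set)
    tier: str = "unknown"
    group_specific: bool = False
    ptp_count: int = 0

    @property
    def samples_total(self) -> int:
        return self.samples_case + self.samples_control


def assign_tier(conc_g_per_l: Optional[float], config: PipelineConfig) -> str:
    """Abundance tier from a plasma concentration in g/L.

    high > 1 μg/mL; mid in [10 ng/mL, 1 μg/mL] (both boundaries assigned
    to mid); low < 10 ng/mL; missing concentration -> unknown."""
    if conc_g_per_l is None:
        return "unknown"
    if conc_g_per_l < 0:
        raise ValueError(f"negative concentration {conc_g_per_l}")
    if conc_g_per_l > config.tier_high_min:
        return "high"
    if conc_g_per_l >= config.tier_mid_min:
        return "mid"
    return "low"


def coverage_percent(covered: set[int] | int, length_aa: int) -> int:
    """Reported coverage: 100*|covered|/length, rounded half-up to int."""
    if length_aa <= 0:
        raise ValueError("length_aa must be positive")
    n = covered if isinstance(covered, int) else len(covered)
    return int(round_half_up(100.0 * n / length_aa))


def _find_all(text: str, sub: str) -> Iterable[int]:
    start = text.find(sub)
    while start >= 0:
        yield start
        start = text.find(sub, start + 1)


def merge_evidence(
    hits_library: Sequence[PeptideHit],
    contig_hits: Sequence[tuple[Contig, Optional[Alignment], ContigClass]],
    db: Sequence[ReferenceProtein],
    config: PipelineConfig,
    abundance: Optional[AbundanceTable] = None,
    sample_groups: Optional[dict[str, str]] = None,
) -> list[ProteinEvidence]:
    """Merge library hits and mapped contigs into per-protein evidence.

    ``sample_groups`` maps sample_id -> group for samples that only
    appear in the de novo channel; when omitted it is derived from the
    library table. Sample counts include any supporting identification
    from either strategy.
    """
    by_acc = {p.accession: p for p in db}
    groups = dict(sample_groups or {})
    for h in hits_library:
        groups.setdefault(h.sample_id, h.group)

    ev: dict[str, ProteinEvidence] = {}

    def get(acc: str) -> ProteinEvidence:
        if acc not in by_acc:
            raise FormatError(f"identification names unknown accession {acc!r}")
        if acc not in ev:
            ev[acc] = ProteinEvidence(acc, by_acc[acc].length_aa)
        return ev[acc]

    samples_by_acc: dict[str, set[str]] = {}
    pos_cache: dict[tuple[str, str], list[int]] = {}

    for h in hits_library:
        for acc in h.proteins:
            e = get(acc)
            e.strategies.add("library")
            samples_by_acc.setdefault(acc, set()).add(h.sample_id)
            key = (acc, h.sequence)
            if key not in pos_cache:
                text = by_acc[acc].sequence
                pep = h.sequence
                if config.il_equivalent:
                    text, pep = collapse_il(text), collapse_il(pep)
                pos_cache[key] = list(_find_all(text, pep))
            for start in pos_cache[key]:
                e.covered_library.update(range(start, start + len(h.sequence)))

    canonical_contig_seqs: list[str] = []
    for contig, aln, cls in contig_hits:
        if aln is None or cls is ContigClass.UNMATCHED:
            continue
        e = get(aln.target_accession)
        e.strategies.add("denovo")
        samples_by_acc.setdefault(aln.target_accession, set()).add(
            contig.sample_id)
        if contig.sample_id not in groups:
            raise FormatError(
                f"contig sample {contig.sample_id!r} has no group assignment"
            )
        if cls is ContigClass.CANONICAL:
            e.covered_denovo.update(
                range(aln.target_start, aln.target_end))
            canonical_contig_seqs.append(contig.sequence)
        else:  # noncanonical variant: matched columns only
            e.covered_noncanonical.update(aln.matched_target_positions)

    # sample counts split by group
    for acc, samples in samples_by_acc.items():
        e = ev[acc]
        for s in samples:
            if s not in groups:
                raise FormatError(f"sample {s!r} has no group assignment")
            if groups[s] == "case":
                e.samples_case += 1
            else:
                e.samples_control += 1

    # proteotypic peptides: distinct detected sequences, library + canonical
    detected = [h.sequence for h in hits_library] + canonical_contig_seqs
    ptps = count_proteotypic(detected, db, config.il_equivalent)
    for acc, e in ev.items():
        e.ptp_count = ptps.get(acc, 0)
        if abundance is not None:
            e.tier = assign_tier(abundance.get(acc), config)
        e.group_specific = (
            e.samples_case >= config.group_specific_min_case
            and e.samples_control <= config.group_specific_max_control
            and e.ptp_count >= 1
        )
        for cov in (e.covered_library, e.covered_denovo,
                    e.covered_noncanonical):
            if cov and max(cov) >= e.length_aa:
                raise FormatError(
                    f"{acc}: coverage index beyond protein length")
    return sorted(ev.values(), key=lambda e: e.accession)


def filter_min_samples(evidence: Sequence[ProteinEvidence],
                       config: PipelineConfig,
                       per_group: bool = False) -> list[ProteinEvidence]:
    """Keep proteins detected in enough samples: pooled cohort by default
    (>= min_samples_detected overall); ``per_group`` applies the stricter
    reading (>= threshold in each group)."""
    k = config.min_samples_detected
    if per_group:
        return [e for e in evidence
                if e.samples_case >= k and e.samples_control >= k]
    return [e for e in evidence if e.samples_total >= k]


def strategy_overlap(
    evidence: Sequence[ProteinEvidence],
    clusters: Optional[Sequence[Cluster]] = None,
    member_strategy: Optional[dict[str, str]] = None,
) -> dict:
    """Disjoint (library_only, denovo_only, both) counts.

    Protein-level counts come from the evidence records. Peptide-level
    counts are computed on clusters when given: a cluster is "both" if
    it holds members from both strategies (``member_strategy`` maps
    member id -> strategy)."""
    prot = {"library_only": 0, "denovo_only": 0, "both": 0}
    for e in evidence:
        if e.strategies == {"library"}:
            prot["library_only"] += 1
        elif e.strategies == {"denovo"}:
            prot["denovo_only"] += 1
        elif e.strategies == {"library", "denovo"}:
            prot["both"] += 1
    out = {"proteins": prot}
    if clusters is not None:
        if member_strategy is None:
            raise ValueError("peptide overlap requires member_strategy")
        pep = {"library_only": 0, "denovo_only": 0, "both": 0}
        for cl in clusters:
            strategies = {member_strategy[m] for m in cl.members}
            if strategies == {"library"}:
                pep["library_only"] += 1
            elif strategies == {"denovo"}:
                pep["denovo_only"] += 1
            else:
                pep["both"] += 1
        out["peptides"] = pep
    return out


def select_group_specific(evidence: Sequence[ProteinEvidence],
                          config: PipelineConfig) -> list[str]:
    """Proteins detected predominantly in case samples: Sz >= min_case,
    Cnt <= max_control and at least one proteotypic peptide."""
    return [e.accession for e in evidence if e.group_specific]


LENGTH_BINS = ((10, 100), (100, 1000), (1000, 10000))


def summarize_length_bins(evidence: Sequence[ProteinEvidence],
                          db: Sequence[ReferenceProtein]) -> dict:
    """Log-decade length histogram of identifications per strategy plus
    per-protein (length, coverage %, strategy) scatter tuples."""
    lengths = {p.accession: p.length_aa for p in db}
    hist = {"library": [0] * len(LENGTH_BINS),
            "denovo": [0] * len(LENGTH_BINS)}
    scatter: list[tuple[int, float, str]] = []
    for e in evidence:
        L = lengths[e.accession]
        bin_idx = next((k for k, (lo, hi) in enumerate(LENGTH_BINS)
                        if lo <= L < hi), None)
        for strategy, cov in (("library", e.covered_library),
                              ("denovo", e.covered_denovo)):
            if strategy in e.strategies:
                if bin_idx is not None:
                    hist[strategy][bin_idx] += 1
                scatter.append((L, 100.0 * len(cov) / L, strategy))
    return {"bins": LENGTH_BINS, "hist": hist, "scatter": scatter}


def coverage_augmentation(evidence: Sequence[ProteinEvidence],
                          db: Sequence[ReferenceProtein]) -> pd.DataFrame:
    """Per-protein coverage by strategy and the extra residues that only
    noncanonical contigs reach (the coverage-augmentation report)."""
    rows = []
    for e in evidence:
        extra = e.covered_noncanonical - (e.covered_library | e.covered_denovo)
        rows.append({
            "accession": e.accession,
            "length_aa": e.length_aa,
            "library_aa": len(e.covered_library),
            "library_pct": coverage_percent(e.covered_library, e.length_aa),
            "denovo_aa": len(e.covered_denovo),
            "denovo_pct": coverage_percent(e.covered_denovo, e.length_aa),
            "noncanonical_aa": len(e.covered_noncanonical),
            "noncanonical_pct": coverage_percent(e.covered_noncanonical,
                                                 e.length_aa),
            "additional_aa": len(extra),
            "additional_pct": coverage_percent(extra, e.length_aa),
        })
    return pd.DataFrame(
        rows, columns=["accession", "length_aa", "library_aa", "library_pct",
                       "denovo_aa", "denovo_pct", "noncanonical_aa",
                       "noncanonical_pct", "additional_aa", "additional_pct"])
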