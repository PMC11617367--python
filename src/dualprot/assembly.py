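"""De Bruijn assembly of de novo peptide reads into contigs.

Reads are decomposed into k-mers (k=8 by default, matching the upstream
de novo pipeline); each k-mer is an edge between its prefix and suffix
(k-1)-mers, weighted by the summed mean per-residue confidence of the
supporting read windows. Contigs are extracted greedily: seed at the
heaviest unused edge and extend in both directions along the heaviest
unused edge, breaking ties lexicographically by k-mer, so assembly is
fully deterministic and independent of read order. Path extension never
reuses an edge, which both terminates cycles and makes every edge
support at most one contig.

Assembly is per sample: contig occurrence counts across samples are a
downstream quantity, so reads from different samples are never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import DenovoRead

log = logging.getLogger(__name__)


@dataclass
class _Edge:
    kmer: str
    weight: float = 0.0
    count: int = 0


@dataclass
class DeBruijnGraph:
    k: int
    edges: dict[str, _Edge] = field(default_factory=dict)
    # adjacency: (k-1)-mer node -> sorted list of k-mer edges
    out_edges: dict[str, list[str]] = field(default_factory=dict)
    in_edges: dict[str, list[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class Contig:
    sequence: str
    support_reads: int
    mean_confidence: float
    sample_id: str


def build_graph(reads: list[DenovoRead], k: int) -> DeBruijnGraph:
    """Build the confidence-weighted de Bruijn graph of all read k-mers.

    Each window occurrence adds 1 to the edge count and the window's
    mean per-residue confidence to the edge weight. Reads shorter than
    k are skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    g = DeBruijnGraph(k=k)
    n_short = 0
    for read in reads:
        if len(read.sequence) < k:
            n_short += 1
            continue
        conf = read.confidence
        for i in range(len(read.sequence) - k + 1):
            kmer = read.sequence[i:i + k]
            edge = g.edges.get(kmer)
            if edge is None:
                edge = g.edges[kmer] = _Edge(kmer)
                g.out_edges.setdefault(kmer[:-1], []).append(kmer)
                g.in_edges.setdefault(kmer[1:], []).append(kmer)
            edge.count += 1
            edge.weight += sum(conf[i:i + k]) / k
    if n_short:
        log.warning("skipped %d reads shorter than k=%d", n_short, k)
    if not g.edges:
        log.warning("all reads shorter than k=%d: empty graph", k)
    for adj in (g.out_edges, g.in_edges):
        for node in adj:
            adj[node].sort()
    return g


def _pick(graph: DeBruijnGraph, candidates: list[str], used: set[str]):
    """Heaviest unused edge among candidates, ties lexicographic."""
    best = None
    for kmer in candidates:
        if kmer in used:
            continue
        e = graph.edges[kmer]
        if best is None or (e.weight, _NEG(e.kmer)) > (best.weight, _NEG(best.kmer)):
            best = e
    return best


class _NEG(str):
    """Inverts string comparison so max() prefers the lexicographically
    smaller k-mer on weight ties."""
    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)
    def __gt__(self, other):
        return str.__lt__(self, other)


def assemble(graph: DeBruijnGraph, min_len: int = 10,
             sample_id: str = "") -> list[Contig]:
    """Extract maximal weight-greedy paths as contigs (length >= min_len),
    sorted by (support_reads desc, sequence asc)."""
    used: set[str] = set()
    contigs: list[Contig] = []
    seeds = sorted(graph.edges.values(),
                   key=lambda e: (-e.weight, e.kmer))
    for seed in seeds:
        if seed.kmer in used:
            continue
        path = [seed.kmer]
        used.add(seed.kmer)
        # extend right from the suffix node
        while True:
            nxt = _pick(graph, graph.out_edges.get(path[-1][1:], []), used)
            if nxt is None:
                break
            path.append(nxt.kmer)
            used.add(nxt.kmer)
        # extend left from the prefix node
        while True:
            prv = _pick(graph, graph.in_edges.get(path[0][:-1], []), used)
            if prv is None:
                break
            path.insert(0, prv.kmer)
            used.add(prv.kmer)
        seq = path[0] + "".join(kmer[-1] for kmer in path[1:])
        if len(seq) < min_len:
            continue
        edges = [graph.edges[kmer] for kmer in path]
        total_count = sum(e.count for e in edges)
        total_weight = sum(e.weight for e in edges)
        contigs.append(Contig(
            sequence=seq,
            support_reads=max(e.count for e in edges),
            mean_confidence=total_weight / total_count if total_count else 0.0,
            sample_id=sample_id,
        ))
    contigs.sort(key=lambda c: (-c.support_reads, c.sequence))
    return contigs


def assemble_reads(reads: list[DenovoRead], k: int = 8,
                   min_len: int = 10) -> list[Contig]:
    """Group reads by sample, assemble each sample independently and
    concatenate the per-sample contig lists (samples in sorted order)."""
    by_sample: dict[str, list[DenovoRead]] = {}
    for r in reads:
        by_sample.setdefault(r.sample_id, []).append(r)
    contigs: list[Contig] = []
    for sample in sorted(by_sample):
        g = build_graph(by_sample[sample], k)
        contigs.extend(assemble(g, min_len=min_len, sample_id=sample))
    return contigs
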