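"""Local alignment, contig-to-reference mapping and greedy clustering.

The mapping stage gates contigs at 75% identity against the reference
proteome (identity over aligned columns); clustering unites peptides and
contigs at >=95% identity where the denominator is the shorter sequence,
so a tryptic peptide nested in a longer contig, or a missed-cleavage
extension, falls into the same cluster.

Alignment is exact affine-gap Smith-Waterman (no heuristic seeding): the
databases at play are desk-scale and exactness keeps the identity gates
meaningful. A gap of length L scores ``gap_open + (L-1)*gap_extend``.
When I/L equivalence is on (the default), Ile and Leu count as matches:
de novo reads cannot distinguish the two isobaric residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from ._util import collapse_il
from .io import ReferenceProtein


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -1
    gap_open: int = -3    # score of the first gapped column
    gap_extend: int = -1  # each further gapped column

DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    query: str
    target_accession: str
    target_start: int          # 0-based half-open target window
    target_end: int
    aligned_columns: int       # gap columns included
    matches: int
    identity_pct: float
    mismatch_positions: list[tuple[int, int, str, str]] = field(default_factory=list)
    query_start: int = 0
    query_end: int = 0
    matched_target_positions: list[int] = field(default_factory=list)
    gaps: int = 0
    score: int = 0


class ContigClass(Enum):
    CANONICAL = "canonical"
    NONCANONICAL_VARIANT = "noncanonical_variant"
    UNMATCHED = "unmatched"


NEG_INF = -(10 ** 9)


def align_local(query: str, target: str, scoring: Scoring = DEFAULT_SCORING,
                il_equivalent: bool = True) -> Optional[Alignment]:
    """Optimal local alignment by affine-gap dynamic programming.

    Returns None when the best local score is <= 0 (no hit). Among
    co-optimal cells the one with the smallest target end (then query
    end) wins, and traceback prefers diagonal moves over gaps, which
    keeps results deterministic and gap-minimal.
    """
    if not query or not target:
        raise ValueError("align_local requires non-empty sequences")
    q = collapse_il(query) if il_equivalent else query
    t = collapse_il(target) if il_equivalent else target
    m, n = len(q), len(t)
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend

    # H/E/F as (m+1) x (n+1); E = gap in query (consumes target),
    # F = gap in target (consumes query).
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    F = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for j in range(1, n + 1):
        tc = t[j - 1]
        for i in range(1, m + 1):
            e = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            f = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            d = H[i - 1][j - 1] + (ma if q[i - 1] == tc else mi)
            h = max(0, d, e, f)
            E[i][j] = e
            F[i][j] = f
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None

    # traceback (state-aware), preferring diagonal, then E, then F
    i, j = bi, bj
    cols = []  # (qpos or None, tpos or None)
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            d = H[i - 1][j - 1] + (ma if q[i - 1] == t[j - 1] else mi)
            if h == d:
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((None, j - 1))
            if E[i][j] == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:  # F
            cols.append((i - 1, None))
            if F[i][j] == H[i - 1][j] + go:
                state = "H"
            i -= 1
    cols.reverse()

    matches = 0
    mismatches: list[tuple[int, int, str, str]] = []
    matched_tpos: list[int] = []
    gaps = 0
    for qp, tp in cols:
        if qp is None or tp is None:
            gaps += 1
        elif q[qp] == t[tp]:
            matches += 1
            matched_tpos.append(tp)
        else:
            mismatches.append((qp, tp, query[qp], target[tp]))
    aligned_columns = len(cols)
    return Alignment(
        query=query, target_accession="",
        target_start=j, target_end=bj,
        aligned_columns=aligned_columns, matches=matches,
        identity_pct=100.0 * matches / aligned_columns,
        mismatch_positions=mismatches,
        query_start=i, query_end=bi,
        matched_target_positions=matched_tpos,
        gaps=gaps, score=best,
    )


def _substring_alignment(query: str, target: str, start: int) -> Alignment:
    """Exact-substring fast path: a gapless 100%-identity alignment."""
    L = len(query)
    return Alignment(
        query=query, target_accession="",
        target_start=start, target_end=start + L,
        aligned_columns=L, matches=L, identity_pct=100.0,
        query_start=0, query_end=L,
        matched_target_positions=list(range(start, start + L)),
        gaps=0, score=L * DEFAULT_SCORING.match,
    )


def map_contig(contig_seq: str, db: Sequence[ReferenceProtein],
               min_identity: float = 75.0, il_equivalent: bool = True,
               scoring: Scoring = DEFAULT_SCORING,
               ) -> tuple[Optional[Alignment], ContigClass]:
    """Map a contig against the reference proteome.

    The best hit maximizes identity, ties broken by more aligned columns
    then accession order; an alignment only counts as a hit when it
    covers at least half the contig. Classification: 100% identity is
    canonical, [min_identity, 100) is a noncanonical variant, anything
    weaker (or no hit) is unmatched.
    """
    if not db:
        raise ValueError("map_contig requires a non-empty database")
    seq = getattr(contig_seq, "sequence", contig_seq)
    cq = collapse_il(seq) if il_equivalent else seq
    best: Optional[Alignment] = None
    for prot in sorted(db, key=lambda p: p.accession):
        pos = (collapse_il(prot.sequence) if il_equivalent
               else prot.sequence).find(cq)
        if pos >= 0:
            aln = _substring_alignment(seq, prot.sequence, pos)
        else:
            aln = align_local(seq, prot.sequence, scoring, il_equivalent)
            if aln is None:
                continue
            if aln.query_end - aln.query_start < 0.5 * len(seq):
                continue
        aln.target_accession = prot.accession
        if best is None or (aln.identity_pct, aln.aligned_columns) > (
                best.identity_pct, best.aligned_columns):
            best = aln
    if best is None:
        return None, ContigClass.UNMATCHED
    # canonical = the whole contig matches exactly (an exact substring up
    # to I/L); a clipped 100%-identity window is a variant, not canonical
    if best.matches == len(seq):
        return best, ContigClass.CANONICAL
    if best.identity_pct >= min_identity:
        return best, ContigClass.NONCANONICAL_VARIANT
    return best, ContigClass.UNMATCHED


@dataclass
class Cluster:
    centroid: str           # sequence of the centroid (longest member)
    centroid_id: str
    members: list[str]      # member ids, centroid first


def pair_identity(a: str, b: str, il_equivalent: bool = True,
                  scoring: Scoring = DEFAULT_SCORING) -> float:
    """Identity with the shorter sequence as denominator:
    100 * matches / min(len(a), len(b)) from the optimal local alignment.
    This is the clustering identity, designed to unite sequences of
    different lengths (nested peptides, missed-cleavage extensions)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    cs = collapse_il(short) if il_equivalent else short
    cl = collapse_il(long_) if il_equivalent else long_
    if cl.find(cs) >= 0:
        return 100.0
    aln = align_local(short, long_, scoring, il_equivalent)
    if aln is None:
        return 0.0
    return 100.0 * aln.matches / len(short)


def cluster_greedy(seqs: Sequence[tuple[str, str]], min_identity: float = 95.0,
                   il_equivalent: bool = True) -> list[Cluster]:
    """Usearch-style greedy centroid clustering.

    Sequences are visited by length (desc), then sequence, then id; the
    first unassigned sequence founds a cluster and later sequences join
    the first centroid (in founding order) they match at
    >= min_identity under the min-length-denominator identity.
    """
    if not seqs:
        return []
    order = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    clusters: list[Cluster] = []
    for sid, seq in order:
        placed = False
        for cl in clusters:
            if pair_identity(seq, cl.centroid, il_equivalent) >= min_identity:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid=seq, centroid_id=sid,
                                    members=[sid]))
    return clusters


def count_proteotypic(peptides: Sequence[str], db: Sequence[ReferenceProtein],
                      il_equivalent: bool = True) -> dict[str, int]:
    """Count detected proteotypic peptides per protein.

    A peptide is proteotypic iff it occurs as a substring of exactly one
    database protein (I/L-equivalent when configured); shared peptides
    count for no protein. Duplicated input sequences count once."""
    db_sorted = sorted(db, key=lambda p: p.accession)
    texts = [(p.accession,
              collapse_il(p.sequence) if il_equivalent else p.sequence)
             for p in db_sorted]
    counts = {p.accession: 0 for p in db_sorted}
    distinct = {collapse_il(p) if il_equivalent else p for p in peptides}
    for cp in sorted(distinct):
        owners = [acc for acc, text in texts if cp in text]
        if len(owners) == 1:
            counts[owners[0]] += 1
    return counts
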