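"""Synthetic cohort generator with ground truth.

Emulates the statistical structure of a two-group plasma DDA study:

* a reference proteome of i.i.d. sequences at human background residue
  frequencies, with plasma concentrations drawn log-uniformly inside
  three abundance tiers (high > 1 μg/mL, mid 10 ng/mL–1 μg/mL, low
  below that);
* per-sample presence/absence detection with tier-dependent probability
  (the published cohort is 48 cases / 50 controls);
* library-strategy output: a random subset of tryptic peptides
  (cleavage after K/R except before P, up to 2 missed cleavages) with
  occasional phospho-PTM annotations;
* de novo-strategy output: overlapping confidence-scored reads tiling
  protein segments, with I/L-biased substitutions and adjacent
  transpositions as the error model;
* planted case-specific proteins (detected in cases only) and planted
  noncanonical variant segments (single-residue substitutions placing
  the segment's identity to its source protein inside [75, 100)), which
  are dropped from the library channel so they surface only de novo.

Everything planted is recorded in a SimTruth object so downstream
stages can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
from pyteomics import parser as _pparser

from .errors import ConfigError
from .io import (AbundanceTable, DenovoRead, PeptideHit, ReferenceProtein,
                 write_abundance, write_fasta, write_identifications)

#: Swiss-Prot background amino-acid frequencies (mole fractions).
AA_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

TRYPSIN_RULE = r"[KR](?!P)"  # cleave after K/R except before P

#: log-uniform concentration ranges per tier, g/L
TIER_CONC_RANGES = {"high": (2e-3, 50.0), "mid": (1e-5, 1e-3),
                    "low": (1e-8, 9e-6)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort (defaults = published
    cohort sizes and plausible plasma detection behavior)."""

    n_case: int = 48
    n_control: int = 50
    n_proteins: int = 150
    length_min: int = 50
    length_max: int = 3000
    tier_fractions: tuple[float, float, float] = (0.23, 0.20, 0.57)
    detect_prob_by_tier: tuple[float, float, float] = (0.9, 0.5, 0.15)
    library_miss_rate: float = 1.0
    denovo_sub_rate: float = 0.01
    denovo_transpose_rate: float = 0.005
    n_group_specific: int = 5
    n_noncanonical: int = 5
    sap_rate: float = 0.1
    phospho_rate: float = 0.02
    read_length: int = 20
    read_step: int = 5
    segment_len: tuple[int, int] = (25, 50)
    segments_per_protein: int = 2
    peptide_detect_prob: float = 0.6
    missed_cleavages_max: int = 2
    min_peptide_len: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("library_miss_rate", "denovo_sub_rate",
                     "denovo_transpose_rate", "sap_rate", "phospho_rate",
                     "peptide_detect_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.detect_prob_by_tier):
            raise ConfigError("detect probabilities must be in [0, 1]")
        if abs(sum(self.tier_fractions) - 1.0) > 1e-9:
            raise ConfigError("tier_fractions must sum to 1")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ConfigError("cohort sizes must be positive")


def noise_free(cfg: SimConfig) -> SimConfig:
    """The noise-free variant of a configuration: certain detection,
    complete peptide emission, no de novo read errors. Planted
    noncanonical proteins still bypass the library channel."""
    return replace(cfg, detect_prob_by_tier=(1.0, 1.0, 1.0),
                   denovo_sub_rate=0.0, denovo_transpose_rate=0.0,
                   peptide_detect_prob=1.0, library_miss_rate=1.0)


@dataclass
class SimTruth:
    tiers: dict[str, str] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    group_specific: list[str] = field(default_factory=list)
    noncanonical: list[dict] = field(default_factory=list)
    denovo_segments: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)
    detected: dict[str, list[str]] = field(default_factory=dict)
    phospho_sites: list[dict] = field(default_factory=list)
    sample_groups: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        raw = json.loads(Path(path).read_text())
        truth = cls(**raw)
        truth.denovo_segments = {
            k: [tuple(v) for v in vs]
            for k, vs in truth.denovo_segments.items()}
        return truth


@dataclass
class SimCohort:
    config: SimConfig
    proteins: list[ReferenceProtein]
    abundance: AbundanceTable
    library_hits: list[PeptideHit]
    denovo_reads: list[DenovoRead]
    truth: SimTruth


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest_tryptic_positions(sequence: str, missed_max: int = 2,
                             min_len: int = 6) -> list[tuple[int, str]]:
    """In-silico tryptic digestion with positions: cleave after K/R
    except before P; all peptides with 0..missed_max missed cleavages and
    length >= min_len, as (0-based start, peptide), sorted."""
    out = {(start, pep)
           for start, pep in _pparser.icleave(
               sequence, TRYPSIN_RULE, missed_cleavages=missed_max,
               min_length=min_len)}
    return sorted(out)


def digest_tryptic(sequence: str, missed_max: int = 2,
                   min_len: int = 6) -> list[str]:
    return [pep for _start, pep in
            digest_tryptic_positions(sequence, missed_max, min_len)]


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def generate_proteome(cfg: SimConfig,
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[list[ReferenceProtein], AbundanceTable,
                                 dict[str, str]]:
    """Random reference proteome + abundance table + per-protein tier."""
    if cfg.n_proteins < cfg.n_group_specific + cfg.n_noncanonical:
        raise ConfigError(
            "n_proteins must cover planted group-specific and "
            "noncanonical proteins")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    letters = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    proteins: list[ReferenceProtein] = []
    tiers: dict[str, str] = {}
    conc: dict[str, float] = {}
    log_lo, log_hi = np.log(cfg.length_min), np.log(cfg.length_max)
    tier_names = ("high", "mid", "low")
    for i in range(cfg.n_proteins):
        L = int(np.exp(rng.uniform(log_lo, log_hi)))
        seq = "".join(rng.choice(letters, size=L, p=probs))
        acc = f"SYN{i + 1:04d}"
        proteins.append(ReferenceProtein(
            accession=acc, sequence=seq, name=f"SYN{i + 1:04d}_SYNTH",
            gene=f"SYNG{i + 1}"))
        tier = tier_names[rng.choice(3, p=np.array(cfg.tier_fractions))]
        lo, hi = TIER_CONC_RANGES[tier]
        tiers[acc] = tier
        conc[acc] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return proteins, AbundanceTable(conc), tiers


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _choose_segments(rng, L: int, cfg: SimConfig) -> list[tuple[int, int]]:
    """Mutually disjoint detected regions (overlapping regions would
    conflate a variant segment with canonical reads of the same span)."""
    segs: list[tuple[int, int]] = []
    for _ in range(cfg.segments_per_protein):
        for _attempt in range(20):
            slen = int(rng.integers(cfg.segment_len[0],
                                    cfg.segment_len[1] + 1))
            slen = min(slen, L)
            start = int(rng.integers(0, L - slen + 1))
            if all(start + slen <= s or e <= start for s, e in segs):
                segs.append((start, start + slen))
                break
    return sorted(segs)


def _variant_of(rng, segment: str) -> tuple[str, int]:
    """Substitute residues so identity to the source lands in [75, 100).

    Edits stay >= 2 residues from the segment ends (local alignment
    would otherwise clip terminal mismatches) and never produce an
    I<->L pair, which would still count as a match under I/L
    equivalence."""
    L = len(segment)
    max_edits = max(1, int(L * 0.25) - 1)
    n_edits = int(np.clip(rng.binomial(L, 0.1), 1, max_edits))
    interior = np.arange(2, L - 2)
    pos = rng.choice(interior, size=min(n_edits, len(interior)),
                     replace=False)
    seq = list(segment)
    alphabet = list(AA_FREQS)
    for p in sorted(int(x) for x in pos):
        old = seq[p]
        banned = {old} | ({"I", "L"} if old in ("I", "L") else set())
        choices = [c for c in alphabet if c not in banned]
        seq[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq), len(pos)


def _noise_read(rng, seq: str, cfg: SimConfig) -> str:
    out = list(seq)
    alphabet = list(AA_FREQS)
    for i, ch in enumerate(out):
        if rng.random() < cfg.denovo_sub_rate:
            if ch == "I":
                out[i] = "L"
            elif ch == "L":
                out[i] = "I"
            else:
                choices = [c for c in alphabet if c != ch]
                out[i] = choices[int(rng.integers(0, len(choices)))]
    i = 0
    while i < len(out) - 1:
        if rng.random() < cfg.denovo_transpose_rate:
            out[i], out[i + 1] = out[i + 1], out[i]
            i += 2
        else:
            i += 1
    return "".join(out)


def _tile_windows(L: int, rl: int, step: int) -> list[int]:
    if L <= rl:
        return [0]
    starts = list(range(0, L - rl + 1, step))
    if starts[-1] != L - rl:
        starts.append(L - rl)
    return starts


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Generate one full synthetic cohort with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    proteins, abundance, tiers = generate_proteome(cfg, rng)
    by_acc = {p.accession: p for p in proteins}
    accs = [p.accession for p in proteins]

    planted = rng.choice(len(accs), size=cfg.n_group_specific
                         + cfg.n_noncanonical, replace=False)
    gs_accs = sorted(accs[int(i)] for i in planted[:cfg.n_group_specific])
    nc_accs = sorted(accs[int(i)] for i in planted[cfg.n_group_specific:])

    truth = SimTruth(tiers=dict(tiers),
                     concentrations={a: abundance.get(a) for a in accs},
                     group_specific=list(gs_accs))

    # de novo segments per protein; one variant segment per noncanonical
    segments: dict[str, list[tuple[int, int, str]]] = {}
    for p in proteins:
        segs = _choose_segments(rng, p.length_aa, cfg)
        entries = [(s, e, p.sequence[s:e]) for s, e in segs]
        if p.accession in nc_accs:
            s, e = segs[0]
            variant, n_edits = _variant_of(rng, p.sequence[s:e])
            entries[0] = (s, e, variant)
            truth.noncanonical.append({
                "accession": p.accession, "start": s, "end": e,
                "variant": variant, "n_edits": n_edits,
                "identity_pct": 100.0 * (e - s - n_edits) / (e - s),
            })
        segments[p.accession] = entries
        truth.denovo_segments[p.accession] = [(s, e) for s, e, _ in entries]

    peptides_cache = {
        p.accession: digest_tryptic_positions(
            p.sequence, cfg.missed_cleavages_max, cfg.min_peptide_len)
        for p in proteins}

    tier_prob = dict(zip(("high", "mid", "low"), cfg.detect_prob_by_tier))
    samples = ([(f"SZ{i + 1:03d}", "case") for i in range(cfg.n_case)]
               + [(f"CNT{i + 1:03d}", "control")
                  for i in range(cfg.n_control)])
    truth.sample_groups = dict(samples)

    library_hits: list[PeptideHit] = []
    denovo_reads: list[DenovoRead] = []

    for sample_id, group in samples:
        detected: list[str] = []
        for acc in accs:
            p_detect = tier_prob[tiers[acc]]
            if acc in gs_accs and group == "control":
                p_detect = 0.0
            if rng.random() >= p_detect:
                continue
            detected.append(acc)
            # library channel
            skip_library = (acc in nc_accs
                            and rng.random() < cfg.library_miss_rate)
            if not skip_library:
                peps = peptides_cache[acc]
                mask = rng.random(len(peps)) < cfg.peptide_detect_prob
                if not mask.any() and len(peps):
                    mask[int(rng.integers(0, len(peps)))] = True
                for (start, pep), keep in zip(peps, mask):
                    if not keep:
                        continue
                    mods = ()
                    if rng.random() < cfg.phospho_rate:
                        sty = [k for k, ch in enumerate(pep)
                               if ch in "STY"]
                        if sty:
                            k = sty[int(rng.integers(0, len(sty)))]
                            mod = {"S": "SEP", "T": "TPO",
                                   "Y": "PTR"}[pep[k]]
                            mods = ((k + 1, mod),)
                            truth.phospho_sites.append({
                                "accession": acc, "sample_id": sample_id,
                                "position_1based": start + k + 1,
                                "mod": mod, "peptide": pep,
                            })
                    library_hits.append(PeptideHit(
                        sample_id=sample_id, group=group, sequence=pep,
                        proteins=(acc,), modifications=mods))
            # de novo channel
            for s, e, segseq in segments[acc]:
                for w in _tile_windows(len(segseq), cfg.read_length,
                                       cfg.read_step):
                    window = segseq[w:w + cfg.read_length]
                    read = _noise_read(rng, window, cfg)
                    conf = tuple(float(c) for c in
                                 rng.beta(8.0, 2.0, size=len(read)))
                    denovo_reads.append(DenovoRead(sample_id, read, conf))
        truth.detected[sample_id] = detected

    return SimCohort(config=cfg, proteins=proteins, abundance=abundance,
                     library_hits=library_hits, denovo_reads=denovo_reads,
                     truth=truth)


def write_cohort(cohort: SimCohort, outdir: str | Path) -> None:
    """Write ref.fasta, abundance.tsv, library.tsv, denovo_reads.tsv and
    truth.json; byte-deterministic for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.proteins, outdir / "ref.fasta")
    write_abundance(cohort.abundance, outdir / "abundance.tsv")
    write_identifications(cohort.library_hits, outdir / "library.tsv",
                          "library")
    write_identifications(cohort.denovo_reads, outdir / "denovo_reads.tsv",
                          "denovo")
    cohort.truth.to_json(outdir / "truth.json")
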