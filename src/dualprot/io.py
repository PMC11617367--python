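"""Data model and readers/writers for every external format the pipeline touches.

Formats
-------
* Reference proteome: FASTA with UniProt-style ``db|ACC|NAME`` headers (a
  plain token is also accepted as the accession).
* Library-search identifications: TSV with columns
  ``sample_id, group, peptide, proteins, mods``. Proteins are
  ``;``-separated accessions; modifications may be given either inline in
  the peptide with bracket notation (``A[SEP]QPQ…``) or in the ``mods``
  column as ``pos:type`` entries separated by ``;``.
* De novo reads: TSV with columns ``sample_id, peptide, confidence`` where
  confidence is a comma-separated list of per-residue reals in [0, 1].
* Abundance: TSV ``accession, concentration_g_per_L`` (SI units in-file).
* Structures: PDB or mmCIF, parsed with gemmi; per-residue model
  confidence is carried in the B-factor column, as AlphaFold models do.

Coordinates and residue indices are 0-based half-open internally;
1-based inclusive numbering appears only at I/O boundaries (PTM sites,
reported positions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
from Bio import SeqIO

from ._util import AA_SET
from .errors import FormatError

log = logging.getLogger(__name__)

MOD_TYPES = ("SEP", "TPO", "PTR")
#: residue each phospho-modification is chemically possible on
MOD_RESIDUE = {"SEP": "S", "TPO": "T", "PTR": "Y"}

GROUPS = ("case", "control")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceProtein:
    """One entry of the reference proteome (the mapping target)."""

    accession: str
    sequence: str
    name: str = ""
    gene: str = ""
    localization: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.accession!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in AA_SET:
                raise FormatError(
                    f"protein {self.accession!r}: illegal residue {ch!r} "
                    f"at position {i + 1}"
                )

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideHit:
    """A library-search peptide identification in one sample."""

    sample_id: str
    group: str
    sequence: str
    proteins: tuple[str, ...]
    modifications: tuple[tuple[int, str], ...] = ()  # (position_1based, type)
    strategy: str = "library"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        for pos, mod in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise FormatError(
                    f"peptide {self.sequence!r}: modification position {pos} "
                    "outside the sequence"
                )
            expected = MOD_RESIDUE.get(mod)
            if expected is not None and self.sequence[pos - 1] != expected:
                raise FormatError(
                    f"peptide {self.sequence!r}: {mod} at position {pos} "
                    f"sits on {self.sequence[pos - 1]!r}, expected {expected!r}"
                )


@dataclass(frozen=True)
class DenovoRead:
    """A de novo sequencing read with per-residue confidence scores."""

    sample_id: str
    sequence: str
    confidence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.confidence) != len(self.sequence):
            raise FormatError(
                f"read {self.sequence!r}: {len(self.confidence)} confidence "
                f"values for {len(self.sequence)} residues"
            )
        if any(not 0.0 <= c <= 1.0 for c in self.confidence):
            raise FormatError(
                f"read {self.sequence!r}: confidence outside [0, 1]"
            )


class AbundanceTable:
    """Maps accession -> plasma concentration in g/L (SI internally)."""

    def __init__(self, concentrations: dict[str, float]):
        for acc, c in concentrations.items():
            if c <= 0:
                raise FormatError(
                    f"abundance for {acc!r} must be positive, got {c}"
                )
        self._conc = dict(concentrations)

    def get(self, accession: str) -> Optional[float]:
        return self._conc.get(accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self._conc

    def __len__(self) -> int:
        return len(self._conc)

    def items(self):
        return self._conc.items()


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    residue_index: int      # author numbering from the file (1-based)
    residue_name: str
    chain: str


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """A single structural model: a flat atom list plus helpers.

    Per-residue model confidence (e.g. AlphaFold pLDDT) rides in the
    B-factor column of each atom.
    """

    atoms: list[Atom] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_index, residue_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.residue_index), a.residue_name)
        return [(c, i, n) for (c, i), n in seen.items()]

    def residue_atoms(self, chain: str, residue_index: int) -> list[Atom]:
        return [a for a in self.atoms
                if a.chain == chain and a.residue_index == residue_index]

    def sequence(self, chain: Optional[str] = None) -> str:
        res = [r for r in self.residues() if chain is None or r[0] == chain]
        return "".join(THREE_TO_ONE.get(n, "X") for _, _, n in res)

    def copy(self) -> "StructureModel":
        return StructureModel(list(self.atoms))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_GN_RE = re.compile(r"\bGN=(\S+)")


def _parse_fasta_header(header_id: str, description: str) -> tuple[str, str, str]:
    parts = header_id.split("|")
    if len(parts) >= 3:
        acc, name = parts[1], parts[2]
    else:
        acc, name = header_id, ""
    m = _GN_RE.search(description)
    gene = m.group(1) if m else ""
    return acc, name, gene


def read_fasta(path: str | Path) -> list[ReferenceProtein]:
    """Read a reference proteome. Rejects non-canonical residues
    (including B/Z/X/U/O) and empty records, naming the offender."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    proteins = []
    seen: set[str] = set()
    for rec in records:
        acc, name, gene = _parse_fasta_header(rec.id, rec.description)
        if acc in seen:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        proteins.append(
            ReferenceProtein(accession=acc, sequence=str(rec.seq).upper(),
                             name=name, gene=gene)
        )
    return proteins


def write_fasta(proteins: Iterable[ReferenceProtein], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = f"sp|{p.accession}|{p.name}" if p.name else p.accession
            if p.gene:
                header += f" GN={p.gene}"
            fh.write(f">{header}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# identification tables
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(r"\[([A-Z]{2,4})\]")

LIBRARY_COLUMNS = ("sample_id", "group", "peptide", "proteins", "mods")
DENOVO_COLUMNS = ("sample_id", "peptide", "confidence")


def parse_modified_sequence(seq: str) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Split bracket PTM notation in which the bracket token stands in
    for the modified residue itself: ``A[SEP]QPQALLVIAR`` ->
    (``ASQPQALLVIAR``, ((2, "SEP"),)); a sequence may begin with a
    bracket (``[SEP]QGGE…`` is a phosphoserine at position 1)."""
    plain: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch == "[":
            m = _BRACKET_RE.match(seq, i)
            residue = MOD_RESIDUE.get(m.group(1)) if m else None
            if residue is None:
                raise FormatError(f"peptide {seq!r}: malformed PTM bracket")
            plain.append(residue)
            mods.append((len(plain), m.group(1)))
            i = m.end()
        else:
            plain.append(ch)
            i += 1
    return "".join(plain), tuple(mods)


def _read_tsv_rows(path: str | Path, expected: tuple[str, ...]) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if set(header) != set(expected):
        unknown = set(header) - set(expected)
        missing = set(expected) - set(header)
        raise FormatError(
            f"{path}: bad header (unknown columns {sorted(unknown)}, "
            f"missing {sorted(missing)})"
        )
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
        rows.append(dict(zip(header, cells)) | {"__line__": lineno})
    return rows


def read_identifications(path: str | Path, strategy: str):
    """Read a library (``strategy="library"``) or de novo
    (``strategy="denovo"``) identification table."""
    if strategy == "library":
        rows = _read_tsv_rows(path, LIBRARY_COLUMNS)
        hits: list[PeptideHit] = []
        for row in rows:
            seq, bracket_mods = parse_modified_sequence(row["peptide"])
            mods = list(bracket_mods)
            if row["mods"]:
                for entry in row["mods"].split(";"):
                    entry = entry.strip()
                    if not entry:
                        continue
                    try:
                        pos_s, typ = entry.split(":")
                        mods.append((int(pos_s), typ))
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}:{row['__line__']}: bad mods entry {entry!r}"
                        ) from exc
            try:
                hits.append(PeptideHit(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    sequence=seq,
                    proteins=tuple(p for p in row["proteins"].split(";") if p),
                    modifications=tuple(sorted(set(mods))),
                ))
            except FormatError as exc:
                raise FormatError(f"{path}:{row['__line__']}: {exc}") from exc
        if not hits:
            log.warning("%s: no identification rows", path)
        return hits
    if strategy == "denovo":
        rows = _read_tsv_rows(path, DENOVO_COLUMNS)
        reads: list[DenovoRead] = []
        for row in rows:
            try:
                conf = tuple(float(x) for x in row["confidence"].split(",") if x)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{row['__line__']}: non-numeric confidence"
                ) from exc
            try:
                reads.append(DenovoRead(row["sample_id"], row["peptide"], conf))
            except FormatError as exc:
                raise FormatError(f"{path}:{row['__line__']}: {exc}") from exc
        if not reads:
            log.warning("%s: no de novo rows", path)
        return reads
    raise ValueError(f"unknown strategy {strategy!r}")


def _format_peptide(hit: PeptideHit) -> str:
    """Render a peptide with bracket PTM notation (the bracket token
    replaces the modified residue)."""
    out = []
    mods = dict(hit.modifications)
    for i, ch in enumerate(hit.sequence, start=1):
        if i in mods and mods[i] in MOD_RESIDUE:
            out.append(f"[{mods[i]}]")
        else:
            out.append(ch)
    return "".join(out)


def write_identifications(items, path: str | Path, strategy: str) -> None:
    with open(path, "w") as fh:
        if strategy == "library":
            fh.write("\t".join(LIBRARY_COLUMNS) + "\n")
            for h in items:
                fh.write("\t".join([
                    h.sample_id, h.group, _format_peptide(h),
                    ";".join(h.proteins), "",
                ]) + "\n")
        elif strategy == "denovo":
            fh.write("\t".join(DENOVO_COLUMNS) + "\n")
            for r in items:
                fh.write("\t".join([
                    r.sample_id, r.sequence,
                    ",".join(f"{c:.4f}" for c in r.confidence),
                ]) + "\n")
        else:
            raise ValueError(f"unknown strategy {strategy!r}")


def read_abundance(path: str | Path) -> AbundanceTable:
    rows = _read_tsv_rows(path, ("accession", "concentration_g_per_L"))
    conc = {}
    for row in rows:
        try:
            conc[row["accession"]] = float(row["concentration_g_per_L"])
        except ValueError as exc:
            raise FormatError(
                f"{path}:{row['__line__']}: non-numeric concentration"
            ) from exc
    return AbundanceTable(conc)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tconcentration_g_per_L\n")
        for acc, c in sorted(table.items()):
            fh.write(f"{acc}\t{c:.6g}\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only,
    waters excluded). Per-residue confidence is taken from B-factors."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models in structure")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            for at in res:
                el = at.element.name
                if not el or el == "X":
                    el = at.name.strip()[0]
                    log.warning("%s: inferred element %s for atom %s",
                                path, el, at.name)
                atoms.append(Atom(
                    name=at.name, element=el,
                    x=at.pos.x, y=at.pos.y, z=at.pos.z,
                    occupancy=at.occ, b_factor=at.b_iso,
                    residue_index=res.seqid.num,
                    residue_name=res.name, chain=chain.name,
                ))
    if not atoms:
        raise FormatError(f"{path}: no polymer atoms")
    return StructureModel(atoms)


ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB rendering of a StructureModel."""
    st = gemmi.Structure()
    st.name = "dualprot"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        key = (a.chain, a.residue_index)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_index, " ")
            chains[a.chain].add_residue(res)
            residues[key] = chains[a.chain][-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(a.x, a.y, a.z)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        residues[key].add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
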