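"""Peptide physicochemistry: tryptic status, average mass, aliphatic index.

The aliphatic index follows Ikai's mole-percent formula

    AI = X(Ala) + 2.9 * X(Val) + 3.9 * (X(Ile) + X(Leu))

where X(r) is the mole percent of residue r. Peptides with AI >= 70 are
conventionally flagged thermostable. Masses are average (not
monoisotopic) residue masses plus one water, reported in kDa.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

from ._util import AA_SET, round_half_up

#: Ikai's side-chain volume coefficients.
AI_COEFF_VAL = 2.9
AI_COEFF_ILE_LEU = 3.9
THERMOSTABLE_AI = 70.0


@dataclass(frozen=True)
class PeptideProps:
    sequence: str
    length_aa: int
    mw_kda: float
    aliphatic_index: float
    tryptic: bool
    thermostable: bool


def _check_canonical(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - AA_SET
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in {seq!r}")


def is_tryptic(seq: str) -> bool:
    """A tryptic peptide ends in Arg or Lys (trypsin cuts after K/R)."""
    if not seq:
        raise ValueError("empty sequence")
    return seq[-1] in ("R", "K")


def average_mass_kda(seq: str) -> float:
    """Average molecular mass in kDa (residue masses + one water)."""
    _check_canonical(seq)
    return _pmass.calculate_mass(sequence=seq, average=True) / 1000.0


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index (unrounded). Report with round_half_up."""
    _check_canonical(seq)
    n = len(seq)
    return 100.0 * (seq.count("A")
                    + AI_COEFF_VAL * seq.count("V")
                    + AI_COEFF_ILE_LEU * (seq.count("I") + seq.count("L"))) / n


def aliphatic_index_reported(seq: str) -> int:
    """Aliphatic index rounded half-up to integer, as printed in reports."""
    return int(round_half_up(aliphatic_index(seq)))


def format_mw_kda(mw_kda: float) -> str:
    """Report masses to one decimal below 10 kDa, integer above."""
    if mw_kda < 10:
        return f"{round_half_up(mw_kda, 1):.1f}"
    return f"{int(round_half_up(mw_kda))}"


def peptide_props(seq: str) -> PeptideProps:
    ai = aliphatic_index(seq)
    return PeptideProps(
        sequence=seq,
        length_aa=len(seq),
        mw_kda=average_mass_kda(seq),
        aliphatic_index=ai,
        tryptic=is_tryptic(seq),
        thermostable=ai >= THERMOSTABLE_AI,
    )
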