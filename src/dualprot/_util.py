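"""Small shared helpers: rounding and the amino-acid alphabet."""

from decimal import Decimal, ROUND_HALF_UP

#: The 20 canonical amino acids. Ambiguity codes (B, Z, X) and the rare
#: translated residues U/O are rejected at I/O because the downstream
#: mass and aliphatic-index formulas are defined only on this alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for all
    reported percentages and indices), avoiding banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if ndigits == 0 else v


def collapse_il(seq: str) -> str:
    """Map Ile to Leu so isobaric residues compare equal.

    De novo sequencing cannot distinguish Leu/Ile from fragment masses,
    so matching, clustering and proteotypic counting treat them as one
    residue when I/L equivalence is enabled.
    """
    return seq.replace("I", "L")
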