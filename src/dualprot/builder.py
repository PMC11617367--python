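"""Synthetic peptide structure builder (NeRF internal coordinates).

Builds an all-heavy-atom *backbone* model (N, CA, C, O plus CB and the
side-chain hydroxyl for Ser/Thr) of a short peptide at prescribed φ/ψ
torsions — enough geometry to exercise the SASA, phosphate-attachment
and secondary-structure operations on fully controlled fixtures.
These models are synthetic test scaffolds, not predicted structures.
"""

from __future__ import annotations

import math

import numpy as np

from .io import Atom, StructureModel, ONE_TO_THREE

# standard backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
B_C_O, A_CA_C_O = 1.231, 120.8
B_CA_CB, A_N_CA_CB, T_CB = 1.530, 110.5, -122.5
B_CB_OG, A_CA_CB_OG, T_OG = 1.417, 110.5, 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D such that
    |CD| = bond, angle(B,C,D) = angle and torsion(A,B,C,D) = torsion."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_peptide(sequence: str, phi: float, psi: float,
                  omega: float = 180.0, chain: str = "A",
                  b_factor: float = 90.0) -> StructureModel:
    """Build a peptide with uniform (φ, ψ) torsions.

    φ = -57, ψ = -47 gives an ideal α-helix; φ = -139, ψ = 135 an ideal
    β-strand; φ = -120, ψ = 120 a generic extended chain."""
    n_res = len(sequence)
    if n_res < 1:
        raise ValueError("empty sequence")
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    # seed residue 0 in the xy-plane
    N[0] = np.zeros(3)
    CA[0] = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    C[0] = CA[0] + np.array([-B_CA_C * math.cos(ang),
                             B_CA_C * math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          B_C_N, A_CA_C_N, psi)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           B_N_CA, A_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi)

    atoms: list[Atom] = []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE[aa]
        idx = i + 1

        def add(name: str, element: str, pos: np.ndarray) -> None:
            atoms.append(Atom(name, element, float(pos[0]), float(pos[1]),
                              float(pos[2]), 1.0, b_factor, idx, res_name,
                              chain))

        add("N", "N", N[i])
        add("CA", "C", CA[i])
        add("C", "C", C[i])
        if i + 1 < n_res:
            o = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi + 180.0)
        else:
            o = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi)
        add("O", "O", o)
        if aa != "G":
            cb = place_atom(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, T_CB)
            add("CB", "C", cb)
            if aa == "S":
                add("OG", "O", place_atom(N[i], CA[i], cb,
                                          B_CB_OG, A_CA_CB_OG, T_OG))
            elif aa == "T":
                add("OG1", "O", place_atom(N[i], CA[i], cb,
                                           B_CB_OG, A_CA_CB_OG, T_OG))
    return StructureModel(atoms)
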