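"""Structural phosphosite characterization.

Solvent-accessible surface area is computed with the Shrake–Rupley
method: each heavy atom's van der Waals sphere, inflated by the probe
radius (1.4 Å water), is sampled with a deterministic golden-section
(Fibonacci) point set; a point is exposed when it lies outside every
neighboring inflated sphere and the atom's SASA is the exposed fraction
of 4π(r+probe)².

K_SASA is the ratio of a peptide's SASA in the intact protein to its
SASA in the phosphorylated protein (phosphate atoms included in the
phospho state); values below 1 mean phosphorylation increased solvent
exposure of the peptide. The phosphorylated proteoform is built by a
minimal explicit geometry: P placed 1.6 Å beyond the side-chain hydroxyl
oxygen along the C–O bond direction, with three terminal oxygens at
tetrahedral geometry (P–O 1.5 Å). No minimization is performed; this is
a reproducible methodological stand-in, not a refined model.

Secondary structure at a site is labelled from backbone φ/ψ windows
(helix, strand, coil) over the site and both neighbors, or "n/d" when
the backbone context is incomplete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError
from .io import Atom, StructureModel

#: van der Waals radii (Å) for the heavy elements of proteins + phosphate
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70

MOD_HYDROXYL = {"SEP": ("S", "OG", "CB"),
                "TPO": ("T", "OG1", "CB"),
                "PTR": ("Y", "OH", "CZ")}


@dataclass(frozen=True)
class PhosphoSite:
    accession: str
    position_1based: int
    residue: str           # S, T or Y
    mod: str               # SEP, TPO or PTR
    peptide_range: tuple[int, int]  # 1-based inclusive residue interval
    chain: str = "A"

    def __post_init__(self) -> None:
        expected = MOD_HYDROXYL.get(self.mod)
        if expected is None or expected[0] != self.residue:
            raise FormatError(
                f"inconsistent site: residue {self.residue!r} with mod "
                f"{self.mod!r}")


@dataclass
class SasaResult:
    per_atom_sasa: np.ndarray         # intact model, one value per atom
    peptide_sasa_intact: float        # Å²
    peptide_sasa_phospho: float       # Å²
    k_sasa: float                     # intact / phospho


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden section)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_shrake_rupley(model: StructureModel, probe: float = 1.4,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom SASA in Å², aligned with model.atoms.

    Hydrogens are ignored entirely (they get SASA 0 and do not occlude),
    consistent with X-ray and predicted models lacking them."""
    if not model.atoms:
        raise FormatError("structure has no atoms")
    heavy_idx = [k for k, a in enumerate(model.atoms) if a.element != "H"]
    if not heavy_idx:
        raise FormatError("structure has no heavy atoms")
    coords = model.coords()[heavy_idx]
    radii = np.array([VDW_RADII.get(model.atoms[k].element, DEFAULT_RADIUS)
                      for k in heavy_idx])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    out = np.zeros(len(model.atoms))
    for pos, (c, r) in enumerate(zip(coords, radii)):
        rp = r + probe
        neigh = [j for j in tree.query_ball_point(c, rp + max_r + probe)
                 if j != pos]
        pts = c + rp * sphere
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)] + probe
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 > (nr ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        out[heavy_idx[pos]] = frac * 4.0 * math.pi * rp * rp
    return out


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def attach_phosphate(model: StructureModel, site: PhosphoSite,
                     ) -> StructureModel:
    """Return a copy of the model with a phosphate built on the site's
    side-chain hydroxyl. No other atoms move."""
    res_atoms = model.residue_atoms(site.chain, site.position_1based)
    if not res_atoms:
        raise FormatError(
            f"no residue {site.position_1based} in chain {site.chain!r}")
    _, o_name, c_name = MOD_HYDROXYL[site.mod]
    by_name = {a.name: a for a in res_atoms}
    if "P" in by_name:
        raise FormatError(
            f"residue {site.position_1based} is already phosphorylated")
    if o_name not in by_name or c_name not in by_name:
        raise FormatError(
            f"residue {site.position_1based} lacks {o_name}/{c_name}; "
            f"cannot attach phosphate for {site.mod}")
    o = by_name[o_name]
    cb = by_name[c_name]
    opos = np.array([o.x, o.y, o.z])
    cpos = np.array([cb.x, cb.y, cb.z])
    u = opos - cpos
    u /= np.linalg.norm(u)
    ppos = opos + 1.6 * u
    # terminal oxygens: tetrahedral about P; the O-P bond runs along -u,
    # so terminal bond directions sit at arccos(1/3) from -u, i.e. their
    # component along +u is +1/3.
    e1, e2 = _orthonormal_frame(u)
    cos_t, sin_t = 1.0 / 3.0, math.sqrt(8.0) / 3.0
    new_atoms = [Atom("P", "P", *ppos, 1.0, o.b_factor,
                      o.residue_index, o.residue_name, o.chain)]
    for k, name in enumerate(("O1P", "O2P", "O3P")):
        theta = 2.0 * math.pi * k / 3.0
        d = cos_t * u + sin_t * (math.cos(theta) * e1 + math.sin(theta) * e2)
        pos = ppos + 1.5 * d
        new_atoms.append(Atom(name, "O", *pos, 1.0, o.b_factor,
                              o.residue_index, o.residue_name, o.chain))
    out = model.copy()
    out.atoms.extend(new_atoms)
    return out


def _peptide_atom_mask(model: StructureModel, chain: str,
                       peptide_range: tuple[int, int]) -> list[int]:
    lo, hi = peptide_range
    return [k for k, a in enumerate(model.atoms)
            if a.chain == chain and lo <= a.residue_index <= hi]


def k_sasa(model: StructureModel, site: PhosphoSite,
           peptide_range: Optional[tuple[int, int]] = None,
           probe: float = 1.4, n_points: int = 960) -> SasaResult:
    """Peptide SASA in the intact vs the phosphorylated protein.

    ``peptide_range`` is 1-based inclusive (defaults to the site's own
    peptide_range). Phosphate atoms inherit the site residue's index, so
    they are summed with the peptide whenever the site lies inside the
    range."""
    rng = peptide_range or site.peptide_range
    intact = sasa_shrake_rupley(model, probe, n_points)
    idx = _peptide_atom_mask(model, site.chain, rng)
    if not idx:
        raise FormatError(f"peptide range {rng} selects no atoms")
    sasa_intact = float(intact[idx].sum())
    phospho_model = attach_phosphate(model, site)
    phospho = sasa_shrake_rupley(phospho_model, probe, n_points)
    idx_p = _peptide_atom_mask(phospho_model, site.chain, rng)
    sasa_phospho = float(phospho[idx_p].sum())
    if sasa_phospho <= 0:
        raise FormatError("phosphorylated peptide SASA is zero")
    return SasaResult(
        per_atom_sasa=intact,
        peptide_sasa_intact=sasa_intact,
        peptide_sasa_phospho=sasa_phospho,
        k_sasa=sasa_intact / sasa_phospho,
    )


# ---------------------------------------------------------------------------
# secondary structure from backbone torsions
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -90.0)
STRAND_PSI = (90.0, 180.0)


def _backbone(model: StructureModel, chain: str, idx: int):
    atoms = {a.name: np.array([a.x, a.y, a.z])
             for a in model.residue_atoms(chain, idx)
             if a.name in ("N", "CA", "C")}
    if len(atoms) != 3:
        return None
    return atoms


def _phi_psi(model: StructureModel, chain: str, idx: int):
    prev = _backbone(model, chain, idx - 1)
    cur = _backbone(model, chain, idx)
    nxt = _backbone(model, chain, idx + 1)
    if prev is None or cur is None or nxt is None:
        return None
    phi = dihedral(prev["C"], cur["N"], cur["CA"], cur["C"])
    psi = dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
    return phi, psi


def _in_window(v: float, win: tuple[float, float]) -> bool:
    return win[0] < v < win[1]


def secondary_structure_at(model: StructureModel, chain: str,
                           position_1based: int) -> str:
    """3-way secondary-structure label at a residue from φ/ψ windows
    applied to the residue and both neighbors; "n/d" when backbone
    context (site ± 2 residues) is incomplete."""
    torsions = []
    for idx in (position_1based - 1, position_1based, position_1based + 1):
        t = _phi_psi(model, chain, idx)
        if t is None:
            return "n/d"
        torsions.append(t)
    if all(_in_window(phi, HELIX_PHI) and _in_window(psi, HELIX_PSI)
           for phi, psi in torsions):
        return "alpha-helix"
    if all(_in_window(phi, STRAND_PHI) and _in_window(psi, STRAND_PSI)
           for phi, psi in torsions):
        return "beta-strand"
    return "coil"


def mean_confidence(model: StructureModel, chain: str,
                    peptide_range: tuple[int, int]) -> tuple[float, float]:
    """Mean ± population sd of per-residue model confidence (B-factor
    column) over a 1-based inclusive residue range."""
    lo, hi = peptide_range
    values = []
    for ch, idx, _name in model.residues():
        if ch == chain and lo <= idx <= hi:
            bs = [a.b_factor for a in model.residue_atoms(ch, idx)]
            values.append(sum(bs) / len(bs))
    if not values:
        raise FormatError(f"peptide range {peptide_range} selects no residues")
    arr = np.array(values)
    return float(arr.mean()), float(arr.std())
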