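"""Shrake-Rupley SASA, phosphate construction, K_SASA, secondary structure."""

import itertools
import math

import numpy as np
import pytest

from dualprot.builder import build_peptide
from dualprot.errors import FormatError
from dualprot.io import Atom, StructureModel
from dualprot.sasa import (PhosphoSite, VDW_RADII, attach_phosphate,
                           dihedral, k_sasa, mean_confidence,
                           sasa_shrake_rupley, secondary_structure_at)


def atom(element, x, y, z, name=None, res=1, b=50.0):
    return Atom(name or element, element, x, y, z, 1.0, b, res, "ALA", "A")


def sphere_area(element, probe=1.4):
    r = VDW_RADII[element] + probe
    return 4.0 * math.pi * r * r


class TestShrakeRupley:
    def test_single_atom_closed_form(self):
        s = sasa_shrake_rupley(StructureModel([atom("C", 0, 0, 0)]))
        assert s[0] == pytest.approx(sphere_area("C"), rel=1e-3)

    def test_two_distant_atoms_fully_exposed(self):
        m = StructureModel([atom("C", 0, 0, 0), atom("C", 10, 0, 0)])
        s = sasa_shrake_rupley(m)
        assert s == pytest.approx([sphere_area("C")] * 2, rel=1e-3)

    def test_caged_atom_is_buried(self):
        # central atom inside a tight icosahedral shell
        phi = (1 + math.sqrt(5)) / 2
        verts = [(0, 1, phi), (0, 1, -phi), (0, -1, phi), (0, -1, -phi),
                 (1, phi, 0), (1, -phi, 0), (-1, phi, 0), (-1, -phi, 0),
                 (phi, 0, 1), (-phi, 0, 1), (phi, 0, -1), (-phi, 0, -1)]
        scale = 2.2 / math.sqrt(1 + phi * phi)
        atoms = [atom("C", 0, 0, 0)]
        atoms += [atom("C", x * scale, y * scale, z * scale)
                  for x, y, z in verts]
        s = sasa_shrake_rupley(StructureModel(atoms))
        assert s[0] < 0.01 * sphere_area("C")

    def test_rigid_motion_invariance(self):
        model = build_peptide("GASAG", phi=-120, psi=120)
        base = sasa_shrake_rupley(model)
        rng = np.random.default_rng(5)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        shift = rng.normal(scale=20.0, size=3)
        moved = StructureModel([
            Atom(a.name, a.element, *(R @ np.array([a.x, a.y, a.z]) + shift),
                 a.occupancy, a.b_factor, a.residue_index, a.residue_name,
                 a.chain)
            for a in model.atoms])
        s_moved = sasa_shrake_rupley(moved)
        # per-atom agreement limited by the finite point sample; totals tight
        assert s_moved == pytest.approx(base, abs=1.5)
        assert s_moved.sum() == pytest.approx(base.sum(), rel=5e-3)

    def test_removing_occluder_never_decreases_sasa(self):
        m = StructureModel([atom("C", 0, 0, 0), atom("C", 3.0, 0, 0),
                            atom("C", 0, 3.2, 0)])
        full = sasa_shrake_rupley(m)
        reduced = sasa_shrake_rupley(StructureModel(m.atoms[:2]))
        assert reduced[0] >= full[0] - 1e-9
        assert reduced[1] >= full[1] - 1e-9

    def test_empty_model_rejected(self):
        with pytest.raises(FormatError):
            sasa_shrake_rupley(StructureModel([]))

    def test_matches_independent_biotite_oracle(self):
        import biotite.structure as struc
        model = build_peptide("GAASTAAG", phi=-57, psi=-47)
        n = len(model.atoms)
        arr = struc.AtomArray(n)
        arr.coord = model.coords()
        arr.element = np.array([a.element for a in model.atoms])
        arr.atom_name = np.array([a.name for a in model.atoms])
        arr.res_id = np.array([a.residue_index for a in model.atoms])
        arr.res_name = np.array([a.residue_name for a in model.atoms])
        arr.chain_id = np.array([a.chain for a in model.atoms])
        arr.hetero = np.zeros(n, bool)
        radii = np.array([VDW_RADII[a.element] for a in model.atoms])
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                         point_number=5000)
        mine = sasa_shrake_rupley(model)
        assert mine.sum() == pytest.approx(ref.sum(), rel=0.02)


class TestAttachPhosphate:
    def site(self, pos=4, mod="SEP", residue="S", rng=(1, 7)):
        return PhosphoSite("X", pos, residue, mod, rng)

    def test_adds_four_atoms_others_untouched(self):
        model = build_peptide("GAASAAG", phi=-120, psi=120)
        out = attach_phosphate(model, self.site())
        assert len(out.atoms) == len(model.atoms) + 4
        for a, b in zip(model.atoms, out.atoms):
            assert (a.x, a.y, a.z) == (b.x, b.y, b.z)
        assert [a.name for a in out.atoms[-4:]] == ["P", "O1P", "O2P", "O3P"]

    def test_tetrahedral_geometry(self):
        model = build_peptide("GAASAAG", phi=-120, psi=120)
        out = attach_phosphate(model, self.site())
        p, *oxy = out.atoms[-4:]
        pv = np.array([p.x, p.y, p.z])
        ov = [np.array([o.x, o.y, o.z]) for o in oxy]
        for o in ov:
            assert np.linalg.norm(o - pv) == pytest.approx(1.5, abs=1e-6)
        for a, b in itertools.combinations(ov, 2):
            assert np.linalg.norm(a - b) == pytest.approx(
                2 * 1.5 * math.sin(math.radians(109.47 / 2)), abs=1e-3)

    def test_double_phosphorylation_rejected(self):
        model = build_peptide("GAASAAG", phi=-120, psi=120)
        once = attach_phosphate(model, self.site())
        with pytest.raises(FormatError, match="already"):
            attach_phosphate(once, self.site())

    def test_missing_hydroxyl_rejected(self):
        model = build_peptide("GAAAAAG", phi=-120, psi=120)  # no Ser
        with pytest.raises(FormatError, match="lacks"):
            attach_phosphate(model, self.site())

    def test_threonine_site(self):
        model = build_peptide("GAATAAG", phi=-120, psi=120)
        out = attach_phosphate(model, PhosphoSite("X", 4, "T", "TPO", (1, 7)))
        assert len(out.atoms) == len(model.atoms) + 4

    def test_inconsistent_residue_mod_pairing(self):
        with pytest.raises(FormatError):
            PhosphoSite("X", 4, "T", "SEP", (1, 7))


class TestKsasa:
    def test_exposed_site_increases_sasa(self):
        model = build_peptide("GAASAAG", phi=-120, psi=120)
        res = k_sasa(model, PhosphoSite("X", 4, "S", "SEP", (1, 7)))
        assert res.k_sasa < 1.0
        assert res.peptide_sasa_phospho > res.peptide_sasa_intact

    def test_range_excluding_site_unchanged(self):
        model = build_peptide("GASAAAAAAG", phi=-120, psi=120)
        res = k_sasa(model, PhosphoSite("X", 3, "S", "SEP", (8, 10)),
                     peptide_range=(8, 10))
        assert res.k_sasa == pytest.approx(1.0, abs=0.02)

    def test_matches_fine_grid_oracle_on_helix(self):
        # coarse sampling (960 points) vs a 10x denser point set
        model = build_peptide("GAASAAG", phi=-57, psi=-47)
        site = PhosphoSite("X", 4, "S", "SEP", (1, 7))
        coarse = k_sasa(model, site, n_points=960)
        fine = k_sasa(model, site, n_points=9600)
        assert coarse.k_sasa == pytest.approx(fine.k_sasa, rel=0.02)
        assert coarse.peptide_sasa_intact == pytest.approx(
            fine.peptide_sasa_intact, rel=0.02)


class TestSecondaryStructure:
    def test_ideal_helix(self):
        model = build_peptide("AAASAAA", phi=-57, psi=-47)
        assert secondary_structure_at(model, "A", 4) == "alpha-helix"

    def test_ideal_strand(self):
        model = build_peptide("AAASAAA", phi=-139, psi=135)
        assert secondary_structure_at(model, "A", 4) == "beta-strand"

    def test_short_fragment_nd(self):
        model = build_peptide("AS", phi=-57, psi=-47)
        assert secondary_structure_at(model, "A", 1) == "n/d"

    def test_generic_extended_is_coil(self):
        model = build_peptide("AAASAAA", phi=-75, psi=150)
        assert secondary_structure_at(model, "A", 4) == "coil"

    def test_dihedral_sign_convention(self):
        # textbook trans (180) and cis (0) configurations
        p = [np.array([0, 1, 0]), np.array([0, 0, 0]),
             np.array([1, 0, 0]), np.array([1, -1, 0])]
        assert abs(dihedral(*p)) == pytest.approx(180.0)
        p[3] = np.array([1, 1, 0])
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)


class TestMeanConfidence:
    def test_uniform(self):
        model = build_peptide("AAAA", phi=-57, psi=-47, b_factor=90.0)
        assert mean_confidence(model, "A", (1, 4)) == (90.0, 0.0)

    def test_population_sd(self):
        atoms = [atom("C", float(i), 0, 0, name="CA", res=i + 1, b=b)
                 for i, b in enumerate((80.0, 100.0))]
        mean, sd = mean_confidence(StructureModel(atoms), "A", (1, 2))
        assert (mean, sd) == (90.0, 10.0)

    def test_empty_range_rejected(self):
        model = build_peptide("AAAA", phi=-57, psi=-47)
        with pytest.raises(FormatError):
            mean_confidence(model, "A", (10, 20))
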