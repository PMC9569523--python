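import numpy as np
import pytest
from hypothesis import given, strategies as st

import phosbench as pb
from phosbench.geometry import dihedral
from phosbench.structure_io import AtomRecord, Conformation, Ensemble, Residue, ResidueKey
from phosbench.synthetic_data import STATE_ANGLES, build_backbone

from conftest import random_rotation


def _point_cloud_conf(coords, names=None):
    residues = []
    for i, c in enumerate(np.asarray(coords, dtype=float)):
        name = (names or ["CA"] * len(coords))[i]
        residues.append(
            Residue(ResidueKey("A", i + 1), "GLY", [AtomRecord(i + 1, name, name[0], c)])
        )
    return Conformation(residues)


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        sup = pb.kabsch_superpose(x, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self, rng):
        x = rng.normal(size=(12, 3))
        theta = np.pi / 2
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        mobile = x @ R.T + np.array([5.0, 0.0, 0.0])
        sup = pb.kabsch_superpose(mobile, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_grid_search_oracle_on_displaced_square(self):
        # square with one corner moved 1 A; oracle = brute-force rotation search
        ref = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        mob = ref.copy()
        mob[2, 0] += 1.0

        def rotmat(a, b, c):
            ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
            rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
            return rz @ ry @ rx

        refc = ref - ref.mean(axis=0)
        mobc = mob - mob.mean(axis=0)
        best = np.inf
        grid = np.linspace(-0.4, 0.4, 33)  # optimum is near identity
        for a in grid:
            for b in grid:
                for c in grid:
                    d = mobc @ rotmat(a, b, c).T - refc
                    best = min(best, np.sqrt(np.mean(np.sum(d**2, axis=1))))
        sup = pb.kabsch_superpose(mob, ref)
        assert sup.rmsd == pytest.approx(best, abs=2e-3)
        assert sup.rmsd <= best + 1e-12  # analytic optimum cannot be worse

    def test_degenerate_collinear_reference_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            pb.kabsch_superpose(line + 0.1, line)

    @given(seed=st.integers(0, 1000))
    def test_rmsd_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(8, 3))
        mob = rng.normal(size=(8, 3))
        base = pb.kabsch_superpose(mob, ref).rmsd
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        moved = mob @ R.T + t
        assert pb.kabsch_superpose(moved, ref).rmsd == pytest.approx(base, abs=1e-8)


class TestRg:
    def test_single_atom_zero(self):
        conf = _point_cloud_conf([[1.0, 2.0, 3.0]])
        assert pb.rg(conf) == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_mass_atoms(self):
        conf = _point_cloud_conf([[0, 0, 0], [2, 0, 0]])
        assert pb.rg(conf, mass_weighted=False) == pytest.approx(1.0)

    def test_direct_sum_oracle(self, rng):
        coords = rng.normal(size=(10, 3)) * 5
        conf = _point_cloud_conf(coords)
        com = coords.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1)))
        assert pb.rg(conf, mass_weighted=False) == pytest.approx(expected, rel=1e-12)

    def test_rigid_invariance_and_scaling(self, rng):
        coords = rng.normal(size=(15, 3))
        base = pb.rg(_point_cloud_conf(coords), mass_weighted=False)
        R = random_rotation(rng)
        moved = coords @ R.T + np.array([3.0, -2.0, 7.0])
        assert pb.rg(_point_cloud_conf(moved), mass_weighted=False) == pytest.approx(base)
        assert pb.rg(_point_cloud_conf(coords * 2.5), mass_weighted=False) == pytest.approx(
            2.5 * base
        )

    def test_empty_selection_rejected(self, helix12):
        with pytest.raises(ValueError, match="empty"):
            pb.rg(helix12, selection=lambda r, a: False)


class TestEndToEnd:
    def test_two_ca_distance(self):
        conf = _point_cloud_conf([[0, 0, 0], [3.8, 0, 0]])
        assert pb.end_to_end(conf) == pytest.approx(3.8)

    def test_extended_chain_matches_vector_sum(self):
        conf = build_backbone("A" * 5, [STATE_ANGLES["E"]] * 5)
        cas = np.array([r.atom("CA").coord for r in conf.residues])
        expected = np.linalg.norm(np.sum(np.diff(cas, axis=0), axis=0))
        assert pb.end_to_end(conf) == pytest.approx(expected)

    def test_coincident_termini_zero(self):
        conf = _point_cloud_conf([[0, 0, 0], [5, 0, 0], [0, 0, 0]])
        assert pb.end_to_end(conf) == 0.0

    def test_missing_terminal_ca_rejected(self):
        conf = _point_cloud_conf([[0, 0, 0], [1, 0, 0], [2, 0, 0]], names=["CA", "CA", "CB"])
        with pytest.raises(ValueError, match="CA"):
            pb.end_to_end(conf)


class TestRmsf:
    def test_identical_frames_zero(self, helix12):
        ens = Ensemble([helix12, helix12, helix12])
        assert np.allclose(pb.rmsf(ens), 0.0, atol=1e-10)

    def test_single_frame_rejected(self, helix12):
        with pytest.raises(ValueError):
            pb.rmsf(Ensemble([helix12]))

    def test_gaussian_jitter_recovers_sigma_sqrt3(self, helix12, rng):
        # sigma per coordinate -> E|r - <r>| contribution sigma*sqrt(3) per atom
        sigma = 0.3
        frames = []
        for _ in range(500):
            residues = []
            for r in helix12.residues:
                atoms = [
                    AtomRecord(a.serial, a.name, a.element, a.coord + rng.normal(0, sigma, 3))
                    for a in r.atoms
                ]
                residues.append(Residue(r.key, r.name, atoms))
            frames.append(Conformation(residues))
        values = pb.rmsf(Ensemble(frames))
        assert np.abs(values.mean() - sigma * np.sqrt(3)) < 0.1 * sigma * np.sqrt(3)


class TestDihedrals:
    def test_round_trip_through_builder(self):
        for state in ("H", "E", "P"):
            conf = build_backbone("A" * 12, [STATE_ANGLES[state]] * 12)
            d = pb.backbone_dihedrals(conf)[0]
            phi, psi = STATE_ANGLES[state]
            np.testing.assert_allclose(d[1:-1, 0], phi, atol=0.5)
            np.testing.assert_allclose(d[1:-1, 1], psi, atol=0.5)
            assert np.isnan(d[0, 0]) and np.isnan(d[-1, 1])

    def test_collinear_atoms_undefined(self):
        p = [np.array([float(i), 0, 0]) for i in range(4)]
        assert np.isnan(dihedral(*p))

    def test_planar_zigzag_is_0_or_180(self, rng):
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        ang = dihedral(*pts)
        assert min(abs(ang), abs(abs(ang) - 180.0)) < 1e-9

    @given(seed=st.integers(0, 500))
    def test_reversal_symmetry_and_mirror_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        ang = dihedral(*pts)
        if np.isnan(ang):
            return
        assert dihedral(*pts[::-1]) == pytest.approx(ang, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-ang, abs=1e-9) or (
            abs(abs(ang) - 180.0) < 1e-9
        )
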