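import numpy as np
import pytest

import phosbench as pb
from phosbench.secstruct import (
    COARSE_MAP_CONVENTIONAL,
    COARSE_MAP_DEFAULT,
    ENERGY_CLAMP,
    assign_dssp,
)
from phosbench.structure_io import AtomRecord, Conformation, Ensemble, Residue, ResidueKey
from phosbench.synthetic_data import (
    GeneratorSpec,
    STATE_ANGLES,
    build_backbone,
    make_ensemble,
    make_strand_pair,
)

from conftest import random_rotation


def _bare_residue(key, name, atom_coords):
    atoms = [
        AtomRecord(i + 1, nm, nm[0], np.asarray(c, dtype=float))
        for i, (nm, c) in enumerate(atom_coords.items())
    ]
    return Residue(key, name, atoms)


class TestPlaceAmideHydrogens:
    def test_existing_hydrogen_unchanged(self, helix12):
        before = {r.key: r.atom("H").coord.copy() for r in helix12.residues if r.atom("H")}
        out = pb.place_amide_hydrogens(helix12)
        for r in out.residues:
            if r.key in before:
                np.testing.assert_array_equal(r.atom("H").coord, before[r.key])

    def test_proline_gets_no_hydrogen(self):
        conf = build_backbone("APA", [STATE_ANGLES["P"]] * 3, add_hydrogens=False)
        out = pb.place_amide_hydrogens(conf)
        assert out.residues[1].name == "PRO"
        assert out.residues[1].atom("H") is None
        assert out.residues[2].atom("H") is not None

    def test_hand_computed_position(self):
        # dipeptide with simple coordinates: H = N + (C_prev - O_prev)/|...|
        r1 = _bare_residue(
            ResidueKey("A", 1), "GLY",
            {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.0, 1.4, 0), "O": (1.4, 2.4, 0)},
        )
        r2 = _bare_residue(
            ResidueKey("A", 2), "GLY",
            {"N": (3.3, 1.5, 0), "CA": (4.2, 2.6, 0), "C": (5.6, 2.2, 0), "O": (6.5, 3.0, 0)},
        )
        out = pb.place_amide_hydrogens(Conformation([r1, r2]))
        v = np.array([2.0, 1.4, 0.0]) - np.array([1.4, 2.4, 0.0])
        expected = np.array([3.3, 1.5, 0.0]) + v / np.linalg.norm(v)
        np.testing.assert_allclose(out.residues[1].atom("H").coord, expected, atol=1e-12)


class TestHbondEnergy:
    def test_direct_formula_evaluation(self):
        # geometry engineered to hit r_ON=2.9, r_CH=3.5, r_OH=1.9, r_CN=3.9
        donor = _bare_residue(
            ResidueKey("A", 5), "ALA", {"N": (0.0, 0, 0), "H": (1.0, 0, 0)}
        )
        acceptor = _bare_residue(
            ResidueKey("A", 1), "ALA",
            {"C": (3.9, 0, 0), "O": (2.9, 0, 0)},
        )
        e = pb.hbond_energy(donor, acceptor)
        expected = 0.084 * 332 * (1 / 2.9 + 1 / 2.9 - 1 / 1.9 - 1 / 3.9)
        assert e == pytest.approx(expected, abs=1e-12)
        assert e < -0.5  # this is a bond

    def test_helix_geometry_distances_give_strong_bond(self):
        # direct evaluation at r_ON=2.9, r_CH=3.5, r_OH=1.9, r_CN=3.9
        expected = 0.084 * 332 * (1 / 2.9 + 1 / 3.5 - 1 / 1.9 - 1 / 3.9)
        assert expected == pytest.approx(-4.2443, abs=1e-3)
        assert expected < -0.5

    def test_distant_pair_below_threshold(self):
        donor = _bare_residue(ResidueKey("A", 1), "ALA", {"N": (0, 0, 0), "H": (1, 0, 0)})
        acceptor = _bare_residue(ResidueKey("A", 9), "ALA", {"C": (20, 0, 0), "O": (21, 0, 0)})
        assert abs(pb.hbond_energy(donor, acceptor)) < 0.5

    def test_close_contact_clamped(self):
        donor = _bare_residue(ResidueKey("A", 1), "ALA", {"N": (0, 0, 0), "H": (0.1, 0, 0)})
        acceptor = _bare_residue(ResidueKey("A", 9), "ALA", {"C": (0.2, 0, 0), "O": (0.3, 0, 0)})
        assert pb.hbond_energy(donor, acceptor) == ENERGY_CLAMP

    def test_not_symmetric_in_roles(self):
        donor = _bare_residue(
            ResidueKey("A", 1), "ALA", {"N": (0, 0, 0), "H": (1, 0, 0), "C": (0, 2, 0), "O": (1, 2, 0)}
        )
        acceptor = _bare_residue(
            ResidueKey("A", 9), "ALA", {"N": (4, 1, 0), "H": (3, 1, 0), "C": (3, 0, 0), "O": (2.2, 0.6, 0)}
        )
        assert pb.hbond_energy(donor, acceptor) != pytest.approx(
            pb.hbond_energy(acceptor, donor)
        )


class TestAssignDssp:
    def test_ideal_helix_core_is_H(self, helix12):
        letters = assign_dssp(helix12).letters
        assert set(letters[2:10]) == {"H"}
        assert assign_dssp(helix12).coarse[5] == "helix"

    def test_single_strand_has_no_E(self, strand12):
        letters = assign_dssp(strand12).letters
        assert "E" not in letters and "B" not in letters
        assert set(letters) <= {" ", "S", "T"}

    @pytest.mark.parametrize("antiparallel", [True, False])
    def test_paired_strands_form_ladder(self, antiparallel):
        conf = make_strand_pair(8, antiparallel=antiparallel)
        letters = assign_dssp(conf).letters
        assert letters.count("E") >= 6
        assert assign_dssp(conf).coarse[letters.index("E")] == "sheet"

    def test_short_chain_all_blank(self):
        conf = build_backbone("AA", [STATE_ANGLES["H"]] * 2)
        assert assign_dssp(conf).letters == "  "

    def test_rigid_motion_invariance(self, helix12, rng):
        base = assign_dssp(helix12).letters
        R = random_rotation(rng)
        t = rng.normal(size=3) * 20
        moved = Conformation(
            [
                Residue(
                    r.key, r.name,
                    [AtomRecord(a.serial, a.name, a.element, a.coord @ R.T + t) for a in r.atoms],
                )
                for r in helix12.residues
            ]
        )
        assert assign_dssp(moved).letters == base

    def test_coarse_mapping_is_exactly_the_documented_one(self, helix12):
        ass = assign_dssp(helix12)
        for letter, coarse in zip(ass.letters, ass.coarse):
            assert coarse == COARSE_MAP_DEFAULT[letter]
        conv = assign_dssp(helix12, coarse_mapping="conventional")
        for letter, coarse in zip(conv.letters, conv.coarse):
            assert coarse == COARSE_MAP_CONVENTIONAL[letter]


class TestSsFractions:
    def test_static_helix_ensemble(self, helix12):
        ens = Ensemble([helix12] * 3)
        fr = pb.ss_fractions(ens)
        # core residues all helix in every frame
        assert (fr.iloc[3:9]["helix"] == 1.0).all()
        np.testing.assert_allclose(fr.sum(axis=1), 1.0)

    def test_single_frame_fractions_are_zero_or_one(self, helix12):
        fr = pb.ss_fractions(Ensemble([helix12]))
        assert set(np.unique(fr.to_numpy())) <= {0.0, 1.0}

    def test_frame_level_mixture_recovers_weights(self):
        spec = GeneratorSpec(
            sequence="A" * 12,
            ss_target=[(0.5, "H" * 12), (0.5, "C" * 12)],
            n_frames=200,
            seed=11,
        )
        ens, truth = make_ensemble(spec)
        fr = pb.ss_fractions(ens)
        core = fr.iloc[4:8]["helix"].mean()
        planted = np.mean(truth["state_fractions"]["H"][4:8])
        # binomial 3-sigma band around the planted frame fraction
        assert abs(core - planted) < 3 * np.sqrt(0.25 / 200) + 0.05
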