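import numpy as np
import pytest

import phosbench as pb
from phosbench.ensemble_analysis import DEFAULT_REGIONS, KB_KCAL, RamaDensity
from phosbench.structure_io import Ensemble, ResidueKey
from phosbench.synthetic_data import GeneratorSpec, STATE_ANGLES, build_backbone, make_ensemble


class TestFreeEnergyLandscape:
    def test_delta_distribution_single_zero_bin(self):
        ls = pb.free_energy_landscape(np.ones(40), np.ones(40) * 2, bins=5)
        occupied = ~np.isnan(ls.free_energy)
        assert occupied.sum() == 1
        assert ls.free_energy[occupied][0] == 0.0
        assert ls.counts.sum() == 40

    def test_two_to_one_occupancy_gives_kT_ln2(self):
        x = np.array([0.25] * 100 + [0.75] * 50)
        ls = pb.free_energy_landscape(x, x, bins=2, temperature=298.15)
        vals = ls.free_energy[~np.isnan(ls.free_energy)]
        delta = vals.max() - vals.min()
        assert delta == pytest.approx(KB_KCAL * 298.15 * np.log(2), abs=1e-6)

    def test_uniform_occupancy_flat_at_zero(self):
        x = np.repeat([0.1, 0.3, 0.5, 0.7], 25)
        ls = pb.free_energy_landscape(x, x, bins=(4, 4))
        diag = np.diagonal(ls.free_energy)
        assert np.allclose(diag, 0.0)

    def test_free_energy_differences_independent_of_frame_count(self):
        a = pb.free_energy_landscape(
            np.array([0.0] * 20 + [1.0] * 10), np.zeros(30), bins=2,
            x_range=(-0.5, 1.5), y_range=(-1, 1),
        )
        b = pb.free_energy_landscape(
            np.array([0.0] * 200 + [1.0] * 100), np.zeros(300), bins=2,
            x_range=(-0.5, 1.5), y_range=(-1, 1),
        )
        da = np.nanmax(a.free_energy) - np.nanmin(a.free_energy)
        db = np.nanmax(b.free_energy) - np.nanmin(b.free_energy)
        assert da == pytest.approx(db)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            pb.free_energy_landscape(np.array([]), np.array([]))

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            pb.free_energy_landscape(np.ones(3), np.ones(3), temperature=-1.0)


class TestRamachandranDensity:
    def test_helix_point_mass_lands_in_helix_region(self):
        d = np.full((50, 1, 2), [-57.0, -47.0])
        density = pb.ramachandran_density(d)
        occ = density.region_occupancy()
        assert occ["helix"] == pytest.approx(1.0)
        assert density.density.sum() == pytest.approx(1.0)

    def test_seventy_thirty_ppii_helix_mixture(self):
        rng = np.random.default_rng(42)
        n = 2000
        states = rng.random(n) < 0.7
        pairs = np.where(
            states[:, None],
            np.array(STATE_ANGLES["P"]) + rng.normal(0, 5, (n, 2)),
            np.array(STATE_ANGLES["H"]) + rng.normal(0, 5, (n, 2)),
        )
        density = pb.ramachandran_density(pairs[:, None, :])
        occ = density.region_occupancy()
        assert occ["ppii"] == pytest.approx(states.mean(), abs=0.03)
        assert occ["helix"] == pytest.approx(1 - states.mean(), abs=0.03)

    def test_density_normalised_for_any_input(self, rng):
        pairs = rng.uniform(-180, 180, size=(500, 3, 2))
        density = pb.ramachandran_density(pairs)
        assert density.density.sum() == pytest.approx(1.0)

    def test_region_masks_plus_remainder_sum_to_one(self, rng):
        pairs = rng.uniform(-180, 180, size=(300, 2, 2))
        occ = pb.ramachandran_density(pairs).region_occupancy()
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pb.ramachandran_density(np.zeros((5, 3, 2)), residue_indices=[])

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="no defined"):
            pb.ramachandran_density(np.full((5, 3, 2), np.nan))


class TestDensityDivergence:
    def _delta(self, phi, psi):
        d = np.full((20, 1, 2), [float(phi), float(psi)])
        return pb.ramachandran_density(d)

    def test_identical_densities_give_zero(self):
        p = self._delta(-57, -47)
        assert pb.density_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_densities_give_ln2(self):
        p = self._delta(-57, -47)
        q = self._delta(100, 100)
        assert pb.density_divergence(p, q) == pytest.approx(np.log(2), abs=1e-12)

    def test_two_bin_hand_value(self):
        a = np.zeros((36, 36))
        b = np.zeros((36, 36))
        a[0, 0], a[5, 5] = 0.5, 0.5
        b[0, 0], b[5, 5] = 0.9, 0.1
        p = RamaDensity(bin_width=10.0, density=a)
        q = RamaDensity(bin_width=10.0, density=b)
        m1, m2 = 0.7, 0.3
        expected = 0.5 * (
            0.5 * np.log(0.5 / m1) + 0.5 * np.log(0.5 / m2)
            + 0.9 * np.log(0.9 / m1) + 0.1 * np.log(0.1 / m2)
        )
        assert pb.density_divergence(p, q) == pytest.approx(expected, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        p = RamaDensity(bin_width=10.0, density=np.full((36, 36), 1 / 36**2))
        q = RamaDensity(bin_width=5.0, density=np.full((72, 72), 1 / 72**2))
        with pytest.raises(ValueError, match="grids"):
            pb.density_divergence(p, q)


class TestHbondCounts:
    def test_helix_core_has_backbone_bonds(self, helix12):
        counts = pb.hbond_counts(Ensemble([helix12]))
        # i -> i-4 backbone bonds populate the helix interior
        assert counts.sum() > 0
        core = [str(ResidueKey("A", i)) for i in range(3, 10)]
        assert all(counts[k] >= 1 for k in core)

    def test_bond_in_one_of_two_frames_gives_half(self, helix12):
        # second frame: same helix pulled apart so no bonds remain
        stretched = build_backbone("A" * 12, [STATE_ANGLES["E"]] * 12)
        ens = Ensemble([helix12, stretched])
        one = pb.hbond_counts(Ensemble([helix12]))
        two = pb.hbond_counts(ens)
        participating = one[one > 0].index
        for k in participating:
            assert two[k] == pytest.approx(one[k] / 2)

    def test_everything_far_apart_gives_zero(self, strand12):
        counts = pb.hbond_counts(Ensemble([strand12]))
        assert (counts == 0).all()

    def test_frame_permutation_invariance(self):
        spec = GeneratorSpec(sequence="A" * 10, ss_target="H" * 10, n_frames=4, seed=2)
        ens, _ = make_ensemble(spec)
        fwd = pb.hbond_counts(ens)
        rev = pb.hbond_counts(Ensemble(ens.frames[::-1]))
        assert (fwd == rev).all()

    def test_subset_restricts_report(self, helix12):
        subset = [ResidueKey("A", 6)]
        counts = pb.hbond_counts(Ensemble([helix12]), subset=subset)
        assert list(counts.index) == ["A:6"]

    def test_phosphate_oxygens_are_acceptors(self):
        conf = build_backbone("GsG", [STATE_ANGLES["P"]] * 3)
        names = [a.name for a in conf.residues[1].atoms]
        assert {"O1P", "O2P", "O3P"} <= set(names)
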