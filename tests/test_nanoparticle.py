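"""Nanoparticle classes: builders, internal energetics, rigid-body moves."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from avidmc import nanoparticle as npm
from avidmc.constants import stiffness_kbt


class TestBuilders:
    def test_full_scale_coreshell_counts(self):
        nano = npm.build_coreshell_np(f=25, n_beads_per_arm=4, seed=0)
        assert nano.n_beads == 25 * 4
        assert nano.n_ligands == 162
        assert np.unique(nano.arm_of_bead).size == 25

    def test_zero_crosslink_fraction_gives_lst_topology(self):
        nano = npm.build_coreshell_np(crosslink_fraction=0.0, seed=0)
        assert nano.class_tag == "LSt"
        assert nano.crosslinks.shape[0] == 0

    def test_dense_crosslinks_give_hst_topology(self):
        nano = npm.build_coreshell_np(crosslink_fraction=1.0, seed=0)
        assert nano.class_tag == "HSt"
        assert nano.crosslinks.shape[0] > nano.n_beads

    @pytest.mark.parametrize("frac", [0.0, 0.4, 1.0])
    def test_identical_seeds_identical_particles(self, frac):
        a = npm.build_coreshell_np(crosslink_fraction=frac, seed=11)
        b = npm.build_coreshell_np(crosslink_fraction=frac, seed=11)
        assert np.array_equal(a.beads, b.beads)
        assert np.array_equal(a.tips, b.tips)
        assert np.array_equal(a.crosslinks, b.crosslinks)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            npm.build_coreshell_np(f=0)
        with pytest.raises(ValueError):
            npm.build_coreshell_np(crosslink_fraction=1.5)

    def test_rigid_and_semirigid_geometry(self):
        rg = npm.build_rigid_np(seed=2)
        srg = npm.build_semirigid_np(seed=2)
        assert rg.n_ligands == srg.n_ligands == 162
        # ligands sit one ligand length beyond the 50 nm core surface
        for nano in (rg, srg):
            r = np.linalg.norm(nano.tips - nano.core_center, axis=1)
            assert np.allclose(r, 65.0, atol=1e-9)
        assert np.allclose(
            np.linalg.norm(srg.anchors - srg.core_center, axis=1), 50.0)


class TestInternalEnergy:
    def test_rigid_particle_has_no_internal_energy(self, rng):
        nano = npm.build_rigid_np(seed=0)
        moved = npm.np_rigid_body_move(nano, rng.normal(size=3),
                                       Rotation.random(rng=rng))
        assert npm.np_internal_energy(nano) == 0.0
        assert npm.np_internal_energy(moved) == 0.0

    @pytest.mark.parametrize("builder", [
        npm.build_semirigid_np,
        lambda seed: npm.build_coreshell_np(crosslink_fraction=0.0, seed=seed),
        lambda seed: npm.build_coreshell_np(crosslink_fraction=1.0, seed=seed),
    ])
    def test_rest_geometry_is_energy_minimum(self, builder):
        nano = builder(seed=4)
        assert npm.np_internal_energy(nano) == pytest.approx(0.0, abs=1e-9)

    def test_single_spring_stretch_energy(self):
        """Stretching one arm spring by x stores (1/2) k_s x^2."""
        nano = npm.build_coreshell_np(f=2, n_beads_per_arm=2, seed=0,
                                      n_ligands=2, core_radius=30.0)
        x = 1.7
        i, j = nano.springs[0]
        direction = nano.beads[j] - nano.beads[i]
        direction /= np.linalg.norm(direction)
        beads = nano.beads.copy()
        beads[j] += x * direction
        # move the tethered tips with their parent so only one term changes
        tips = nano.tips.copy()
        tips[nano.tip_parent == j] += x * direction
        e = npm.np_internal_energy_positions(nano, beads=beads, tips=tips)
        expected = 0.5 * stiffness_kbt(1.74e-4) * x ** 2
        assert e == pytest.approx(expected, rel=1e-9)

    def test_invariance_under_rigid_motion(self, rng):
        nano = npm.build_coreshell_np(crosslink_fraction=0.5, seed=3)
        nano.beads += 0.8 * rng.standard_normal(nano.beads.shape)
        e0 = npm.np_internal_energy(nano)
        assert e0 > 0
        moved = npm.np_rigid_body_move(
            nano, [4.0, -2.0, 7.0], Rotation.from_rotvec([0.4, -0.1, 0.9]))
        assert npm.np_internal_energy(moved) == pytest.approx(e0, rel=1e-9)


class TestRigidBodyMove:
    def test_identity_transform(self):
        nano = npm.build_coreshell_np(seed=0)
        out = npm.np_rigid_body_move(nano, np.zeros(3))
        assert np.array_equal(out.beads, nano.beads)
        assert np.array_equal(out.tips, nano.tips)

    def test_translation_shifts_every_block(self):
        nano = npm.build_semirigid_np(seed=0)
        t = np.array([1.0, 0.0, 0.0])
        out = npm.np_rigid_body_move(nano, t)
        assert np.allclose(out.tips, nano.tips + t)
        assert np.allclose(out.anchors, nano.anchors + t)
        assert np.allclose(out.core_center, nano.core_center + t)

    def test_rotation_preserves_pairwise_distances(self, rng):
        nano = npm.build_coreshell_np(seed=1)
        rot = Rotation.random(rng=np.random.default_rng(5))
        out = npm.np_rigid_body_move(nano, np.zeros(3), rot)
        d0 = np.linalg.norm(nano.beads[:, None] - nano.tips[None, :], axis=2)
        d1 = np.linalg.norm(out.beads[:, None] - out.tips[None, :], axis=2)
        assert np.allclose(d0, d1, atol=1e-12 * d0.max())


class TestElasticCalibration:
    def test_crosslinking_stiffens_the_particle(self):
        lst = npm.build_coreshell_np(crosslink_fraction=0.0, seed=2)
        hst = npm.build_coreshell_np(crosslink_fraction=1.0, seed=2)
        e_lst = npm.estimate_elastic_modulus(lst)
        e_hst = npm.estimate_elastic_modulus(hst)
        assert 0 < e_lst < e_hst
        assert np.isinf(npm.estimate_elastic_modulus(npm.build_rigid_np()))
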