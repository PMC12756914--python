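"""Membrane discretization: Helfrich energetics, moves, topology, sampling."""

import numpy as np
import pytest
import trimesh

from avidmc import membrane as mb
from avidmc.system_builder import build_membrane_fixture

KAPPA = 20.0


def flat_patch(L=100.0, n=10, **kw):
    kw.setdefault("kappa", KAPPA)
    kw.setdefault("sigma", 0.0)
    return mb.triangular_lattice_patch(L, n, n, **kw)


class TestHelfrichEnergy:
    def test_flat_patch_has_zero_energy(self):
        m = flat_patch()
        assert mb.bending_energy(m) == pytest.approx(0.0, abs=1e-9)
        assert mb.helfrich_energy(m) == pytest.approx(0.0, abs=1e-9)
        assert mb.excess_area(m) == pytest.approx(0.0, abs=1e-12)

    def test_tension_term_vanishes_when_area_equals_projected(self):
        m = flat_patch(sigma=0.5)
        assert mb.area_energy(m, mb.total_area(m)) == pytest.approx(0.0)

    @pytest.mark.parametrize("subdivisions,tol", [(2, 0.03), (3, 0.01), (4, 0.003)])
    def test_sphere_energy_approaches_closed_form(self, subdivisions, tol):
        """Discrete bending energy of a sphere converges to 8 pi kappa."""
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=30.0)
        m = mb.MembraneMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                            box=None, kappa=KAPPA, sigma=0.0)
        target = 8.0 * np.pi * KAPPA
        assert mb.bending_energy(m) == pytest.approx(target, rel=tol)

    def test_sphere_error_decreases_monotonically(self):
        errs = []
        for sub in (2, 3, 4):
            ico = trimesh.creation.icosphere(subdivisions=sub, radius=30.0)
            m = mb.MembraneMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                                box=None, kappa=KAPPA)
            errs.append(abs(mb.bending_energy(m) - 8 * np.pi * KAPPA))
        assert errs[0] > errs[1] > errs[2]

    def test_invariance_under_inplane_translation(self, rough_mesh):
        e0 = mb.helfrich_energy(rough_mesh)
        shifted = rough_mesh.vertices.copy()
        shifted[:, 0] = np.mod(shifted[:, 0] + 37.3, rough_mesh.box)
        shifted[:, 1] = np.mod(shifted[:, 1] + 11.9, rough_mesh.box)
        assert mb.helfrich_energy(rough_mesh, shifted) == pytest.approx(e0)

    def test_invariance_under_vertex_relabeling(self, rough_mesh):
        e0 = mb.helfrich_energy(rough_mesh)
        perm = np.random.default_rng(0).permutation(rough_mesh.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        m2 = mb.MembraneMesh(rough_mesh.vertices[perm],
                             inv[rough_mesh.triangles],
                             box=rough_mesh.box, kappa=rough_mesh.kappa,
                             sigma=rough_mesh.sigma)
        assert mb.helfrich_energy(m2) == pytest.approx(e0)

    def test_flat_sheet_is_bending_ground_state(self, rng):
        m = flat_patch()
        e_flat = mb.bending_energy(m)
        for _ in range(5):
            pos = m.vertices.copy()
            pos[:, 2] += 0.5 * rng.standard_normal(m.n_vertices)
            assert mb.bending_energy(m, pos) > e_flat


class TestExcessArea:
    def test_direct_arithmetic(self):
        m = flat_patch()
        # a configuration with A = 1.25 A_p has A_ex = 0.2
        a_p = m.projected_area
        assert (1.25 * a_p - a_p) / (1.25 * a_p) == pytest.approx(0.2)

    def test_unphysical_area_raises(self, rough_mesh):
        m2 = mb.MembraneMesh(rough_mesh.vertices * 0.5,
                             rough_mesh.triangles, box=rough_mesh.box)
        with pytest.raises(ValueError, match="unphysical"):
            mb.excess_area(m2)

    @pytest.mark.parametrize("target", [0.06, 0.12, 0.20])
    def test_builder_reaches_studied_range(self, target):
        m = build_membrane_fixture(L=120.0, n_vertices=144, a_ex=target,
                                   seed=3)
        assert mb.excess_area(m) == pytest.approx(target, abs=0.005)

    def test_builder_zero_target_returns_flat_mesh(self):
        m = build_membrane_fixture(L=120.0, n_vertices=144, a_ex=0.0, seed=3)
        assert np.all(m.vertices[:, 2] == 0.0)

    def test_builder_deterministic(self):
        a = build_membrane_fixture(L=120.0, n_vertices=144, a_ex=0.1, seed=9)
        b = build_membrane_fixture(L=120.0, n_vertices=144, a_ex=0.1, seed=9)
        assert np.array_equal(a.vertices, b.vertices)


class TestVertexMove:
    def test_zero_displacement_zero_energy(self, rough_mesh):
        res = mb.vertex_move(rough_mesh, 12, np.zeros(3))
        assert res.ok and res.delta_energy == pytest.approx(0.0, abs=1e-9)

    def test_lifting_flat_vertex_costs_energy(self):
        m = flat_patch()
        res = mb.vertex_move(m, 33, np.array([0.0, 0.0, 1.5]))
        assert res.ok and res.delta_energy > 0

    @pytest.mark.parametrize("v", [0, 9, 37, 55, 99])
    def test_local_equals_global_recomputation(self, rough_mesh, v):
        a0 = mb.total_area(rough_mesh)
        e0 = mb.helfrich_energy(rough_mesh)
        disp = np.array([0.2, -0.1, 1.1])
        res = mb.vertex_move(rough_mesh, v, disp, current_area=a0)
        pos = rough_mesh.vertices.copy()
        pos[v] += disp
        d_global = mb.helfrich_energy(rough_mesh, pos) - e0
        assert res.delta_energy == pytest.approx(d_global, rel=1e-9, abs=1e-9)

    def test_degenerate_triangle_rejected(self, rough_mesh):
        v = 12
        nbr = int(rough_mesh.triangles[rough_mesh.incident_triangles(v)[0], 1])
        if nbr == v:
            nbr = int(rough_mesh.triangles[rough_mesh.incident_triangles(v)[0], 2])
        disp = rough_mesh.wrap_deltas(
            rough_mesh.vertices[nbr] - rough_mesh.vertices[v])
        res = mb.vertex_move(rough_mesh, v, disp)
        assert not res.ok


class TestTopology:
    def test_valid_meshes_pass(self, rough_mesh):
        for m in (rough_mesh, flat_patch(60, 6)):
            rep = mb.mesh_topology_check(m)
            assert rep.ok and not rep.defects

    def test_closed_counts(self):
        m = flat_patch(60, 6)
        assert m.n_links == 3 * m.n_vertices
        assert m.n_triangles == 2 * m.n_vertices

    def test_missing_triangle_is_located(self, rough_mesh):
        broken = mb.MembraneMesh(rough_mesh.vertices.copy(),
                                 rough_mesh.triangles[1:],
                                 box=rough_mesh.box)
        rep = mb.mesh_topology_check(broken)
        assert not rep.ok
        located = {d[1] for d in rep.defects if d[0] == "manifold"}
        lost_tri = rough_mesh.triangles[0]
        lost_edges = {tuple(sorted((int(lost_tri[i]), int(lost_tri[(i + 1) % 3]))))
                      for i in range(3)}
        assert located & lost_edges  # defects locate the lost links

    def test_full_scale_preset_counts(self):
        """The full-scale patch is the closest periodic triangulation to the
        nominal vertex count; E = 3V and F = 2V hold exactly."""
        m = build_membrane_fixture(L=500.0, n_vertices=2704, a_ex=0.0, seed=0)
        rep = mb.mesh_topology_check(m)
        assert rep.ok
        assert rep.n_vertices == 2704
        assert rep.n_links == 3 * rep.n_vertices


class TestSurfaceSampling:
    def test_heights_exact_at_vertices(self, rough_mesh):
        s = mb.surface_sample(rough_mesh, rough_mesh.vertices[:, :2])
        assert np.allclose(s.z, rough_mesh.vertices[:, 2], atol=1e-9)

    def test_scalar_and_vector_paths_agree(self, rough_mesh, rng):
        pts = rng.uniform(-50.0, 150.0, size=(200, 2))
        vec = mb.surface_sample(rough_mesh, np.mod(pts, rough_mesh.box))
        for k, (x, y) in enumerate(pts):
            one = mb.surface_sample_one(rough_mesh, x, y)
            assert one.z[0] == pytest.approx(vec.z[k], abs=1e-9)
            assert np.allclose(one.normals[0], vec.normals[k], atol=1e-9)

    def test_normals_are_unit_and_upward(self, rough_mesh, rng):
        pts = rng.uniform(0.0, 100.0, size=(50, 2))
        s = mb.surface_sample(rough_mesh, pts)
        assert np.allclose(np.linalg.norm(s.normals, axis=1), 1.0)
        assert np.all(s.normals[:, 2] > 0)
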