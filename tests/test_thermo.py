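"""Thermodynamic estimators, multivalency statistics and contrasts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from avidmc import thermo_analysis as ta
from avidmc.constants import HBAR_J, KB_J, T_REF, thermal_wavelength_nm


def _gaussian_entropy_exact(sigmas_nm, mass_kg, temperature=T_REF):
    """Closed-form classical oscillator entropy for independent Gaussian
    coordinates (per-mode S/k_B = 1 + ln(sqrt(m kT) sigma / hbar))."""
    kt = KB_J * temperature
    s = 0.0
    for sig in sigmas_nm:
        s += 1.0 + 0.5 * math.log(kt * mass_kg * (sig * 1e-9) ** 2 / HBAR_J ** 2)
    return s


class TestQuasiharmonicEntropy:
    def test_matches_independent_gaussians(self, rng):
        sigmas = np.array([0.4, 0.8, 1.2, 0.6, 1.0, 0.9])
        mass = 1.44e-22
        samples = rng.standard_normal((10_000, 6)) * sigmas
        s = ta.quasiharmonic_entropy(samples, np.full(6, mass))
        assert s == pytest.approx(_gaussian_entropy_exact(sigmas, mass),
                                  rel=0.01)

    def test_rigid_record_raises_rank_error(self):
        frames = np.zeros((200, 4, 3))
        with pytest.raises(ValueError, match="rank-deficient"):
            ta.quasiharmonic_entropy(frames, np.full(4, 1e-22))

    def test_alignment_removes_rigid_body_modes(self, rng):
        """A rigidly tumbling but internally frozen body has zero aligned
        configurational entropy (all modes fall below the filter)."""
        base = rng.standard_normal((5, 3)) * 4.0
        frames = []
        from scipy.spatial.transform import Rotation
        for _ in range(300):
            rot = Rotation.random(rng=rng)
            frames.append(base @ rot.as_matrix().T + rng.normal(size=3))
        with pytest.raises(ValueError, match="rank-deficient"):
            ta.quasiharmonic_entropy(np.array(frames), np.full(5, 1e-22),
                                     align=True)

    def test_inflating_fluctuations_increases_entropy(self, rng):
        samples = rng.standard_normal((5_000, 9))
        m = np.full(9, 1e-22)
        assert (ta.quasiharmonic_entropy(2.0 * samples, m)
                > ta.quasiharmonic_entropy(samples, m))

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            ta.quasiharmonic_entropy(rng.standard_normal((10, 6)),
                                     np.full(6, 1e-22))


class TestMembraneEntropy:
    def test_identical_records_give_zero(self, rng):
        z = rng.standard_normal((2_000, 30))
        assert ta.membrane_entropy_delta(z, z.copy(), 5.5e-22) == pytest.approx(0.0)

    def test_inflated_bound_fluctuations_raise_entropy(self, rng):
        z = rng.standard_normal((2_000, 30))
        assert ta.membrane_entropy_delta(1.5 * z, z, 5.5e-22) > 0

    def test_matches_per_mode_closed_form(self, rng):
        sigmas = np.array([0.5, 1.0, 2.0])
        z = rng.standard_normal((8_000, 3)) * sigmas
        got = ta.quasiharmonic_entropy(z, np.full(3, 5.5e-22))
        assert got == pytest.approx(_gaussian_entropy_exact(sigmas, 5.5e-22),
                                    rel=0.02)


class TestSackurTetrode:
    def test_doubling_area_adds_n_ln2(self):
        s1 = ta.receptor_translational_entropy(100, 1e5)
        s2 = ta.receptor_translational_entropy(100, 2e5)
        assert s2 - s1 == pytest.approx(100 * math.log(2.0))

    def test_extensivity(self):
        s1 = ta.receptor_translational_entropy(50, 1e5)
        s2 = ta.receptor_translational_entropy(100, 2e5)
        assert s2 == pytest.approx(2.0 * s1)

    def test_direct_formula_evaluation(self):
        n, area, mass = 250, 2.5e5, 1.5e-22
        lam = thermal_wavelength_nm(mass)
        expected = n * (math.log(area / (n * lam ** 2)) + 2.0)
        assert ta.receptor_translational_entropy(n, area, mass) == \
            pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ta.receptor_translational_entropy(0, 1e5)
        with pytest.raises(ValueError):
            ta.receptor_translational_entropy(10, -1.0)

    def test_bound_receptors_lower_translational_entropy(self):
        d = ta.receptor_entropy_delta(100, 1e5, mean_bound=30.0)
        assert d < 0
        assert ta.receptor_entropy_delta(100, 1e5, mean_bound=0.0) == 0.0


class TestFreeEnergyAssembly:
    def test_worked_example(self):
        res = ta.binding_free_energy(-100.0, -5.0, -10.0, -5.0, mean_m=40.0)
        assert res.TdS_total == pytest.approx(-20.0)
        assert res.dF == pytest.approx(-80.0)
        assert res.per_bond()["dF"] == pytest.approx(-2.0)

    def test_zero_inputs(self):
        res = ta.binding_free_energy(0.0, 0.0, 0.0, 0.0)
        assert res.dF == 0.0
        assert res.per_bond() is None

    def test_identity_holds_for_random_components(self, rng):
        for _ in range(20):
            h, a, b, c = rng.normal(size=4) * 50
            res = ta.binding_free_energy(h, a, b, c, mean_m=1.0)
            assert res.dF == pytest.approx(res.dH - res.TdS_total, abs=1e-12)

    def test_sd_propagates_in_quadrature(self):
        res = ta.binding_free_energy(-10, 0, 0, 0, dH_sd=3.0, TdS_sd=4.0)
        assert res.dF_sd == pytest.approx(5.0)


class TestBindingEnthalpy:
    def test_identical_trajectories_give_zero(self, desk_trajectory):
        _, traj = desk_trajectory
        dh, sd = ta.binding_enthalpy(traj, traj)
        assert dh == 0.0 and sd == 0.0

    def test_protocol_mismatch_rejected(self, desk_trajectory):
        from avidmc.mc_engine import EnsembleResult
        _, traj = desk_trajectory
        two = EnsembleResult([traj, traj], [1, 2])
        with pytest.raises(ValueError, match="protocol"):
            ta.binding_enthalpy(two, traj)


class TestEnsembleAnalysis:
    def test_full_decomposition_pipeline(self):
        """analyze_ensembles produces a consistent dH/TdS/dF decomposition
        from matched bound/unbound replica ensembles."""
        import copy
        from avidmc import mc_engine as eng
        from avidmc.system_builder import desk_fixture

        system = desk_fixture("mini_LSt_strong_lowNr")
        sched = copy.deepcopy(system.schedule)
        sched.equilibration_steps = 8_000
        sched.production_steps = 24_000
        sched.sample_interval = 200
        sched.record_interval = 300
        bound = eng.run_replicas(system, sched, [1, 2])
        unbound = eng.EnsembleResult(
            [eng.run_unbound_reference(system, sched, s) for s in (8, 9)],
            [8, 9])
        res = ta.analyze_ensembles(bound, unbound, system)
        assert math.isfinite(res.dF)
        assert res.dF == pytest.approx(res.dH - res.TdS_total, abs=1e-12)
        assert res.mean_m >= 0
        # binding removes mobile receptors: translational term non-positive
        if res.mean_m > 0:
            assert res.TdS_rec <= 0


class TestMultivalencyDistribution:
    def test_small_series_example(self):
        support, p, mean, modes = ta.multivalency_distribution(
            np.array([2, 2, 3]), smooth_sigma=0)
        assert p[2] == pytest.approx(2 / 3)
        assert p[3] == pytest.approx(1 / 3)
        assert mean == pytest.approx(7 / 3)

    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1,
                    max_size=300))
    def test_normalization_and_support(self, series):
        support, p, mean, modes = ta.multivalency_distribution(np.array(series))
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)
        assert 0 <= mean <= max(series)
        assert all(0 <= m <= max(series) for m in modes)

    def test_saturation_peak_is_reported_at_support_edge(self, rng):
        series = np.clip(rng.normal(20, 0.8, 4000).round().astype(int), 0, 20)
        _, _, _, modes = ta.multivalency_distribution(series, m_max=20)
        assert 20 in modes

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ta.multivalency_distribution(np.array([], dtype=int))


class TestCoverageAndSelectivity:
    def test_coverage_examples(self):
        assert ta.coverage_theta(162.0, 162) == 1.0
        assert ta.coverage_theta(81.0, 162) == 0.5
        assert ta.coverage_theta(0.0, 162) == 0.0
        tile = ta.PhaseTile(0.2, 250, dF=-10, dF_sd=1, theta=0.5)
        assert tile.coverage_marker

    def test_power_law_exponent_recovered(self):
        n_r = np.array([50.0, 125, 250, 500, 1000])
        theta = 1e-4 * n_r ** 2
        alpha, valid = ta.selectivity_index(n_r, theta)
        inner = slice(1, -1)
        assert np.allclose(alpha[inner], 2.0, atol=1e-9)

    def test_constant_coverage_has_zero_slope(self):
        n_r = np.array([50.0, 125, 250])
        alpha, valid = ta.selectivity_index(n_r, np.full(3, 0.4))
        assert np.allclose(alpha, 0.0, atol=1e-12)
        assert valid.all()

    def test_saturated_rows_fall_outside_validity_window(self):
        n_r = np.array([50.0, 125, 250])
        alpha, valid = ta.selectivity_index(n_r, np.full(3, 0.99))
        assert not valid.any()

    def test_zero_coverage_points_excluded(self):
        n_r = np.array([50.0, 125, 250])
        alpha, valid = ta.selectivity_index(n_r, np.array([0.0, 0.2, 0.4]))
        assert np.isnan(alpha[0]) and not valid[0]


class TestWelchAndBH:
    def test_identical_groups_not_significant(self):
        a = [1.0, 1.1, 0.9, 1.0]
        _, _, p = ta.welch_test(a, list(a))
        assert p > 0.95

    def test_matches_textbook_formula(self, rng):
        """Welch statistic and Satterthwaite dof against the raw formulas."""
        a = rng.normal(0.0, 1.0, 7)
        b = rng.normal(1.0, 2.5, 5)
        t, dof, p = ta.welch_test(a, b)
        sa, sb = a.var(ddof=1) / 7, b.var(ddof=1) / 5
        t_ref = (a.mean() - b.mean()) / math.sqrt(sa + sb)
        dof_ref = (sa + sb) ** 2 / (sa ** 2 / 6 + sb ** 2 / 4)
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t_ref), dof_ref)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert dof == pytest.approx(dof_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_equal_groups(self):
        _, _, p = ta.welch_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_bh_worked_example(self):
        # brute-force step-up BH against the library implementation
        p = np.array([0.01, 0.02, 0.03, 0.5])
        m = p.size
        order = np.argsort(p)
        stepup = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        q_brute = np.empty(m)
        q_brute[order] = np.minimum(stepup, 1.0)
        from statsmodels.stats.multitest import multipletests
        _, q_lib, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q_lib, q_brute, atol=1e-12)
        assert np.all(q_lib >= p - 1e-12)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=2, max_size=12))
    def test_bh_qvalues_dominate_pvalues(self, pvals):
        from statsmodels.stats.multitest import multipletests
        p = np.array(pvals)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.all(q >= p - 1e-12)
        # step-up monotonicity: sorted q follows sorted p ordering
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_direction_points_to_more_favorable_row(self):
        pv, qv, rej, favors = ta.welch_bh_contrast(
            [[-10.0, -10.5, -9.5], [-1.0, -1.2, -0.8]],
            [[-2.0, -2.2, -1.8], [-5.0, -5.5, -4.5]])
        assert favors[0] == -1.0 and favors[1] == 1.0


class TestPhaseDiagram:
    def _tiles(self):
        tiles = []
        for a_ex in (0.06, 0.20):
            for k, n_r in enumerate((50, 125, 250)):
                tiles.append(ta.PhaseTile(
                    a_ex=a_ex, n_r=n_r, dF=-5.0 * (k + 1), dF_sd=0.5,
                    theta=0.6, alpha=2.0 if n_r == 50 else 0.5,
                    alpha_valid=True, q_value=0.01 if k == 0 else 0.06))
        return tiles

    def test_markers_and_flags(self):
        df, fig = ta.build_phase_diagram(self._tiles())
        assert df.coverage_marker.all()          # theta >= 0.5 everywhere
        assert df[df.n_r == 50].superselective.all()
        assert not df[df.n_r == 250].superselective.any()
        assert df[df.q_value < 0.05].significant.all()
        assert not df[df.q_value >= 0.05].significant.any()

    def test_missing_tiles_flagged(self):
        grid = [(a, n) for a in (0.06, 0.20) for n in (50, 125, 250, 500)]
        with pytest.raises(ValueError, match="missing"):
            ta.build_phase_diagram(self._tiles(), expected_grid=grid)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            ta.PhaseTile(0.2, 50, dF=0, dF_sd=0, theta=1.5)
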