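import math

import numpy as np
import pytest

from hemeqmc import AndersonModel, ImaginaryTimeGrid
from hemeqmc.constants import K_B
from hemeqmc.ed import ed_observables
from hemeqmc.hf import run_qmc
from hemeqmc.observables import (
    SusceptibilityCurve,
    curie_fit,
    effective_moment,
    fe_host_correlation,
    moment_vs_mu_scan,
    project_moment_density,
    tune_mu,
)
from hemeqmc.synth import make_curie_dataset, make_toy_cluster


class TestEffectiveMoment:
    def test_free_spin_half_gives_sqrt3(self):
        # chi of a free S=1/2 (g=2): beta * <M_z^2> = beta * 1 muB^2
        for T in (50.0, 300.0, 1000.0):
            chi = 1.0 / (K_B * T)
            assert effective_moment(chi, T) == pytest.approx(math.sqrt(3.0),
                                                             rel=1e-12)

    def test_free_spin_two_gives_4p9(self):
        """S = 2: g sqrt(S(S+1)) = sqrt(24) = 4.899 muB."""
        T = 200.0
        chi = 4.0 * 2.0 * 3.0 / 3.0 / (K_B * T)   # g^2 S(S+1)/3 * beta
        assert effective_moment(chi, T) == pytest.approx(math.sqrt(24.0),
                                                         rel=1e-12)
        assert effective_moment(chi, T) == pytest.approx(4.9, abs=0.002)

    def test_zero_chi_and_negative_chi(self):
        assert effective_moment(0.0, 300.0) == 0.0
        with pytest.raises(ValueError):
            effective_moment(-1.0, 300.0)


class TestCurieFit:
    def test_exact_generator_recovery(self):
        curve = make_curie_dataset(4.9, [100, 200, 300, 450, 600], noise=0.0)
        fit = curie_fit(curve)
        assert fit.M_eff == pytest.approx(4.9, rel=1e-12)
        assert not fit.has_crossover
        assert fit.red_chi2 == pytest.approx(0.0, abs=1e-16)

    def test_noisy_recovery_within_2_sigma(self):
        """Repeated-seed calibration: 5% noise recovers M_eff within 2 sigma."""
        hits = 0
        for seed in range(10):
            curve = make_curie_dataset(4.9, [100, 150, 200, 300, 450, 600],
                                       noise=0.05, seed=seed)
            fit = curie_fit(curve)
            if abs(fit.M_eff - 4.9) < 2 * fit.M_eff_err:
                hits += 1
        assert hits >= 8  # ~95% coverage expected

    def test_crossover_dataset_flagged_and_resolved(self):
        curve = make_curie_dataset(2.1, [100, 150, 200, 250, 400, 500, 600],
                                   noise=0.01, seed=1, T_star=300.0,
                                   M_eff_high=4.1)
        fit = curie_fit(curve)
        assert fit.has_crossover
        assert 200 <= fit.crossover["T_star"] <= 450
        assert fit.crossover["M_low"] == pytest.approx(2.1, rel=0.1)
        assert fit.crossover["M_high"] == pytest.approx(4.1, rel=0.1)

    def test_idempotent_with_effective_moment_on_exact_data(self):
        curve = make_curie_dataset(3.3, [120, 240, 480], noise=0.0)
        fit = curie_fit(curve)
        for T, chi in zip(curve.T, curve.chi):
            assert effective_moment(chi, T) == pytest.approx(fit.M_eff,
                                                             rel=1e-12)


class TestTuneMu:
    def test_particle_hole_symmetric_point(self):
        """Single orbital: mu = eps_d + U/2 gives <n> = 1 (here eps_d=-U/2)."""
        m = make_toy_cluster(1, 2, "symmetric", U=2.0, V=0.5)
        mu = tune_mu(m.with_mu(0.3), T=1.0 / (K_B * 2.0), solver="ed", tol=1e-3)
        assert mu == pytest.approx(0.0, abs=0.02)

    def test_noninteracting_half_filling_at_symmetric_point(self):
        m = AndersonModel(host_energies=[1.0, -1.0], impurity_energies=[0.0],
                          hybridization=[[0.3], [0.3]], U=0.0, J=0.0,
                          n_target=3.0)
        mu = tune_mu(m, T=300.0, solver="noninteracting", tol=1e-4)
        assert mu == pytest.approx(0.0, abs=1e-3)

    def test_qmc_tuned_mu_matches_ed_tuned_mu(self, hubbard_dimer):
        import dataclasses
        T = 1.0 / (K_B * 2.0)
        m = dataclasses.replace(hubbard_dimer, n_target=2.0)
        mu_ed = tune_mu(m, T, solver="ed", tol=0.005)
        grid = ImaginaryTimeGrid(beta=2.0, L=8)
        mu_qmc = tune_mu(m, T, solver="qmc", tol=0.02,
                         solver_kwargs={"grid": grid, "n_warmup": 100,
                                        "n_sweeps": 1500, "n_bins": 8,
                                        "seed": 9})
        assert mu_qmc == pytest.approx(mu_ed, abs=0.1)

    def test_no_bracket_raises(self):
        m = AndersonModel(host_energies=np.empty(0), impurity_energies=[0.0],
                          hybridization=np.empty((0, 1)), U=0.0, J=0.0,
                          n_target=5.0)  # impossible: max 2 electrons
        with pytest.raises(RuntimeError):
            tune_mu(m, T=300.0, solver="noninteracting")


class TestMomentVsMu:
    def test_free_moment_maximal_at_level_crossing(self):
        m = AndersonModel(host_energies=[3.0], impurity_energies=[0.5],
                          hybridization=[[0.0]], U=0.0, J=0.0)
        T = 1000.0
        df = moment_vs_mu_scan(m, T, np.linspace(-0.5, 1.5, 21), solver="free")
        peak_mu = df.loc[df.M_t.idxmax(), "mu"]
        assert peak_mu == pytest.approx(0.5, abs=0.11)

    def test_flat_region_far_from_levels_has_no_moment(self):
        m = AndersonModel(host_energies=[5.0], impurity_energies=[-5.0],
                          hybridization=[[0.0]], U=0.0, J=0.0)
        df = moment_vs_mu_scan(m, 300.0, [0.0], solver="free")
        assert df.M_t.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_ed_and_free_agree_when_u_is_zero(self, two_level_model):
        T = 1.0 / (K_B * 2.0)
        grid = np.array([-0.5, 0.0, 0.5])
        free = moment_vs_mu_scan(two_level_model, T, grid, solver="free")
        ed = moment_vs_mu_scan(two_level_model, T, grid, solver="ed")
        assert np.allclose(free.M_t, ed.M_t, rtol=1e-8)


class TestMomentDensityMap:
    def _result(self, model, seed=4):
        grid = ImaginaryTimeGrid(beta=2.0, L=8)
        return run_qmc(model, grid, n_warmup=100, n_sweeps=1500, n_bins=8,
                       seed=seed)

    def test_atomic_sum_equals_total_moment(self, toy_interacting):
        r = self._result(toy_interacting)
        n_states = toy_interacting.n_sites
        rng = np.random.default_rng(0)
        proj = rng.random((n_states, 3))
        proj /= proj.sum(axis=1, keepdims=True)
        dmap = project_moment_density(r, proj)
        assert dmap.moments.sum() == pytest.approx(r.m_t_instantaneous,
                                                   rel=1e-8)

    def test_unnormalized_projection_rejected(self, toy_interacting):
        r = self._result(toy_interacting)
        proj = np.ones((toy_interacting.n_sites, 2))
        with pytest.raises(ValueError):
            project_moment_density(r, proj)

    def test_decoupled_host_shows_only_its_own_moment(self):
        """V = 0: host-impurity cross correlations vanish."""
        m = AndersonModel(host_energies=[0.0], impurity_energies=[-1.0],
                          hybridization=[[0.0]], U=2.0, J=0.0)
        r = self._result(m)
        assert abs(r.fe_host_corr[0]) < 3 * r.fe_host_corr_err[0] + 1e-10

    def test_af_fixture_host_sign_opposite_to_impurity(self):
        """Hund-coupled two-orbital impurity + half-filled host, strong V:
        the impurity moment dominates the total and the antiferromagnetically
        locked host site comes out with the opposite sign in the map."""
        m = make_toy_cluster(2, 1, "kondo", U=2.0, J=0.4, V=0.9)
        ed = ed_observables(m, 1.0 / (K_B * 4.0))
        corr = ed["site_moment_corr"]
        assert corr[0, 1:].sum() < 0     # ED oracle: AF impurity-host cross
        assert corr[0].sum() < 0         # ED oracle: host row-sum negative
        r = run_qmc(m, ImaginaryTimeGrid(beta=4.0, L=16), n_warmup=300,
                    n_sweeps=6000, n_bins=12, seed=6)
        # host state -> C site; both impurity orbitals -> Fe site
        proj = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        dmap = project_moment_density(r, proj, atom_labels=("Fe", "C"))
        assert dmap.moments[0] > 0
        assert dmap.moments[1] < 0
        assert dmap.moments.sum() == pytest.approx(r.m_t_instantaneous, rel=1e-8)


class TestFeHostCorrelation:
    def test_zero_for_free_decoupled_model(self):
        m = AndersonModel(host_energies=[0.5], impurity_energies=[-0.5],
                          hybridization=[[0.0]], U=0.0, J=0.0)
        r = run_qmc(m, ImaginaryTimeGrid(beta=2.0, L=8), n_warmup=20,
                    n_sweeps=200, n_bins=4, seed=0)
        s = fe_host_correlation(r)
        assert abs(s.iloc[0]) < 1e-10

    def test_kondo_like_correlation_negative_and_grows_on_cooling(self):
        m = make_toy_cluster(1, 1, "kondo", U=2.0, V=0.9)
        prev = 0.0
        for beta in (1.0, 2.0, 4.0):
            corr = ed_observables(m, 1.0 / (K_B * beta))["site_moment_corr"][0, 1]
            assert corr < 0
            assert corr < prev  # more negative as T drops
            prev = corr

    def test_far_empty_host_level_uncorrelated(self):
        m = AndersonModel(host_energies=[8.0], impurity_energies=[-1.0],
                          hybridization=[[0.4]], U=2.0, J=0.0)
        corr = ed_observables(m, 1.0 / (K_B * 2.0))["site_moment_corr"][0, 1]
        assert abs(corr) < 5e-3


class TestSusceptibilityCurve:
    def test_sorting_and_validation(self):
        c = SusceptibilityCurve(T=[300.0, 100.0, 200.0], chi=[1.0, 3.0, 1.5])
        assert list(c.T) == [100.0, 200.0, 300.0]
        assert list(c.chi) == [3.0, 1.5, 1.0]
        with pytest.raises(ValueError):
            SusceptibilityCurve(T=[0.0, 100.0], chi=[1.0, 1.0])
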