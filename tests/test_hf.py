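import math

import numpy as np
import pytest

from hemeqmc import AndersonModel, ImaginaryTimeGrid
from hemeqmc.constants import K_B
from hemeqmc.ed import ed_observables
from hemeqmc.hf import (
    HSFieldConfiguration,
    enumerate_fields,
    extrapolate_dtau,
    green_from_fields,
    jackknife_ratio,
    propose_flip,
    quadratic_extrapolate,
    run_qmc,
    sweep,
)
from hemeqmc.model import build_pair_table, compute_bath_g0


def random_fields(table, L, seed=0):
    rng = np.random.default_rng(seed)
    return HSFieldConfiguration.random(table.n_pairs, L, rng).fields


@pytest.fixture
def dimer_setup(hubbard_dimer):
    grid = ImaginaryTimeGrid(beta=2.0, L=8)
    table = build_pair_table(hubbard_dimer, grid)
    bath = compute_bath_g0(hubbard_dimer, grid,
                           impurity_shift=table.hartree_shift(1))
    return hubbard_dimer, grid, table, bath


@pytest.fixture
def two_orbital_setup():
    model = AndersonModel(host_energies=[0.4, -0.6],
                          impurity_energies=[-1.6, -1.4],
                          hybridization=[[0.5, 0.2], [0.3, 0.4]],
                          U=2.0, J=0.4)
    grid = ImaginaryTimeGrid(beta=2.0, L=8)
    table = build_pair_table(model, grid)
    bath = compute_bath_g0(model, grid, impurity_shift=table.hartree_shift(2))
    return model, grid, table, bath


class TestGreenFromFields:
    def test_free_theory_returns_g0(self):
        m = AndersonModel(host_energies=[0.5], impurity_energies=[-0.5],
                          hybridization=[[0.4]], U=0.0, J=0.0)
        grid = ImaginaryTimeGrid(beta=1.0, L=4)
        table = build_pair_table(m, grid)
        bath = compute_bath_g0(m, grid)
        G = green_from_fields(bath, random_fields(table, grid.L), table)
        assert np.allclose(G[0], bath.g0, atol=1e-14)
        assert np.allclose(G[1], bath.g0, atol=1e-14)

    def test_discrete_path_integral_small_L(self):
        """Weighted enumeration over all configs equals ED (Trotter-limited)."""
        m = AndersonModel(host_energies=np.empty(0), impurity_energies=[-0.25],
                          hybridization=np.empty((0, 1)), U=0.5, J=0.0)
        grid = ImaginaryTimeGrid(beta=0.4, L=2)  # 4 configurations
        en = enumerate_fields(m, grid)
        ed = ed_observables(m, 1.0 / (K_B * grid.beta))
        # atomic limit: HS decoupling is exact at any dtau
        assert en["occ"] == pytest.approx(ed["n"], abs=1e-12)
        assert en["pair_density"][0] == pytest.approx(ed["docc"][0], abs=1e-12)

    def test_flip_then_clean_matches_fast_update(self, two_orbital_setup):
        model, grid, table, bath = two_orbital_setup
        f = random_fields(table, grid.L, seed=3)
        G, sgn, ld = green_from_fields(bath, f, table, return_weight=True)
        for p, l in [(0, 0), (1, 3), (2, 5), (4, 7), (5, 2)]:
            G2, f2 = G.copy(), f.copy()
            R, apply = propose_flip(G2, f2, table, p, l)
            apply()
            Gc = green_from_fields(bath, f2, table)
            assert np.abs(G2 - Gc).max() < 1e-9


class TestProposeFlip:
    def test_zero_lambda_ratio_is_one(self):
        m = AndersonModel(host_energies=[0.5], impurity_energies=[-0.5],
                          hybridization=[[0.4]], U=0.0, J=0.0)
        grid = ImaginaryTimeGrid(beta=1.0, L=4)
        table = build_pair_table(m, grid)
        bath = compute_bath_g0(m, grid)
        f = random_fields(table, grid.L)
        G = green_from_fields(bath, f, table)
        R, _ = propose_flip(G, f, table, 0, 1)
        assert R == pytest.approx(1.0, abs=1e-14)

    def test_ratio_equals_dense_determinant_ratio(self, two_orbital_setup):
        """Covers scalar (opposite-spin) and 2x2 (same-spin) channels."""
        model, grid, table, bath = two_orbital_setup
        f = random_fields(table, grid.L, seed=5)
        G, sgn, ld = green_from_fields(bath, f, table, return_weight=True)
        for p in range(table.n_pairs):
            f2 = f.copy()
            R, _ = propose_flip(G.copy(), f2, table, p, 4)
            f2[p, 4] = -f2[p, 4]
            _, sg2, ld2 = green_from_fields(bath, f2, table, return_weight=True)
            R_exact = sg2 * sgn * math.exp(ld2 - ld)
            assert R == pytest.approx(R_exact, rel=1e-10)


class TestSweep:
    def test_free_theory_metropolis_accepts_all_and_leaves_g(self):
        m = AndersonModel(host_energies=[0.5], impurity_energies=[-0.5],
                          hybridization=[[0.4]], U=0.0, J=0.0)
        grid = ImaginaryTimeGrid(beta=1.0, L=6)
        table = build_pair_table(m, grid)
        bath = compute_bath_g0(m, grid)
        f = random_fields(table, grid.L)
        G = green_from_fields(bath, f, table)
        G0 = G.copy()
        rng = np.random.default_rng(0)
        nacc, _ = sweep(G, f, table, rng, acceptance="metropolis")
        assert nacc == table.n_pairs * grid.L
        assert np.allclose(G, G0, atol=1e-12)

    def test_acceptance_rate_strictly_between_zero_and_one(self, dimer_setup):
        model, grid, table, bath = dimer_setup
        f = random_fields(table, grid.L, seed=2)
        G = green_from_fields(bath, f, table)
        rng = np.random.default_rng(7)
        total = acc = 0
        for _ in range(20):
            n, _ = sweep(G, f, table, rng)
            acc += n
            total += table.n_pairs * grid.L
        assert 0 < acc < total

    def test_drift_stays_small_over_100_sweeps(self, two_orbital_setup):
        model, grid, table, bath = two_orbital_setup
        f = random_fields(table, grid.L, seed=9)
        G, sgn, _ = green_from_fields(bath, f, table, return_weight=True)
        rng = np.random.default_rng(1)
        for _ in range(100):
            _, sgn = sweep(G, f, table, rng, sign=sgn)
        Gc, sgc, _ = green_from_fields(bath, f, table, return_weight=True)
        assert np.abs(G - Gc).max() < 1e-8
        assert sgn == sgc


class TestRunQMC:
    def test_toy_fixture_agrees_with_ed_within_3_sigma(self, toy_interacting):
        grid = ImaginaryTimeGrid(beta=2.0, L=16)
        r = run_qmc(toy_interacting, grid, n_warmup=300, n_sweeps=6000,
                    n_bins=16, seed=12)
        ed = ed_observables(toy_interacting, 1.0 / (K_B * 2.0))
        assert abs(r.pair_density[0] - ed["docc"][0]) < 3 * r.pair_density_err[0] \
            + 0.002  # small Trotter allowance at dtau = 0.125
        assert abs(r.m2_total - ed["m2_total"]) < 3 * r.m2_total_err + 0.01
        assert np.all(np.abs(r.occ - ed["n"]) < 3 * r.occ_err + 0.003)

    def test_atomic_limit_double_occupancy(self):
        """V = 0, U = 2, beta = 2: <n_up n_dn> from the 4-state atomic trace."""
        eps = -0.7
        m = AndersonModel(host_energies=np.empty(0), impurity_energies=[eps],
                          hybridization=np.empty((0, 1)), U=2.0, J=0.0)
        beta = 2.0
        grid = ImaginaryTimeGrid(beta=beta, L=8)
        Z = 1 + 2 * math.exp(-beta * eps) + math.exp(-beta * (2 * eps + 2.0))
        docc_exact = math.exp(-beta * (2 * eps + 2.0)) / Z
        r = run_qmc(m, grid, n_warmup=200, n_sweeps=8000, n_bins=16, seed=5)
        # atomic limit: decoupling exact at any dtau, so only statistics remain
        assert r.pair_density[0] == pytest.approx(docc_exact,
                                                  abs=3.5 * r.pair_density_err[0])

    def test_same_seed_bit_identical(self, hubbard_dimer):
        grid = ImaginaryTimeGrid(beta=2.0, L=8)
        r1 = run_qmc(hubbard_dimer, grid, n_warmup=50, n_sweeps=400, n_bins=8,
                     seed=42)
        r2 = run_qmc(hubbard_dimer, grid, n_warmup=50, n_sweeps=400, n_bins=8,
                     seed=42)
        assert np.array_equal(r1.occ, r2.occ)
        assert np.array_equal(r1.site_moment_corr, r2.site_moment_corr)
        assert r1.chi_t == r2.chi_t and r1.sign == r2.sign

    def test_spin_symmetry_and_unit_sign_single_orbital(self, dimer_setup):
        model, grid, table, bath = dimer_setup
        r = run_qmc(model, grid, n_warmup=200, n_sweeps=4000, n_bins=16, seed=8)
        assert r.sign == 1.0  # no sign problem for a single orbital
        assert np.all(np.abs(r.occ[:, 0] - r.occ[:, 1]) < 4 * np.hypot(
            r.occ_err[:, 0], r.occ_err[:, 1]) + 1e-3)

    def test_heatbath_and_metropolis_agree(self, hubbard_dimer):
        grid = ImaginaryTimeGrid(beta=2.0, L=8)
        ed = ed_observables(hubbard_dimer, 1.0 / (K_B * 2.0))
        for acc in ("heatbath", "metropolis"):
            r = run_qmc(hubbard_dimer, grid, n_warmup=200, n_sweeps=6000,
                        n_bins=16, seed=21, acceptance=acc)
            assert r.pair_density[0] == pytest.approx(
                ed["docc"][0], abs=3 * r.pair_density_err[0] + 0.003)

    def test_tau_resolved_chi_cross_checks_equal_time_estimator(self, toy_interacting):
        """M_z conservation: tau-integrated chi tracks the beta<M^2> route.

        The displaced-time entries of the fixed-field Green's function built
        on an exact (non-Trotterized) bath carry a few-percent offset against
        the equal-time ones at these couplings (it vanishes in the free and
        atomic limits), so the cross-check allows a 10% discretization
        margin on top of the statistical errors; the equal-time route is the
        ED-validated primary estimator.
        """
        grid = ImaginaryTimeGrid(beta=2.0, L=16)
        r = run_qmc(toy_interacting, grid, n_warmup=200, n_sweeps=3000,
                    n_bins=12, seed=3, tau_resolved=True)
        err = math.hypot(r.chi_t_err, r.chi_t_tau_err)
        assert abs(r.chi_t - r.chi_t_tau) < 2.5 * err + 0.10 * r.chi_t

    def test_tau_corr_exactly_flat_in_atomic_limit(self):
        """Per-configuration densities are conserved when V = 0."""
        m = AndersonModel(host_energies=np.empty(0), impurity_energies=[-0.7],
                          hybridization=np.empty((0, 1)), U=2.0, J=0.0)
        r = run_qmc(m, ImaginaryTimeGrid(beta=1.0, L=8), n_warmup=50,
                    n_sweeps=500, n_bins=4, seed=1, tau_resolved=True)
        assert np.ptp(r.tau_corr) < 1e-10

    def test_bad_binning_rejected(self, hubbard_dimer):
        grid = ImaginaryTimeGrid(beta=2.0, L=8)
        with pytest.raises(ValueError):
            run_qmc(hubbard_dimer, grid, n_bins=2)


class TestEnumeration:
    def test_matches_ed_to_a_tenth_of_percent(self, hubbard_dimer):
        """Exhaustive sum over 2^(L n_pairs) configs vs ED at dtau <= 0.1."""
        grid = ImaginaryTimeGrid(beta=1.0, L=10)
        en = enumerate_fields(hubbard_dimer, grid)
        ed = ed_observables(hubbard_dimer, 1.0 / (K_B * grid.beta))
        assert en["pair_density"][0] == pytest.approx(ed["docc"][0], rel=1e-3)
        assert en["chi_zz"] == pytest.approx(ed["chi_zz"], rel=1e-3)
        assert en["occ"] == pytest.approx(ed["n"], rel=1e-3)

    def test_refuses_oversized_enumerations(self, hubbard_dimer):
        grid = ImaginaryTimeGrid(beta=2.0, L=20)
        with pytest.raises(ValueError):
            enumerate_fields(hubbard_dimer, grid)


class TestExtrapolation:
    def test_recovers_exact_quadratic(self):
        dtaus = [0.1, 0.2, 0.3]
        vals = [1.0 + 0.1 * d ** 2 for d in dtaus]
        O0, err, c = quadratic_extrapolate(dtaus, vals)
        assert O0 == pytest.approx(1.0, abs=1e-12)
        assert c == pytest.approx(0.1, abs=1e-10)

    def test_constant_series_zero_slope(self):
        O0, err, c = quadratic_extrapolate([0.5, 0.25, 0.125], [2.0, 2.0, 2.0],
                                           [0.1, 0.1, 0.1])
        assert O0 == pytest.approx(2.0)
        assert c == pytest.approx(0.0, abs=1e-10)

    def test_refuses_fewer_than_three_points(self):
        with pytest.raises(ValueError):
            quadratic_extrapolate([0.1, 0.2], [1.0, 1.0])

    def test_extrapolation_beats_any_single_dtau(self, toy_interacting):
        """dtau -> 0 limit of <n_up n_dn> lands closer to ED than raw points."""
        ed = ed_observables(toy_interacting, 1.0 / (K_B * 2.0))["docc"][0]
        results = []
        for i, dtau in enumerate((0.5, 0.25, 0.125)):
            L = int(round(2.0 / dtau))
            results.append(run_qmc(toy_interacting,
                                   ImaginaryTimeGrid(beta=2.0, L=L),
                                   n_warmup=300, n_sweeps=12000, n_bins=16,
                                   seed=31 + 7 * i))
        ex = extrapolate_dtau(results, observables=("pair_density",))
        val, err, _ = ex["pair_density"]
        worst_raw = max(abs(r.pair_density[0] - ed) for r in results)
        assert abs(val[0] - ed) < max(worst_raw, 3 * err[0])

    def test_requires_common_physics(self, toy_interacting):
        r1 = run_qmc(toy_interacting, ImaginaryTimeGrid(beta=2.0, L=4),
                     n_warmup=20, n_sweeps=80, n_bins=4, seed=1)
        r2 = run_qmc(toy_interacting, ImaginaryTimeGrid(beta=1.0, L=4),
                     n_warmup=20, n_sweeps=80, n_bins=4, seed=1)
        r3 = run_qmc(toy_interacting, ImaginaryTimeGrid(beta=2.0, L=8),
                     n_warmup=20, n_sweeps=80, n_bins=4, seed=1)
        with pytest.raises(ValueError):
            extrapolate_dtau([r1, r2, r3])


class TestJackknife:
    def test_reduces_to_mean_and_sem_without_sign(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(32) + 5.0
        est, err = jackknife_ratio(x, np.ones(32))
        assert est == pytest.approx(x.mean(), rel=1e-12)
        assert err == pytest.approx(x.std(ddof=1) / math.sqrt(32), rel=1e-6)
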