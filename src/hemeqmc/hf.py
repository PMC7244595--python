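"""Hirsch-Fye determinantal QMC for the multi-orbital Anderson model.

Every density-density interaction pair (45 of them for five orbitals)
carries one discrete Ising Hubbard-Stratonovich field per time slice.
For a fixed field configuration the action is Gaussian, so the interacting
Green's function follows from the clean-update Dyson equation

    G(s) = [1 + (1 - g0)(e^{V(s)} - 1)]^{-1} g0   (<T c c+> convention)

with V(s) diagonal over (spin-orbital, time slice):  +lam_p s_{p,l} on
member a of pair p and -lam_p s_{p,l} on member b.  Single flips are
accepted from determinant ratios (scalar per spin block for opposite-spin
pairs, a 2x2 determinant for same-spin pairs) and applied as
Sherman-Morrison rank-1 updates; the configuration weight sign is tracked
and estimators are reweighted by it.

Host-state observables are never simulated directly: they are
reconstructed from the impurity Green's function through the exact
embedding relation

    G_host = g_hi [g_ii^{-1} (G_ii - g_ii) g_ii^{-1}] g_ih  + g_hh

which keeps the QMC cost at O((n_orb L)^3) independent of host size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import (
    AndersonModel,
    BathGreenFunction,
    ImaginaryTimeGrid,
    InteractionPairTable,
    build_pair_table,
    compute_bath_g0,
)

__all__ = [
    "HSFieldConfiguration",
    "QMCResult",
    "green_from_fields",
    "propose_flip",
    "sweep",
    "run_qmc",
    "extrapolate_dtau",
    "quadratic_extrapolate",
    "enumerate_fields",
]


# ---------------------------------------------------------------------------
# field configurations
# ---------------------------------------------------------------------------

@dataclass
class HSFieldConfiguration:
    """Ising auxiliary fields s_{p,l} = +-1, one per interaction pair per slice."""

    fields: np.ndarray  # (n_pairs, L) int8
    seed: int | None = None

    def __post_init__(self):
        f = np.asarray(self.fields, dtype=np.int8)
        if f.ndim != 2:
            raise ValueError("fields must be 2-D (n_pairs, L)")
        if not np.all(np.abs(f) == 1):
            raise ValueError("fields must be strictly +-1")
        self.fields = f

    @classmethod
    def random(cls, n_pairs: int, L: int, rng: np.random.Generator,
               seed: int | None = None) -> "HSFieldConfiguration":
        f = (rng.integers(0, 2, size=(n_pairs, L)) * 2 - 1).astype(np.int8)
        return cls(fields=f, seed=seed)


# ---------------------------------------------------------------------------
# clean (from-scratch) Green's function
# ---------------------------------------------------------------------------

def _field_potential(fields: np.ndarray, table: InteractionPairTable,
                     L: int, n_orb: int) -> np.ndarray:
    """Diagonal V(s) per spin over the flattened (orbital, slice) index."""
    v = np.zeros((2, n_orb * L))
    for p in range(table.n_pairs):
        lam_s = table.lam[p] * fields[p]
        a0 = table.a_orb[p] * L
        b0 = table.b_orb[p] * L
        v[table.a_spin[p], a0:a0 + L] += lam_s
        v[table.b_spin[p], b0:b0 + L] -= lam_s
    return v


def green_from_fields(g0, fields, table: InteractionPairTable,
                      return_weight: bool = False):
    """Exact per-spin G for a fixed field configuration (no Monte Carlo error).

    Parameters
    ----------
    g0
        A :class:`BathGreenFunction` or its (n_orb L, n_orb L) matrix.
    fields
        (n_pairs, L) array of +-1 (or an :class:`HSFieldConfiguration`).
    return_weight
        Also return ``(sign, logdet)`` of the configuration weight
        prod_spin det[1 + (1-g0)(e^V - 1)].
    """
    if isinstance(g0, BathGreenFunction):
        g0 = g0.g0
    if isinstance(fields, HSFieldConfiguration):
        fields = fields.fields
    fields = np.asarray(fields)
    n_pairs, L = fields.shape
    nL = g0.shape[0]
    n_orb = nL // L
    if n_orb * L != nL:
        raise ValueError("g0 size incompatible with number of slices")
    v = _field_potential(fields, table, L, n_orb)
    G = np.empty((2, nL, nL))
    sign, logdet = 1.0, 0.0
    eye = np.eye(nL)
    for s in (0, 1):
        e = np.expm1(v[s])
        # note the + sign: with the g = -<T c c+> storage convention the
        # textbook (1 - g0) factor becomes (1 + g0)
        A = eye + (eye + g0) * e[np.newaxis, :]
        try:
            G[s] = np.linalg.solve(A, g0)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"singular Dyson matrix (pathological lam*L?); "
                f"dtau={table.dtau}, max|v|={np.abs(v).max():.3f}"
            ) from exc
        if return_weight:
            sg, ld = np.linalg.slogdet(A)
            sign *= sg
            logdet += ld
    if return_weight:
        return G, sign, logdet
    return G


# ---------------------------------------------------------------------------
# single-flip ratios and updates
# ---------------------------------------------------------------------------

def _flip_gammas(table: InteractionPairTable, s: int, p: int):
    """exp-changes (gamma_a, gamma_b) for flipping s -> -s on pair p."""
    la = table.lam[p]
    return math.expm1(-2.0 * la * s), math.expm1(2.0 * la * s)


def propose_flip(G: np.ndarray, fields, table: InteractionPairTable,
                 p: int, l: int):
    """Determinant ratio R for flipping field (p, l), plus an apply closure.

    R may be negative; the caller multiplies its sign into the sign
    tracker.  ``apply()`` performs the Sherman-Morrison updates on G and
    flips the field in place.
    """
    if isinstance(fields, HSFieldConfiguration):
        fields = fields.fields
    L = fields.shape[1]
    s = int(fields[p, l])
    ga, gb = _flip_gammas(table, s, p)
    ia = int(table.a_orb[p]) * L + l
    ib = int(table.b_orb[p]) * L + l
    sa, sb = int(table.a_spin[p]), int(table.b_spin[p])
    if sa != sb:
        Ra = 1.0 + (1.0 + G[sa, ia, ia]) * ga
        Rb = 1.0 + (1.0 + G[sb, ib, ib]) * gb
        R = Ra * Rb
    else:
        Gs = G[sa]
        d11 = 1.0 + (1.0 + Gs[ia, ia]) * ga
        d22 = 1.0 + (1.0 + Gs[ib, ib]) * gb
        R = d11 * d22 - (Gs[ia, ib] * gb) * (Gs[ib, ia] * ga)

    def apply():
        if sa != sb:
            _rank1_py(G[sa], ia, ga)
            _rank1_py(G[sb], ib, gb)
        else:
            _rank1_py(G[sa], ia, ga)
            _rank1_py(G[sa], ib, gb)
        fields[p, l] = -s

    return R, apply


def _rank1_py(G: np.ndarray, i: int, gamma: float) -> None:
    """G <- G - (G[:,i] + e_i) gamma/r  outer  G[i,:], r = 1 + (1+G_ii) gamma."""
    r = 1.0 + (1.0 + G[i, i]) * gamma
    col = G[:, i].copy()
    col[i] += 1.0
    G -= np.outer(col * (gamma / r), G[i, :])


# ---------------------------------------------------------------------------
# numba sweep kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rank1_nb(G, i, gamma):  # pragma: no cover - exercised via kernel
    n = G.shape[0]
    r = 1.0 + (1.0 + G[i, i]) * gamma
    gi = G[i, :].copy()
    col = G[:, i].copy()
    col[i] += 1.0
    coef = -gamma / r
    for x in range(n):
        cx = coef * col[x]
        if cx != 0.0:
            for y in range(n):
                G[x, y] += cx * gi[y]


@njit(cache=True)
def _sweep_kernel(G, fields, a_base, a_spin, b_base, b_spin, lam,
                  order, unif, heatbath, sign):  # pragma: no cover
    n_pairs, L = fields.shape
    nacc = 0
    u = 0
    for oi in range(n_pairs):
        p = order[oi]
        la = lam[p]
        for l in range(L):
            s = fields[p, l]
            ga = math.expm1(-2.0 * la * s)
            gb = math.expm1(2.0 * la * s)
            ia = a_base[p] + l
            ib = b_base[p] + l
            sa = a_spin[p]
            sb = b_spin[p]
            if sa != sb:
                R = ((1.0 + (1.0 + G[sa, ia, ia]) * ga)
                     * (1.0 + (1.0 + G[sb, ib, ib]) * gb))
            else:
                d11 = 1.0 + (1.0 + G[sa, ia, ia]) * ga
                d22 = 1.0 + (1.0 + G[sa, ib, ib]) * gb
                R = d11 * d22 - (G[sa, ia, ib] * gb) * (G[sa, ib, ia] * ga)
            aR = abs(R)
            if heatbath:
                prob = aR / (1.0 + aR)
            else:
                prob = aR if aR < 1.0 else 1.0
            if unif[u] < prob:
                _rank1_nb(G[sa], ia, ga)
                _rank1_nb(G[sb], ib, gb)
                fields[p, l] = -s
                nacc += 1
                if R < 0.0:
                    sign = -sign
            u += 1
    return nacc, sign


def sweep(G: np.ndarray, fields, table: InteractionPairTable,
          rng: np.random.Generator, acceptance: str = "heatbath",
          sweep_order: str = "sequential", sign: float = 1.0):
    """One pass over all n_pairs x L fields with in-place fast updates.

    Returns ``(n_accepted, sign)``; G and fields are modified in place.
    """
    if isinstance(fields, HSFieldConfiguration):
        fields = fields.fields
    n_pairs, L = fields.shape
    order = (np.arange(n_pairs) if sweep_order == "sequential"
             else rng.permutation(n_pairs))
    unif = rng.random(n_pairs * L)
    nacc, sign = _sweep_kernel(
        G, fields,
        (table.a_orb * L).astype(np.int64), table.a_spin.astype(np.int64),
        (table.b_orb * L).astype(np.int64), table.b_spin.astype(np.int64),
        table.lam, order.astype(np.int64), unif,
        acceptance == "heatbath", float(sign),
    )
    return nacc, sign


# ---------------------------------------------------------------------------
# measurements (per-configuration Wick's theorem)
# ---------------------------------------------------------------------------

def _embedding_T(Gs: np.ndarray, g_ii: np.ndarray) -> np.ndarray:
    """T-matrix g_ii^{-1} (G - g_ii) g_ii^{-1} of the fixed-field problem."""
    X = np.linalg.solve(g_ii, Gs - g_ii)
    return np.linalg.solve(g_ii.T, X.T).T


def _measure(G: np.ndarray, bath: BathGreenFunction,
             table: InteractionPairTable, tau_resolved: bool = False) -> dict:
    """Equal-time estimators for one field configuration (before sign reweighting).

    Returns impurity occupations, per-pair densities, the full site-resolved
    moment-correlation matrix <M_z,p M_z,q> (mu_B^2), the total <M_z^2> and
    optionally the tau-resolved total-moment correlation function.
    """
    L = bath.grid.L
    no, nh, N = bath.n_orb, bath.n_host, bath.n_sites
    g_ii = bath.block("ii")
    g_eq = bath.equal_time_full()

    # per-spin full equal-time Green blocks F[s, l, p, q] = G_full[(p,l),(q,l)]
    F = np.empty((2, L, N, N))
    if nh > 0:
        g_fi = bath.block("fi").reshape(N, L, no * L)
        g_if = bath.block("if").reshape(no * L, N, L)
        for s in (0, 1):
            T = _embedding_T(G[s], g_ii)
            C = np.einsum("plk,km->plm", g_fi, T)   # (N, L, nL)
            F[s] = g_eq[np.newaxis] + np.einsum("plk,kql->lpq", C, g_if)
    else:
        # no hosts: F comes straight from the impurity matrix
        for s in (0, 1):
            Gr = G[s].reshape(no, L, no, L)
            F[s] = np.einsum("plql->lpq", Gr)

    n_full = 1.0 + np.einsum("slpp->slp", F)        # (2, L, N)
    m_site = n_full[0] - n_full[1]                  # (L, N) per slice

    # site-resolved moment correlations, slice averaged
    corr = np.einsum("lp,lq->pq", m_site, m_site)
    corr -= np.einsum("slpq,slqp->pq", F, F)
    diag = (n_full[0] + n_full[1] - 2.0 * n_full[0] * n_full[1]).sum(axis=0)
    np.fill_diagonal(corr, diag)
    corr /= L

    # impurity occupations and per-pair densities
    occ = n_full[:, :, nh:].mean(axis=1).T          # (n_orb, 2)
    ia = nh + table.a_orb
    ib = nh + table.b_orb
    na = n_full[table.a_spin, :, ia]                # (n_pairs, L)
    nb = n_full[table.b_spin, :, ib]
    pair = na * nb
    same = table.a_spin == table.b_spin
    if np.any(same):
        Fa = F[table.a_spin[same], :, ia[same], :]  # (n_same, L, N)
        cross = (np.take_along_axis(Fa, ib[same][:, None, None], axis=2)[..., 0]
                 * np.take_along_axis(
                     F[table.b_spin[same], :, ib[same], :],
                     ia[same][:, None, None], axis=2)[..., 0])
        pair[same] -= cross
    pair = pair.mean(axis=1)

    out = {
        "occ": occ,
        "pair_density": pair,
        "site_moment_corr": corr,
        "m2_total": float(corr.sum()),
        "N_total": float(n_full.sum() / L),
    }
    if tau_resolved:
        out["tau_corr"] = _tau_corr(F, G, bath, m_site, corr)
    return out


def _tau_corr(F, G, bath: BathGreenFunction, m_site, corr_eq) -> np.ndarray:
    """<M_z,t(tau_i) M_z,t(0)> for i = 0..L-1 (one reference slice)."""
    L = bath.grid.L
    no, nh, N = bath.n_orb, bath.n_host, bath.n_sites
    mm = np.empty(L)
    mm[0] = float(corr_eq.sum())
    dtau = bath.grid.dtau
    Cs: list = [None, None]
    if nh > 0:
        g_fi = bath.block("fi").reshape(N, L, no * L)
        g_if = bath.block("if").reshape(no * L, N, L)
        for s_idx in (0, 1):
            T = _embedding_T(G[s_idx], bath.block("ii"))
            Cs[s_idx] = np.einsum("plk,km->plm", g_fi, T)
    for i in range(1, L):
        acc = float(m_site[i] @ m_site[0])
        for s_idx in (0, 1):
            if nh > 0:
                Fi0 = bath.g_tau(i * dtau) + Cs[s_idx][:, i, :] @ g_if[:, :, 0]
                F0i = bath.g_tau(-i * dtau) + Cs[s_idx][:, 0, :] @ g_if[:, :, i]
            else:
                Gr = G[s_idx].reshape(no, L, no, L)
                Fi0 = Gr[:, i, :, 0]
                F0i = Gr[:, 0, :, i]
            acc -= float(np.einsum("pq,qp->", Fi0, F0i))
        mm[i] = acc
    return mm


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife_ratio(num: np.ndarray, den: np.ndarray):
    """Delete-one jackknife for <O sgn>/<sgn> over bins.

    ``num`` has shape (B, ...) of per-bin means of O*sgn; ``den`` shape (B,).
    Returns (estimate, error) with the bin axis removed.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    B = den.size
    if B < 2:
        raise ValueError("need at least 2 bins for jackknife")
    Sn = num.sum(axis=0)
    Sd = den.sum()
    shape = (B,) + (1,) * (num.ndim - 1)
    theta = (Sn - num) / (Sd - den).reshape(shape)
    mean = theta.mean(axis=0)
    err = np.sqrt((B - 1) / B * ((theta - mean) ** 2).sum(axis=0))
    full = Sn / Sd
    # bias-corrected estimate
    est = B * full - (B - 1) * mean
    return est, err


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class QMCResult:
    """Sign-reweighted, jackknifed Hirsch-Fye estimators.

    All moments are in mu_B (g = 2), correlations in mu_B^2 and
    susceptibilities in mu_B^2/eV.  ``site_moment_corr`` covers all sites
    (hosts first, impurity orbitals last); impurity and Fe-host blocks are
    exposed as properties.
    """

    beta: float
    dtau: float
    L: int
    n_orb: int
    n_host: int
    occ: np.ndarray
    occ_err: np.ndarray
    pair_density: np.ndarray
    pair_density_err: np.ndarray
    site_moment_corr: np.ndarray
    site_moment_corr_err: np.ndarray
    m2_total: float
    m2_total_err: float
    chi_t: float
    chi_t_err: float
    total_N: float
    total_N_err: float
    sign: float
    sign_err: float
    acceptance_rate: float
    meta: dict = field(default_factory=dict)
    tau_corr: np.ndarray | None = None
    tau_corr_err: np.ndarray | None = None
    chi_t_tau: float | None = None
    chi_t_tau_err: float | None = None

    @property
    def imp_moment_corr(self) -> np.ndarray:
        """Equal-time <M_z,v M_z,v'> over impurity orbitals (mu_B^2)."""
        return self.site_moment_corr[self.n_host:, self.n_host:]

    @property
    def fe_host_corr(self) -> np.ndarray:
        """<M_z,Fe M_z,m> per host state; negative = antiferromagnetic."""
        return self.site_moment_corr[self.n_host:, :self.n_host].sum(axis=0)

    @property
    def fe_host_corr_err(self) -> np.ndarray:
        return np.sqrt(
            (self.site_moment_corr_err[self.n_host:, :self.n_host] ** 2).sum(axis=0))

    @property
    def site_moment_total_corr(self) -> np.ndarray:
        """<M_z,p M_z,t> per site (row sums of the correlation matrix)."""
        return self.site_moment_corr.sum(axis=1)

    @property
    def m_fe(self) -> float:
        """sqrt(<M_z,Fe^2>): instantaneous Fe moment in mu_B."""
        block = self.site_moment_corr[self.n_host:, self.n_host:]
        return float(np.sqrt(max(block.sum(), 0.0)))

    @property
    def m_t_instantaneous(self) -> float:
        """sqrt(<M_z,t^2>): instantaneous total moment in mu_B."""
        return float(np.sqrt(max(self.m2_total, 0.0)))

    def reliable(self, threshold: float = 0.05) -> bool:
        return abs(self.sign) >= threshold

    def to_frame(self):
        """Scalar observables as a tidy pandas DataFrame (value, error)."""
        import pandas as pd
        rows = []
        for v in range(self.n_orb):
            for s, sn in enumerate(("up", "dn")):
                rows.append((f"n[{v},{sn}]", self.occ[v, s], self.occ_err[v, s]))
        rows += [
            ("m2_total", self.m2_total, self.m2_total_err),
            ("chi_t", self.chi_t, self.chi_t_err),
            ("sign", self.sign, self.sign_err),
            ("acceptance_rate", self.acceptance_rate, 0.0),
        ]
        return pd.DataFrame(rows, columns=["observable", "value", "error"])


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

def run_qmc(model: AndersonModel, grid: ImaginaryTimeGrid,
            n_warmup: int = 200, n_sweeps: int = 2000, n_bins: int = 16,
            seed: int = 0, measure_interval: int = 1,
            acceptance: str = "heatbath", sweep_order: str = "sequential",
            clean_interval: int = 50, drift_tol: float = 1e-6,
            tau_resolved: bool = False) -> QMCResult:
    """Full Hirsch-Fye run: warmup, binned measurements, jackknife errors.

    Reproducible: the same (model, grid, seed, settings) give bit-identical
    results.  Estimators are reweighted by the configuration sign,
    <O> = <O sgn>/<sgn>, with errors from a delete-one jackknife over
    ``n_bins`` bins.  Results with |<sgn>| < 0.05 are flagged unreliable in
    ``meta['warnings']``.
    """
    if n_bins < 4:
        raise ValueError("need n_bins >= 4")
    if n_sweeps < n_bins * measure_interval:
        raise ValueError("n_sweeps too small for the requested binning")
    grid.check_trotter(model)
    table = build_pair_table(model, grid)
    bath = compute_bath_g0(model, grid,
                           impurity_shift=table.hartree_shift(model.n_orb))
    rng = np.random.default_rng(seed)
    cfg = HSFieldConfiguration.random(table.n_pairs, grid.L, rng, seed=seed)
    G, sign, _ = green_from_fields(bath, cfg, table, return_weight=True)

    warns: list[str] = []
    max_drift = 0.0
    n_acc = 0
    n_prop = 0

    def do_sweeps(k: int, sgn: float) -> float:
        nonlocal n_acc, n_prop, max_drift, G
        for i in range(k):
            acc, sgn = sweep(G, cfg.fields, table, rng, acceptance,
                             sweep_order, sgn)
            n_acc += acc
            n_prop += table.n_pairs * grid.L
        return sgn

    # warmup with periodic clean rebuilds
    done = 0
    while done < n_warmup:
        step = min(clean_interval, n_warmup - done)
        sign = do_sweeps(step, sign)
        done += step
        G, sign, d = _clean_rebuild(G, bath, cfg, table, warns, drift_tol)
        max_drift = max(max_drift, d)

    # measurement phase
    sweeps_per_bin = n_sweeps // n_bins
    bin_num: dict[str, list] = {}
    bin_den: list[float] = []
    tau_keys = ("tau_corr",) if tau_resolved else ()
    since_clean = 0
    for b in range(n_bins):
        acc_num: dict[str, np.ndarray] = {}
        acc_den = 0.0
        count = 0
        for i in range(sweeps_per_bin):
            sign = do_sweeps(1, sign)
            since_clean += 1
            if since_clean >= clean_interval:
                G, sign, d = _clean_rebuild(G, bath, cfg, table, warns,
                                            drift_tol)
                max_drift = max(max_drift, d)
                since_clean = 0
            if (i + 1) % measure_interval:
                continue
            m = _measure(G, bath, table, tau_resolved=tau_resolved)
            for k in (("occ", "pair_density", "site_moment_corr", "N_total")
                      + tau_keys):
                acc_num[k] = acc_num.get(k, 0.0) + sign * m[k]
            acc_den += sign
            count += 1
        for k, v in acc_num.items():
            bin_num.setdefault(k, []).append(v / count)
        bin_den.append(acc_den / count)

    den = np.array(bin_den)
    est: dict[str, np.ndarray] = {}
    err: dict[str, np.ndarray] = {}
    for k, v in bin_num.items():
        est[k], err[k] = jackknife_ratio(np.array(v), den)
    m2_bins = np.array([c.sum() for c in bin_num["site_moment_corr"]])
    m2, m2_err = jackknife_ratio(m2_bins, den)
    sgn_mean = den.mean()
    sgn_err = den.std(ddof=1) / math.sqrt(n_bins)
    if abs(sgn_mean) < 0.05:
        warns.append(f"average sign {sgn_mean:.3f} < 0.05: result unreliable")

    result = QMCResult(
        beta=grid.beta, dtau=grid.dtau, L=grid.L,
        n_orb=model.n_orb, n_host=model.n_host,
        occ=est["occ"], occ_err=err["occ"],
        pair_density=est["pair_density"], pair_density_err=err["pair_density"],
        site_moment_corr=est["site_moment_corr"],
        site_moment_corr_err=err["site_moment_corr"],
        m2_total=float(m2), m2_total_err=float(m2_err),
        chi_t=float(grid.beta * m2), chi_t_err=float(grid.beta * m2_err),
        total_N=float(est["N_total"]), total_N_err=float(err["N_total"]),
        sign=float(sgn_mean), sign_err=float(sgn_err),
        acceptance_rate=n_acc / max(n_prop, 1),
        meta={
            "seed": seed, "n_warmup": n_warmup, "n_sweeps": n_sweeps,
            "n_bins": n_bins, "measure_interval": measure_interval,
            "acceptance": acceptance, "sweep_order": sweep_order,
            "clean_interval": clean_interval, "max_drift": max_drift,
            "mu": model.mu, "warnings": warns,
        },
    )
    if tau_resolved:
        tc, tc_err = est["tau_corr"], err["tau_corr"]
        result.tau_corr = tc
        result.tau_corr_err = tc_err
        result.chi_t_tau = float(grid.dtau * tc.sum())
        result.chi_t_tau_err = float(grid.dtau * np.sqrt((tc_err ** 2).sum()))
    result.meta["max_drift"] = max_drift
    return result


def _clean_rebuild(G, bath, cfg, table, warns, drift_tol):
    """Recompute G from scratch; warn when the fast-update drift is large."""
    Gc, sign, _ = green_from_fields(bath, cfg, table, return_weight=True)
    drift = float(np.abs(G - Gc).max())
    if drift > drift_tol:
        warns.append(f"fast-update drift {drift:.2e} > {drift_tol:.0e}; "
                     "forced clean rebuild")
        warnings.warn(warns[-1], stacklevel=3)
    return Gc, sign, drift


# ---------------------------------------------------------------------------
# Trotter extrapolation
# ---------------------------------------------------------------------------

def quadratic_extrapolate(dtaus, values, errors=None):
    """Weighted LS fit O(dtau) = O0 + c dtau^2; returns (O0, O0_err, c).

    ``values`` may be (n_dtau,) or (n_dtau, ...); the fit is elementwise.
    """
    x = np.asarray(dtaus, dtype=float) ** 2
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 dtau values to extrapolate")
    flat = y.reshape(x.size, -1)
    if errors is None:
        wf = np.ones_like(flat)
    else:
        ef = np.asarray(errors, dtype=float).reshape(x.size, -1)
        ef = np.where(ef > 0, ef, np.nan)
        wf = 1.0 / ef ** 2
        wf[np.isnan(wf)] = np.nanmax(wf) if np.isfinite(np.nanmax(wf)) else 1.0
    O0 = np.empty(flat.shape[1])
    O0e = np.empty(flat.shape[1])
    c = np.empty(flat.shape[1])
    X = np.column_stack([np.ones_like(x), x])
    for j in range(flat.shape[1]):
        W = np.diag(wf[:, j])
        cov = np.linalg.inv(X.T @ W @ X)
        beta = cov @ X.T @ W @ flat[:, j]
        O0[j], c[j] = beta
        O0e[j] = math.sqrt(cov[0, 0])
    shape = y.shape[1:]
    return O0.reshape(shape) if shape else float(O0[0]), \
        O0e.reshape(shape) if shape else float(O0e[0]), \
        c.reshape(shape) if shape else float(c[0])


def extrapolate_dtau(results: list[QMCResult],
                     observables: tuple[str, ...] = ("occ", "pair_density",
                                                     "m2_total", "chi_t")) -> dict:
    """dtau -> 0 extrapolation of a set of runs at common physics.

    Returns {name: (value, error, curvature)} per requested observable.
    """
    if len(results) < 3:
        raise ValueError("need >= 3 results at different dtau")
    dtaus = np.array([r.dtau for r in results])
    if np.unique(dtaus).size < 3:
        raise ValueError("dtau values must be distinct")
    betas = {round(r.beta, 12) for r in results}
    if len(betas) != 1:
        raise ValueError("results are not at common physics (beta differs)")
    out = {}
    for name in observables:
        vals = np.array([np.asarray(getattr(r, name), dtype=float) for r in results])
        errs = np.array([np.asarray(getattr(r, name + "_err"), dtype=float)
                         for r in results])
        out[name] = quadratic_extrapolate(dtaus, vals, errs)
    return out


# ---------------------------------------------------------------------------
# exhaustive enumeration (small-lattice oracle)
# ---------------------------------------------------------------------------

def enumerate_fields(model: AndersonModel, grid: ImaginaryTimeGrid,
                     max_bits: int = 16) -> dict:
    """Exact sum over all 2^(n_pairs L) field configurations.

    The weighted average over determinants reproduces the thermal averages
    of the Trotterized model; it differs from ED only by the O(dtau^2)
    discretization error.  Intended for n_pairs*L <= ~12.
    """
    table = build_pair_table(model, grid)
    bits = table.n_pairs * grid.L
    if bits > max_bits:
        raise ValueError(f"2^{bits} configurations is too many to enumerate")
    bath = compute_bath_g0(model, grid,
                           impurity_shift=table.hartree_shift(model.n_orb))
    logws = []
    signs = []
    measures = []
    for idx in range(1 << bits):
        f = np.array([1 if (idx >> b) & 1 else -1 for b in range(bits)],
                     dtype=np.int8).reshape(table.n_pairs, grid.L)
        G, sgn, ld = green_from_fields(bath, f, table, return_weight=True)
        logws.append(ld)
        signs.append(sgn)
        measures.append(_measure(G, bath, table))
    logws = np.array(logws)
    w = np.array(signs) * np.exp(logws - logws.max())
    Z = w.sum()
    out: dict = {}
    for k in ("occ", "pair_density", "site_moment_corr", "m2_total"):
        acc = sum(wi * np.asarray(m[k], dtype=float)
                  for wi, m in zip(w, measures))
        out[k] = acc / Z
    out["chi_zz"] = grid.beta * out["m2_total"]
    out["avg_sign"] = float(np.sum(w) / np.abs(w).sum())
    return out
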