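"""Exact diagonalization of small Anderson clusters.

Ground truth for every QMC estimator.  The full Fock space of
n_sites = n_host + n_orb sites (4^n_sites states) is built with fermionic
signs and block-diagonalized by the conserved particle numbers (N_up,
N_down) — both are good quantum numbers because only density-density
interactions are kept (no spin-flip / pair-hopping).  Dense
diagonalization only: the size cap keeps this exact and simple.

An unblocked construction by explicit Jordan-Wigner/Kronecker operator
strings is retained as an independent cross-validation path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .constants import beta_from_temperature
from .model import AndersonModel, build_one_body_matrix

__all__ = [
    "FockSpectrum",
    "build_fock_hamiltonian",
    "thermal_expectation",
    "ed_observables",
    "dense_fock_hamiltonian",
]

MAX_SITES_DEFAULT = 6


@dataclass
class FockSpectrum:
    """Eigen-decomposition of the cluster Fock space, blocked by (N_up, N_dn).

    ``blocks`` maps (N_up, N_dn) -> (masks, eigvals, eigvecs) where ``masks``
    are the occupation-basis bitmasks of that block (bit a = site a up-spin,
    bit n_sites + a = site a down-spin).
    """

    n_sites: int
    n_host: int
    blocks: dict

    def iter_states(self):
        """Yield (energy, weights, masks) per block; weights are |psi|^2 columns."""
        for (nu, nd), (masks, evals, evecs) in self.blocks.items():
            yield nu, nd, masks, evals, evecs

    @property
    def ground_energy(self) -> float:
        return min(float(ev[0]) for _, ev, _ in self.blocks.values())


def _masks_for_block(n_sites: int, n_up: int, n_dn: int) -> np.ndarray:
    ups = [sum(1 << i for i in c) for c in combinations(range(n_sites), n_up)]
    dns = [sum(1 << (n_sites + i) for i in c)
           for c in combinations(range(n_sites), n_dn)]
    return np.array([u | d for u in ups for d in dns], dtype=np.int64)


def _fermi_sign(mask: int, a: int) -> int:
    """(-1)^(number of occupied modes below a)."""
    return 1 - 2 * (bin(mask & ((1 << a) - 1)).count("1") & 1)


def build_fock_hamiltonian(model: AndersonModel,
                           max_sites: int = MAX_SITES_DEFAULT) -> FockSpectrum:
    """Assemble and diagonalize H in the occupation basis, per (N_up, N_dn) block."""
    n = model.n_sites
    if n > max_sites:
        raise ValueError(
            f"cluster has {n} sites > cap {max_sites}; ED is meant for toy "
            "clusters — reduce the host count or raise max_sites explicitly"
        )
    h1 = build_one_body_matrix(model)
    nh = model.n_host
    # interacting (orbital-orbital) couplings on impurity sites
    blocks: dict = {}
    for n_up in range(n + 1):
        for n_dn in range(n + 1):
            masks = _masks_for_block(n, n_up, n_dn)
            index = {int(m): i for i, m in enumerate(masks)}
            dim = masks.size
            H = np.zeros((dim, dim))
            for i, m in enumerate(masks):
                m = int(m)
                # diagonal: one-body energies + interactions
                occ_up = [(m >> a) & 1 for a in range(n)]
                occ_dn = [(m >> (n + a)) & 1 for a in range(n)]
                e = sum(h1[a, a] * (occ_up[a] + occ_dn[a]) for a in range(n))
                for v in range(model.n_orb):
                    av = nh + v
                    e += model.U * occ_up[av] * occ_dn[av]
                    for vp in range(v):
                        avp = nh + vp
                        e += model.U_prime * (occ_up[av] * occ_dn[avp]
                                              + occ_dn[av] * occ_up[avp])
                        e += model.U_dprime * (occ_up[av] * occ_up[avp]
                                               + occ_dn[av] * occ_dn[avp])
                H[i, i] = e
                # hopping: host <-> impurity, both spins
                for s, base in ((0, 0), (1, n)):
                    for mhost in range(nh):
                        for v in range(model.n_orb):
                            a = base + mhost
                            b = base + nh + v
                            V = model.hybridization[mhost, v]
                            if V == 0.0:
                                continue
                            # c+_a c_b |m>
                            if (m >> b) & 1 and not (m >> a) & 1:
                                m2 = m & ~(1 << b)
                                sgn = _fermi_sign(m, b) * _fermi_sign(m2, a)
                                j = index[m2 | (1 << a)]
                                H[j, i] += V * sgn
                            # c+_b c_a |m>
                            if (m >> a) & 1 and not (m >> b) & 1:
                                m2 = m & ~(1 << a)
                                sgn = _fermi_sign(m, a) * _fermi_sign(m2, b)
                                j = index[m2 | (1 << b)]
                                H[j, i] += V * sgn
            evals, evecs = np.linalg.eigh(H)
            blocks[(n_up, n_dn)] = (masks, evals, evecs)
    return FockSpectrum(n_sites=n, n_host=nh, blocks=blocks)


# ---------------------------------------------------------------------------
# thermal averages
# ---------------------------------------------------------------------------

def thermal_expectation(spectrum: FockSpectrum, T: float, observable) -> float:
    """Tr[e^{-beta H} O] / Z with ground-energy shift for overflow safety.

    ``observable`` is a callable ``f(mask, n_sites) -> float`` evaluated on
    occupation-basis states (sufficient for every density-diagonal quantity:
    n, n*n, M_z products), or a dict mapping (N_up, N_dn) to a dense matrix
    in that block's basis for general operators.
    """
    beta = beta_from_temperature(T)
    e0 = spectrum.ground_energy
    Z = 0.0
    acc = 0.0
    for (nu, nd), (masks, evals, evecs) in spectrum.blocks.items():
        w = np.exp(-beta * (evals - e0))
        Z += w.sum()
        if callable(observable):
            diag = np.array([observable(int(m), spectrum.n_sites) for m in masks])
            acc += float(w @ ((evecs ** 2).T @ diag))
        else:
            O = observable.get((nu, nd))
            if O is None:
                continue
            acc += float(w @ np.einsum("ik,ij,jk->k", evecs, O, evecs))
    return acc / Z


def _occ(mask: int, a: int) -> int:
    return (mask >> a) & 1


def occupation(site: int, spin: int):
    """Diagonal observable n_{site,spin} (spin 0 = up, 1 = down)."""
    def f(mask, n_sites):
        return _occ(mask, site + spin * n_sites)
    return f


def double_occupancy(site: int):
    def f(mask, n_sites):
        return _occ(mask, site) * _occ(mask, site + n_sites)
    return f


def mz_product(site_a: int, site_b: int):
    """M_z,a * M_z,b in mu_B^2 (g = 2: M_z = n_up - n_down per site)."""
    def f(mask, n_sites):
        ma = _occ(mask, site_a) - _occ(mask, site_a + n_sites)
        mb = _occ(mask, site_b) - _occ(mask, site_b + n_sites)
        return ma * mb
    return f


def total_mz_squared():
    def f(mask, n_sites):
        m = sum(_occ(mask, a) - _occ(mask, a + n_sites) for a in range(n_sites))
        return m * m
    return f


def total_number():
    def f(mask, n_sites):
        return bin(mask).count("1")
    return f


def ed_observables(model: AndersonModel, T: float,
                   max_sites: int = MAX_SITES_DEFAULT,
                   spectrum: FockSpectrum | None = None) -> dict:
    """Exact thermal observables of a toy cluster.

    Returns a dict with per-spin-orbital impurity occupations ``n``
    (n_orb, 2), per-orbital double occupancies ``docc``, total electron
    number ``N``, site-resolved moment correlations ``site_moment_corr``
    (n_sites x n_sites, mu_B^2), total ``m2_total`` and the zz spin
    susceptibility ``chi_zz = beta <M_z^2>`` (M_z conserved, <M_z> = 0 at
    zero field) in mu_B^2/eV.
    """
    if spectrum is None:
        spectrum = build_fock_hamiltonian(model, max_sites)
    beta = beta_from_temperature(T)
    nh, no, ns = model.n_host, model.n_orb, model.n_sites
    n = np.array([[thermal_expectation(spectrum, T, occupation(nh + v, s))
                   for s in (0, 1)] for v in range(no)])
    docc = np.array([thermal_expectation(spectrum, T, double_occupancy(nh + v))
                     for v in range(no)])
    corr = np.zeros((ns, ns))
    for p in range(ns):
        for q in range(p, ns):
            c = thermal_expectation(spectrum, T, mz_product(p, q))
            corr[p, q] = corr[q, p] = c
    m2 = float(corr.sum())
    return {
        "n": n,
        "docc": docc,
        "N": thermal_expectation(spectrum, T, total_number()),
        "site_moment_corr": corr,
        "m2_total": m2,
        "chi_zz": beta * m2,
        "spectrum": spectrum,
    }


# ---------------------------------------------------------------------------
# independent dense (unblocked) construction for cross-validation
# ---------------------------------------------------------------------------

def dense_fock_hamiltonian(model: AndersonModel, max_sites: int = 4) -> np.ndarray:
    """Full 4^n dense H via explicit Jordan-Wigner operator strings.

    Deliberately a different construction path from the blocked builder.
    """
    n = model.n_sites
    if n > max_sites:
        raise ValueError(f"{n} sites exceeds dense-path cap {max_sites}")
    nmodes = 2 * n
    dim = 1 << nmodes
    id2 = np.eye(2)
    ann = np.array([[0.0, 1.0], [0.0, 0.0]])
    sz = np.array([[1.0, 0.0], [0.0, -1.0]])  # JW string factor

    def c_op(a: int) -> np.ndarray:
        ops = [sz] * a + [ann] + [id2] * (nmodes - a - 1)
        out = np.array([[1.0]])
        for o in ops:
            out = np.kron(out, o)
        return out

    cs = [c_op(a) for a in range(nmodes)]
    ns_ = [cs[a].T @ cs[a] for a in range(nmodes)]
    h1 = build_one_body_matrix(model)
    H = np.zeros((dim, dim))
    for s, base in ((0, 0), (1, n)):
        for a in range(n):
            H += h1[a, a] * ns_[base + a]
            for b in range(a):
                if h1[a, b] != 0.0:
                    hop = cs[base + a].T @ cs[base + b]
                    H += h1[a, b] * (hop + hop.T)
    nh = model.n_host
    for v in range(model.n_orb):
        av = nh + v
        H += model.U * ns_[av] @ ns_[n + av]
        for vp in range(v):
            avp = nh + vp
            H += model.U_prime * (ns_[av] @ ns_[n + avp] + ns_[n + av] @ ns_[avp])
            H += model.U_dprime * (ns_[av] @ ns_[avp] + ns_[n + av] @ ns_[n + avp])
    return H
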