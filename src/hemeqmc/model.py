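"""Multi-orbital Anderson impurity model and its noninteracting propagators.

The model describes a handful of correlated impurity orbitals (the Fe(3d)
shell of a heme group) hybridized with a set of noninteracting host
molecular-orbital levels.  Its Hamiltonian is

    H = sum_{m,s} (eps_m - mu) c+_ms c_ms
      + sum_{v,s} (eps_dv - mu) d+_vs d_vs
      + sum_{m,v,s} V_mv (c+_ms d_vs + d+_vs c_ms)
      + sum_v U n_v+ n_v-
      + sum_{v>v',s} [ U' n_vs n_v'-s + (U'-J) n_vs n_v's ]

with U' = U - 2J (free-atom relation) and only the longitudinal
(density-density) part of the Hund exchange J: spin-flip and pair-hopping
terms are excluded, so total S_z is conserved.

The host levels are taken as already diagonal (they come from a one-particle
eigenbasis), so the one-body matrix has arrowhead structure.  Hybridizations
are real.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

import numpy as np

from .constants import K_B, beta_from_temperature

__all__ = [
    "AndersonModel",
    "ImaginaryTimeGrid",
    "InteractionPairTable",
    "BathGreenFunction",
    "build_one_body_matrix",
    "compute_bath_g0",
    "noninteracting_density",
    "build_pair_table",
    "n_interaction_pairs",
]

D_ORBITAL_LABELS = ("xy", "xz", "yz", "z2", "x2y2")


class ConfigurationError(ValueError):
    """Inconsistent model or grid specification."""


@dataclass(frozen=True)
class AndersonModel:
    """Parameters of the multi-orbital Anderson impurity model (all in eV).

    Parameters
    ----------
    host_energies
        Host level energies ``eps_m``.
    impurity_energies
        Impurity (Fe 3d) level energies ``eps_dv``; length 5 for heme but
        any length >= 1 is allowed.
    hybridization
        Matrix ``V[m, v]`` with one row per host state and one column per
        impurity orbital.
    U, J
        Intra-orbital Coulomb repulsion and (longitudinal) Hund coupling.
        The inter-orbital couplings follow as U' = U - 2J (opposite spins)
        and U'' = U' - J (parallel spins).
    mu
        Chemical potential; the grand-canonical one-body energies are
        ``eps - mu``.
    n_target
        Target total electron number used by chemical-potential tuning
        (optional).
    """

    host_energies: np.ndarray
    impurity_energies: np.ndarray
    hybridization: np.ndarray
    U: float
    J: float
    mu: float = 0.0
    n_target: float | None = None
    host_labels: tuple[str, ...] | None = None
    orbital_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        eh = np.atleast_1d(np.asarray(self.host_energies, dtype=float))
        ed = np.atleast_1d(np.asarray(self.impurity_energies, dtype=float))
        V = np.atleast_2d(np.asarray(self.hybridization, dtype=float))
        object.__setattr__(self, "host_energies", eh)
        object.__setattr__(self, "impurity_energies", ed)
        object.__setattr__(self, "hybridization", V)
        if V.shape != (eh.size, ed.size):
            raise ConfigurationError(
                f"hybridization shape {V.shape} does not match "
                f"(n_host, n_orb) = ({eh.size}, {ed.size})"
            )
        for name, arr in (("host_energies", eh), ("impurity_energies", ed),
                          ("hybridization", V)):
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name} contains non-finite entries")
        if not (np.isfinite(self.U) and np.isfinite(self.J) and np.isfinite(self.mu)):
            raise ConfigurationError("U, J, mu must be finite")
        if self.U < 0:
            raise ConfigurationError(f"U must be >= 0, got {self.U}")
        if not (0.0 <= self.J <= self.U / 2 + 1e-12):
            raise ConfigurationError(
                f"J must satisfy 0 <= J <= U/2 (got J={self.J}, U={self.U})"
            )
        if self.U - 3 * self.J < -1e-12:
            warnings.warn(
                f"U'' = U - 3J = {self.U - 3 * self.J:.4g} eV is negative; "
                "the parallel-spin channel is attractive and the discrete "
                "decoupling will refuse it",
                stacklevel=2,
            )
        if self.host_labels is not None and len(self.host_labels) != eh.size:
            raise ConfigurationError("host_labels length mismatch")
        if self.orbital_labels is not None and len(self.orbital_labels) != ed.size:
            raise ConfigurationError("orbital_labels length mismatch")

    # -- derived couplings -------------------------------------------------
    @property
    def U_prime(self) -> float:
        """Inter-orbital, opposite-spin Coulomb U' = U - 2J."""
        return self.U - 2 * self.J

    @property
    def U_dprime(self) -> float:
        """Inter-orbital, parallel-spin Coulomb U'' = U' - J = U - 3J."""
        return self.U - 3 * self.J

    @property
    def n_host(self) -> int:
        return self.host_energies.size

    @property
    def n_orb(self) -> int:
        return self.impurity_energies.size

    @property
    def n_sites(self) -> int:
        return self.n_host + self.n_orb

    def with_mu(self, mu: float) -> "AndersonModel":
        """Copy of the model at a different chemical potential."""
        return _dc_replace(self, mu=mu)

    def orbital_label(self, v: int) -> str:
        if self.orbital_labels is not None:
            return self.orbital_labels[v]
        if self.n_orb == 5:
            return D_ORBITAL_LABELS[v]
        return f"d{v}"


@dataclass(frozen=True)
class ImaginaryTimeGrid:
    """Uniform imaginary-time discretization tau_l = l * dtau, l = 0..L-1."""

    beta: float
    L: int

    def __post_init__(self):
        if self.L < 2:
            raise ConfigurationError(f"need at least 2 time slices, got {self.L}")
        if self.beta <= 0:
            raise ConfigurationError(f"beta must be positive, got {self.beta}")

    @property
    def dtau(self) -> float:
        return self.beta / self.L

    @property
    def temperature(self) -> float:
        return 1.0 / (K_B * self.beta)

    @classmethod
    def from_temperature(cls, T: float, L: int | None = None,
                         dtau: float | None = None) -> "ImaginaryTimeGrid":
        """Grid at temperature ``T`` (kelvin), given either L or dtau.

        When ``dtau`` is given, L is rounded up so that L*dtau = beta holds
        exactly with an actual dtau <= the requested one.
        """
        beta = beta_from_temperature(T)
        if (L is None) == (dtau is None):
            raise ConfigurationError("specify exactly one of L, dtau")
        if L is None:
            L = max(2, math.ceil(beta / dtau))
        return cls(beta=beta, L=int(L))

    def check_trotter(self, model: AndersonModel) -> None:
        wmax = max(model.U, abs(model.U_prime), abs(model.U_dprime))
        if self.dtau * wmax > 0.5:
            warnings.warn(
                f"dtau*max(U,U',U'') = {self.dtau * wmax:.3f} > 0.5; "
                "Trotter error may be large, consider more slices",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# one-body problem
# ---------------------------------------------------------------------------

def build_one_body_matrix(model: AndersonModel,
                          impurity_shift: np.ndarray | float = 0.0) -> np.ndarray:
    """Arrowhead one-body matrix of size (n_host + n_orb).

    Diagonal: host energies then impurity energies, both measured from mu;
    off-diagonal: the host-impurity hybridization block.  ``impurity_shift``
    is an optional extra diagonal term on the impurity orbitals (used for
    the Hartree shift of the auxiliary-field decoupling).
    """
    nh, no = model.n_host, model.n_orb
    H = np.zeros((nh + no, nh + no))
    H[np.arange(nh), np.arange(nh)] = model.host_energies - model.mu
    H[nh + np.arange(no), nh + np.arange(no)] = (
        model.impurity_energies - model.mu + np.asarray(impurity_shift, dtype=float)
    )
    H[:nh, nh:] = model.hybridization
    H[nh:, :nh] = model.hybridization.T
    return H


def _fermi(E: np.ndarray, beta: float) -> np.ndarray:
    """Fermi function, overflow-safe."""
    E = np.asarray(E, dtype=float)
    out = np.empty_like(E)
    pos = E >= 0
    out[pos] = np.exp(-beta * E[pos]) / (1.0 + np.exp(-beta * E[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(beta * E[~pos]))
    return out


def noninteracting_density(model: AndersonModel, T: float) -> tuple[np.ndarray, float]:
    """Per-spin site occupations and the total electron number at U = J = 0.

    Returns ``(n, N)`` where ``n[a]`` is the occupation per spin of site ``a``
    (hosts first, then impurity orbitals) and ``N = 2 * sum(n)``.
    """
    beta = beta_from_temperature(T)
    E, C = np.linalg.eigh(build_one_body_matrix(model))
    f = _fermi(E, beta)
    n = (C ** 2) @ f
    return n, 2.0 * float(f.sum())


# ---------------------------------------------------------------------------
# bath (noninteracting) Green's function
# ---------------------------------------------------------------------------

def _g_blocks(E: np.ndarray, C: np.ndarray, beta: float, taus: np.ndarray,
              rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """g_ab(tau) for a in rows, b in cols, for each tau in ``taus``.

    Convention g_ab(tau) = -<T c_a(tau) c_b+(0)>; tau = 0 means 0+.
    tau may lie in (-beta, beta).  Overflow-safe: exponentials are always
    evaluated with non-positive arguments.
    """
    out = np.empty((taus.size, rows.size, cols.size))
    Cr = C[rows, :]
    Cc = C[cols, :]
    for i, tau in enumerate(taus):
        if tau >= 0:
            # -e^{-tau E} (1 - f(E)); for E>=0: e^{-tau E}/(1+e^{-beta E})
            #              for E<0 : e^{(beta-tau)E} ... kept <= 0 exponents
            w = np.where(
                E >= 0,
                -np.exp(-tau * E) / (1.0 + np.exp(-beta * E)),
                -np.exp((beta - tau) * E) / (np.exp(beta * E) + 1.0),
            )
        else:
            # +e^{-tau E} f(E); tau < 0 so -tau E has sign of E
            w = np.where(
                E >= 0,
                np.exp(-(tau + beta) * E) / (1.0 + np.exp(-beta * E)),
                np.exp(-tau * E) / (np.exp(beta * E) + 1.0),
            )
        out[i] = (Cr * w) @ Cc.T
    return out


@dataclass
class BathGreenFunction:
    """Imaginary-time bath propagator of the impurity block (per spin).

    ``g0`` is the (n_orb*L) x (n_orb*L) matrix G0[(v,i),(w,j)] =
    g_vw(tau_i - tau_j) with the flattened index ``v*L + i`` and equal times
    read as tau -> 0+.  It is spin-independent (zero field).  The object
    also carries the one-body eigenpairs so that host blocks needed by the
    embedding measurements can be built on demand.
    """

    grid: ImaginaryTimeGrid
    n_host: int
    n_orb: int
    eigvals: np.ndarray  # measured from mu
    eigvecs: np.ndarray
    g0: np.ndarray = field(repr=False)

    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_sites(self) -> int:
        return self.n_host + self.n_orb

    def g_tau(self, tau: float, rows=None, cols=None) -> np.ndarray:
        """g_ab(tau) for tau in (-beta, beta); tau = 0 is read as 0+."""
        beta = self.grid.beta
        if not (-beta < tau < beta):
            raise ValueError(f"tau must lie in (-beta, beta), got {tau}")
        rows = np.arange(self.n_sites) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_sites) if cols is None else np.asarray(cols)
        return _g_blocks(self.eigvals, self.eigvecs, beta,
                         np.array([tau]), rows, cols)[0]

    def _tau_diff_blocks(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """blocks[d] = g_rc((i-j)*dtau) for d = i-j in -(L-1)..(L-1)."""
        L, dtau = self.grid.L, self.grid.dtau
        ds = np.arange(-(L - 1), L)
        taus = ds * dtau  # d = 0 -> tau = 0 read as 0+
        return _g_blocks(self.eigvals, self.eigvecs, self.grid.beta,
                         taus, rows, cols)

    def _assemble(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Big matrix M[(a,i),(b,j)] = g_ab(tau_i - tau_j), index a*L+i."""
        L = self.grid.L
        blocks = self._tau_diff_blocks(rows, cols)  # (2L-1, nr, nc)
        nr, nc = rows.size, cols.size
        ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        d_idx = (ii - jj) + (L - 1)
        # out[(a,i),(b,j)] = blocks[d_idx[i,j], a, b]
        out = blocks[d_idx]                      # (L, L, nr, nc)
        out = out.transpose(2, 0, 3, 1)          # (nr, L, nc, L)
        return out.reshape(nr * L, nc * L)

    def block(self, kind: str) -> np.ndarray:
        """Cached big matrices: 'ii' (imp-imp), 'fi' (full-imp), 'if' (imp-full)."""
        if kind not in self._cache:
            imp = np.arange(self.n_host, self.n_sites)
            full = np.arange(self.n_sites)
            if kind == "ii":
                self._cache[kind] = self.g0
            elif kind == "fi":
                self._cache[kind] = self._assemble(full, imp)
            elif kind == "if":
                self._cache[kind] = self._assemble(imp, full)
            else:
                raise KeyError(kind)
        return self._cache[kind]

    def equal_time_full(self) -> np.ndarray:
        """g_ab(0+) over all sites (host + impurity)."""
        if "eq" not in self._cache:
            full = np.arange(self.n_sites)
            self._cache["eq"] = self.g_tau(0.0, full, full)
        return self._cache["eq"]


def compute_bath_g0(model: AndersonModel, grid: ImaginaryTimeGrid,
                    impurity_shift: np.ndarray | float = 0.0) -> BathGreenFunction:
    """Noninteracting impurity-block propagator with every host state kept.

    Folds all host levels into the impurity propagator exactly through the
    eigen-decomposition of the arrowhead one-body matrix:
    g_ab(tau>0) = -sum_k c_ak c_bk e^{-tau E_k} / (1 + e^{-beta E_k}).
    """
    H = build_one_body_matrix(model, impurity_shift)
    E, C = np.linalg.eigh(H)
    bath = BathGreenFunction(grid=grid, n_host=model.n_host, n_orb=model.n_orb,
                             eigvals=E, eigvecs=C, g0=np.empty(0))
    imp = np.arange(model.n_host, model.n_sites)
    bath.g0 = bath._assemble(imp, imp)
    return bath


# ---------------------------------------------------------------------------
# interaction pair table / discrete decoupling
# ---------------------------------------------------------------------------

def n_interaction_pairs(n_orb: int) -> int:
    """Number of density-density pairs: n + 2 n(n-1)."""
    return n_orb + 2 * n_orb * (n_orb - 1)


@dataclass(frozen=True)
class InteractionPairTable:
    """Density-density pairs and their discrete decoupling constants.

    One auxiliary Ising field decouples each pair (a, b) with coupling W:
    e^{-dtau W (n_a - 1/2)(n_b - 1/2)} = const * sum_{s=+-1}
    e^{lam s (n_a - n_b)}, cosh(lam) = e^{dtau W / 2}.  Members are stored
    as (orbital, spin) with spin 0 = up, 1 = down.
    """

    a_orb: np.ndarray
    a_spin: np.ndarray
    b_orb: np.ndarray
    b_spin: np.ndarray
    W: np.ndarray
    lam: np.ndarray
    dtau: float

    @property
    def n_pairs(self) -> int:
        return self.W.size

    def hartree_shift(self, n_orb: int) -> np.ndarray:
        """Per-spin-orbital one-body shift +1/2 sum_{pairs containing a} W.

        Rewriting U n_a n_b as W (n_a-1/2)(n_b-1/2) + W/2 (n_a+n_b) - W/4
        moves this shift into the one-body part; it is identical for both
        spins by construction, so a single per-orbital array is returned.
        """
        shift = np.zeros((n_orb, 2))
        for ao, asp, bo, bsp, w in zip(self.a_orb, self.a_spin,
                                       self.b_orb, self.b_spin, self.W):
            shift[ao, asp] += 0.5 * w
            shift[bo, bsp] += 0.5 * w
        if not np.allclose(shift[:, 0], shift[:, 1]):
            raise AssertionError("pair table lost spin symmetry")
        return shift[:, 0]


def build_pair_table(model: AndersonModel, grid: ImaginaryTimeGrid) -> InteractionPairTable:
    """Enumerate the 45 (for 5 orbitals) density-density pairs of the model.

    Channels: intra-orbital (v up, v down, U); inter-orbital opposite spin
    (v s, v' -s, U') and same spin (v s, v' s, U' - J) for v > v'.
    Refuses attractive channels (W < 0), which this real discrete
    decoupling cannot represent.
    """
    dtau = grid.dtau
    rows: list[tuple[int, int, int, int, float]] = []
    for v in range(model.n_orb):
        rows.append((v, 0, v, 1, model.U))
    for v in range(model.n_orb):
        for vp in range(v):
            for s in (0, 1):
                rows.append((v, s, vp, 1 - s, model.U_prime))
            for s in (0, 1):
                rows.append((v, s, vp, s, model.U_dprime))
    W = np.array([r[4] for r in rows], dtype=float)
    if np.any(W < -1e-12):
        raise ConfigurationError(
            "attractive density-density channel (W < 0); the Ising "
            "decoupling requires U - 3J >= 0"
        )
    W = np.clip(W, 0.0, None)
    lam = np.arccosh(np.exp(dtau * W / 2.0))
    return InteractionPairTable(
        a_orb=np.array([r[0] for r in rows]),
        a_spin=np.array([r[1] for r in rows]),
        b_orb=np.array([r[2] for r in rows]),
        b_spin=np.array([r[3] for r in rows]),
        W=W, lam=lam, dtau=dtau,
    )
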