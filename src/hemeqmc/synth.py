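"""Synthetic Anderson-model parameter sets with heme-like spectral structure.

The DFT-derived level energies and hybridizations of the real heme
clusters are not published, so these generators emulate their qualitative
structure: a broad host manifold of molecular-orbital levels, a bonding pi
level about 3 eV below the Fermi level, a nearly half-filled pi1* and a
nearly empty pi2* acceptor manifold of width about 0.3 eV, and — for the
oxy-like variant — an acceptor feature within 0.15 eV of the Fermi level
whose screening suppresses the total moment there.  Fe(3d) level positions
are calibrated by exact enumeration of the atomic (density-density)
interaction energies so that the d^6 configuration is charge-stable at
mu = 0, with a small crystal-field splitting for the high-spin deoxy-like
variant and a large one for the low-spin oxy-like variant.

Every generator is a pure function of its seed and spec.  None of this
attempts to match the real DFT spectrum quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .constants import K_B
from .model import AndersonModel, D_ORBITAL_LABELS
from .observables import SusceptibilityCurve

__all__ = [
    "HemeFixtureSpec",
    "make_toy_cluster",
    "make_heme_like",
    "make_curie_dataset",
    "atomic_level_calibration",
]


# ---------------------------------------------------------------------------
# toy clusters (ED-checkable)
# ---------------------------------------------------------------------------

def make_toy_cluster(n_orb: int = 1, n_host: int = 2, regime: str = "symmetric",
                     seed: int = 0, U: float = 2.0, J: float = 0.0,
                     V: float = 0.5, host_spread: float = 2.0) -> AndersonModel:
    """Small reproducible Anderson clusters for exact-diagonalization checks.

    regimes
        'symmetric' — particle-hole symmetric: eps_d at the half-filling
        point, host levels in +-e pairs with equal couplings;
        'kondo' — half-filled impurity plus a half-filled host level at the
        Fermi level with strong V (antiferromagnetic screening regime);
        'free' — U = J = 0.
    """
    rng = np.random.default_rng(seed)
    if regime == "free":
        U = J = 0.0
    # half-filling point of the density-density atom
    eps_half = -(U / 2.0 + (n_orb - 1) * (2 * (U - 2 * J) - J) / 2.0)
    if regime in ("symmetric", "free"):
        eh = []
        for i in range(n_host // 2):
            e = host_spread * (i + 1) / max(n_host // 2, 1)
            eh += [e, -e]
        if n_host % 2:
            eh.append(0.0)
        eh = np.array(sorted(eh))
        Vm = np.zeros((n_host, n_orb))
        for m in range(n_host):
            Vm[m, m % n_orb] = V
        if regime == "free":
            eh = eh + 0.05 * rng.standard_normal(n_host)
    elif regime == "kondo":
        eh = np.array([0.0] + [2.0 * (-1) ** i for i in range(n_host - 1)])
        Vm = np.zeros((n_host, n_orb))
        Vm[0, :] = max(V, 0.8)          # strong screening channel
        for m in range(1, n_host):
            Vm[m, m % n_orb] = 0.3
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return AndersonModel(
        host_energies=eh,
        impurity_energies=np.full(n_orb, eps_half),
        hybridization=Vm, U=U, J=J, mu=0.0,
        n_target=float(n_orb + 2 * int(np.sum(eh < 0)) + (n_host % 2)),
    )


# ---------------------------------------------------------------------------
# atomic-level calibration
# ---------------------------------------------------------------------------

def _atomic_energies(eps: np.ndarray, U: float, J: float) -> np.ndarray:
    """E_min(N) for N = 0..2*n_orb of the isolated density-density atom."""
    Up, Upp = U - 2 * J, U - 3 * J
    n_orb = eps.size
    best = np.full(2 * n_orb + 1, np.inf)
    for occ in product((0, 1), repeat=2 * n_orb):
        nu = np.array(occ[:n_orb])
        nd = np.array(occ[n_orb:])
        E = float(eps @ (nu + nd) + U * (nu @ nd))
        for v in range(n_orb):
            for w in range(v):
                E += Up * (nu[v] * nd[w] + nd[v] * nu[w])
                E += Upp * (nu[v] * nu[w] + nd[v] * nd[w])
        N = int(nu.sum() + nd.sum())
        if E < best[N]:
            best[N] = E
    return best


def atomic_level_calibration(pattern: np.ndarray, U: float, J: float,
                             n_d: int = 6) -> np.ndarray:
    """Shift a d-level pattern so the N = n_d atom is charge-stable at mu = 0.

    Returns eps such that the addition energies E(n_d+1)-E(n_d) and
    E(n_d)-E(n_d-1) are symmetric about zero (mid-gap at the Fermi level).
    """
    E = _atomic_energies(np.asarray(pattern, dtype=float), U, J)
    up = E[n_d + 1] - E[n_d]
    dn = E[n_d] - E[n_d - 1]
    return np.asarray(pattern, dtype=float) - 0.5 * (up + dn)


# ---------------------------------------------------------------------------
# heme-like fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemeFixtureSpec:
    """Recipe for a heme-like Anderson model (energies in eV).

    Special host states mirror the known porphyrin structure: a bonding pi
    level ~3 eV below the Fermi level, a nearly half-filled pi1* manifold
    at the Fermi level and a nearly empty pi2* manifold 0.3 eV above, each
    of width 0.3 eV; the oxy-like variant adds a strongly coupled acceptor
    state within 0.15 eV of the Fermi level.  The seed is mandatory — no
    implicit entropy.
    """

    variant: str = "deoxy-like"         # 'deoxy-like' | 'oxy-like' | 'toy'
    seed: int = 0
    n_host: int = 60
    window: tuple = (-25.0, 10.0)
    hyb_scale: float = 0.35
    hyb_decay: float = 3.0
    pi_coupling: float = 0.35
    pi1_coupling: float = 0.5
    pi2_coupling: float = 0.4
    acceptor_coupling: float = 1.6
    pi_energy: float = -3.0
    pi1_center: float = 0.0
    pi1_width: float = 0.3
    pi2_center: float = 0.3
    pi2_width: float = 0.3
    n_special: int = 3                  # states per special manifold
    acceptor_offset: float = 0.05       # oxy acceptor, within 0.15 eV of mu_F
    U: float = 4.0
    J: float = 0.9
    crystal_field: float | None = None  # default by variant
    n_carbon: int = 20
    n_nitrogen: int = 4

    def __post_init__(self):
        if self.variant not in ("deoxy-like", "oxy-like", "toy"):
            raise ValueError(f"unknown variant {self.variant!r}")
        lo, hi = self.window
        for e in (self.pi_energy, self.pi1_center, self.pi2_center):
            if not (lo < e < hi):
                raise ValueError(f"special-state energy {e} outside host window")
        if abs(self.acceptor_offset) > 0.15:
            raise ValueError("acceptor feature must lie within 0.15 eV of mu_F")


def make_heme_like(spec: HemeFixtureSpec):
    """Heme-like model plus a host-state -> atom projection matrix.

    Returns ``(model, projection, info)`` where ``projection`` is a pandas
    DataFrame (rows: host states then the five Fe(3d) orbitals; columns:
    atoms Fe, N1..N4, C1..C20[, O1, O2]; rows sum to 1) and ``info`` holds
    the state labels and calibration details.
    """
    import pandas as pd
    rng = np.random.default_rng(spec.seed)
    oxy = spec.variant == "oxy-like"
    lo, hi = spec.window

    # --- host manifold -----------------------------------------------------
    energies: list[float] = []
    labels: list[str] = []
    ns = spec.n_special
    for k in range(ns):
        energies.append(spec.pi_energy + 0.05 * rng.standard_normal())
        labels.append("pi")
    for e in np.linspace(spec.pi1_center - spec.pi1_width / 2,
                         spec.pi1_center + spec.pi1_width / 2, ns):
        energies.append(float(e))
        labels.append("pi1*")
    for e in np.linspace(spec.pi2_center - spec.pi2_width / 2,
                         spec.pi2_center + spec.pi2_width / 2, ns):
        energies.append(float(e))
        labels.append("pi2*")
    if oxy:
        energies.append(spec.acceptor_offset)
        labels.append("acceptor")
    n_generic = spec.n_host - len(energies)
    if n_generic < 0:
        raise ValueError("n_host too small for the special manifolds")
    grid = np.linspace(lo, hi, n_generic)
    jitter = 0.3 * (hi - lo) / max(n_generic, 1)
    for e in grid + jitter * rng.uniform(-1, 1, n_generic):
        energies.append(float(np.clip(e, lo, hi)))
        labels.append("host")
    energies = np.array(energies)
    labels = np.array(labels)

    # --- Fe(3d) levels ------------------------------------------------------
    cf = spec.crystal_field if spec.crystal_field is not None else (3.9 if oxy else 0.8)
    # orbital order: xy, xz, yz, z2, x2y2 — t2g first three
    pattern = np.array([0.0, 0.0, 0.0, cf, cf])
    eps_d = atomic_level_calibration(pattern, spec.U, spec.J, n_d=6)

    # --- hybridization -------------------------------------------------------
    V = (spec.hyb_scale * np.exp(-np.abs(energies) / spec.hyb_decay)[:, None]
         * rng.standard_normal((energies.size, 5)))
    pi_sym = np.array([0.0, 1.0, 1.0, 0.0, 0.0])      # xz, yz channels
    for i, lab in enumerate(labels):
        if lab == "pi":
            V[i] = spec.pi_coupling * pi_sym * np.sign(rng.standard_normal(5) + 1e-9)
        elif lab == "pi1*":
            V[i] = spec.pi1_coupling * pi_sym * np.sign(rng.standard_normal(5) + 1e-9)
        elif lab == "pi2*":
            V[i] = spec.pi2_coupling * pi_sym * np.sign(rng.standard_normal(5) + 1e-9)
        elif lab == "acceptor":
            # couples to the thermally active t2g channel: resonant screening
            V[i] = spec.acceptor_coupling * np.array([0.7, 0.7, 0.7, 0.0, 0.0])

    n_target = float(2 * int(np.sum(energies < 0.0)) + 6)
    model = AndersonModel(
        host_energies=energies, impurity_energies=eps_d, hybridization=V,
        U=spec.U, J=spec.J, mu=0.0, n_target=n_target,
        host_labels=tuple(labels), orbital_labels=D_ORBITAL_LABELS,
    )

    # --- projection onto atoms ----------------------------------------------
    atoms = (["Fe"] + [f"N{i+1}" for i in range(spec.n_nitrogen)]
             + [f"C{i+1}" for i in range(spec.n_carbon)]
             + (["O1", "O2"] if oxy else []))
    n_atoms = len(atoms)
    c0 = 1 + spec.n_nitrogen
    proj = np.zeros((energies.size + 5, n_atoms))
    for i, lab in enumerate(labels):
        if lab in ("pi", "pi1*", "pi2*"):
            # C(2p_z) character spread over the 20 carbons
            w = 1.0 + 0.3 * rng.uniform(-1, 1, spec.n_carbon)
            proj[i, c0:c0 + spec.n_carbon] = w / w.sum()
        elif lab == "acceptor":
            proj[i, -2:] = 0.35                      # O2-dominated
            proj[i, 1:1 + spec.n_nitrogen] = 0.3 / spec.n_nitrogen
        else:
            w = 1.0 + 0.5 * rng.uniform(-1, 1, spec.n_nitrogen + spec.n_carbon)
            proj[i, 1:c0 + spec.n_carbon] = w / w.sum()
    proj[energies.size:, 0] = 1.0                    # Fe(3d) rows -> Fe site
    state_labels = list(labels) + [f"Fe({o})" for o in D_ORBITAL_LABELS]
    projection = pd.DataFrame(proj, index=state_labels, columns=atoms)

    info = {
        "state_labels": state_labels,
        "crystal_field": cf,
        "eps_d": eps_d,
        "pi1_states": np.where(labels == "pi1*")[0],
        "pi2_states": np.where(labels == "pi2*")[0],
        "pi_states": np.where(labels == "pi")[0],
        "acceptor_states": np.where(labels == "acceptor")[0],
    }
    return model, projection, info


# ---------------------------------------------------------------------------
# Curie datasets
# ---------------------------------------------------------------------------

def make_curie_dataset(M_eff: float, T_list, noise: float = 0.0, seed: int = 0,
                       T_star: float | None = None,
                       M_eff_high: float | None = None) -> SusceptibilityCurve:
    """chi(T) = M_eff^2 / (3 k_B T) with optional noise and a crossover.

    With ``T_star`` and ``M_eff_high`` set, temperatures above T_star use
    the high-T moment — the two-regime shape seen in the oxy cluster.
    ``noise`` is the relative Gaussian noise level; the stored error bars
    are the exact noise widths, so fits can be tested against their
    generating parameters.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    T = np.asarray(T_list, dtype=float)
    M = np.full_like(T, float(M_eff))
    if T_star is not None:
        if M_eff_high is None:
            raise ValueError("two-regime dataset needs M_eff_high")
        M = np.where(T > T_star, M_eff_high, M_eff)
    chi = M ** 2 / (3.0 * K_B * T)
    err = None
    if noise > 0:
        err = noise * chi
        chi = chi + err * rng.standard_normal(T.size)
    return SusceptibilityCurve(
        T=T, chi=chi, err=err,
        provenance={"generator": "make_curie_dataset", "M_eff": M_eff,
                    "noise": noise, "seed": seed, "T_star": T_star,
                    "M_eff_high": M_eff_high},
    )
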