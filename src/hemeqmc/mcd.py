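"""Orbital-selective model for the anomalous UV MCD of deoxy-heme.

The UV absorption near 3 eV is the porphyrin pi -> pi* transition.  Two
partially occupied pi* bands matter: pi1* (nearly half-filled, spin
polarized parallel to an applied field through its antiferromagnetic
coupling to the large Fe moment) and pi2* (nearly empty, slightly higher).
Left-circularly polarized light feeds pi -> pi1*, right-circularly
polarized light feeds pi -> pi2*; the spin selection inherited from the
Fe-pi* antiferromagnetism makes the two bands enter the MCD difference
spectrum with opposite signs:

    dEps(E) = A p(T, B) [ (1 - f1) G(E; E_pi1, w1) - (1 - f2) G(E; E_pi2, w2) ]

with G a unit-area line shape and p a Curie-law (tanh) polarization — so
the spectrum rises first (peak) and then dips as the photon energy grows,
the reverse of the usual MCD ordering, and its amplitude scales as 1/T.
The pi* bands behave as if they had negative g-factors.  Band widths are
FWHM in eV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import K_B, MU_B_EV_PER_T

__all__ = [
    "MCDBandModel",
    "MCDSpectrum",
    "band_polarization",
    "mcd_spectrum",
    "classify_lineshape",
    "amplitude_vs_T",
]


@dataclass(frozen=True)
class MCDBandModel:
    """Two-band model for the UV MCD of a heme cluster (energies in eV).

    ``E_pi`` is the depth of the bonding pi level below the Fermi level;
    ``E1``/``E2`` place the pi1*/pi2* band centers relative to the Fermi
    level, so the optical transitions sit at ``E_pi + E1`` and
    ``E_pi + E2``.  Widths are FWHM.  ``coupling_sign = +1`` encodes the
    antiferromagnetic Fe-pi1* coupling of deoxy-heme (the anomalous case).
    """

    E_pi: float = 3.0
    E1: float = 0.0
    E2: float = 0.3
    w1: float = 0.3
    w2: float = 0.3
    f1: float = 0.5
    f2: float = 0.0
    A: float = 1.0
    coupling_sign: int = +1
    lineshape: str = "gaussian"

    def __post_init__(self):
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("band widths must be positive")
        if not (0 <= self.f1 <= 1 and 0 <= self.f2 <= 1):
            raise ValueError("band fillings must lie in [0, 1]")
        if self.E2 < self.E1:
            raise ValueError("pi2* must not lie below pi1* (E2 >= E1)")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")

    def default_grid(self, n: int = 601) -> np.ndarray:
        w = max(self.w1, self.w2)
        return np.linspace(self.E_pi + self.E1 - 3 * w,
                           self.E_pi + self.E2 + 3 * w, n)


@dataclass
class MCDSpectrum:
    """Energy grid (eV), MCD difference dEps and total absorption eps."""

    E: np.ndarray
    dEps: np.ndarray
    eps: np.ndarray
    T: float
    B: float
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"E_eV": self.E, "dEps": self.dEps, "eps": self.eps})


def band_polarization(T: float, B: float, coupling_sign: int = +1,
                      g_eff: float = 2.0) -> float:
    """Thermal spin polarization p = sign * tanh(g mu_B B / 2 k_B T).

    Linear in B/T in the Curie regime — this is the 1/T carrier of the MCD
    amplitude.  ``coupling_sign`` flips p for a band antiferromagnetically
    locked to the Fe moment (the effective negative g-factor of the pi*
    states).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return coupling_sign * math.tanh(g_eff * MU_B_EV_PER_T * B / (2 * K_B * T))


def _unit_line(E: np.ndarray, center: float, fwhm: float, kind: str) -> np.ndarray:
    if kind == "gaussian":
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return np.exp(-0.5 * ((E - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    gamma = fwhm / 2.0
    return (gamma / math.pi) / ((E - center) ** 2 + gamma ** 2)


def mcd_spectrum(model: MCDBandModel, T: float, B: float,
                 grid: np.ndarray | None = None,
                 polarization: float | None = None) -> MCDSpectrum:
    """MCD difference spectrum and (T-independent) total absorption.

    ``polarization`` overrides the thermal tanh factor, e.g. with a value
    derived from a QMC Fe-pi1* correlation, so the impurity solver can be
    chained into the optics.
    """
    E = model.default_grid() if grid is None else np.asarray(grid, dtype=float)
    p = (band_polarization(T, B, model.coupling_sign)
         if polarization is None else polarization)
    G1 = _unit_line(E, model.E_pi + model.E1, model.w1, model.lineshape)
    G2 = _unit_line(E, model.E_pi + model.E2, model.w2, model.lineshape)
    dEps = model.A * p * ((1 - model.f1) * G1 - (1 - model.f2) * G2)
    eps = model.A * ((1 - model.f1) * G1 + (1 - model.f2) * G2)
    return MCDSpectrum(E=E, dEps=dEps, eps=eps, T=T, B=B,
                       meta={"polarization": p, "model": model})


def classify_lineshape(spectrum: MCDSpectrum, tol: float = 1e-12,
                       rel_min: float = 0.05) -> str:
    """'anomalous' (peak then dip), 'normal' (dip then peak) or 'null'.

    Orders the significant extrema of dEps along increasing photon energy;
    extrema below ``rel_min`` of the global maximum magnitude are ignored.
    Invariant under overall amplitude scaling.
    """
    d = spectrum.dEps
    amax = float(np.abs(d).max(initial=0.0))
    if amax <= tol:
        return "null"
    dn = d / amax
    # local extrema of the sampled curve
    interior = np.arange(1, d.size - 1)
    is_max = (dn[interior] >= dn[interior - 1]) & (dn[interior] >= dn[interior + 1])
    is_min = (dn[interior] <= dn[interior - 1]) & (dn[interior] <= dn[interior + 1])
    signs = []
    for i in interior[(is_max | is_min)]:
        v = dn[i]
        if abs(v) < rel_min:
            continue
        s = 1 if v > 0 else -1
        if not signs or signs[-1] != s:
            signs.append(s)
    if not signs:
        return "null"
    return "anomalous" if signs[0] > 0 else "normal"


def amplitude_vs_T(model: MCDBandModel, B: float, T_list,
                   grid: np.ndarray | None = None):
    """Positive-peak amplitude of dEps per temperature: [(T, amplitude)].

    In the Curie regime the amplitude is proportional to 1/T.
    """
    out = []
    for T in T_list:
        sp = mcd_spectrum(model, T, B, grid)
        out.append((float(T), float(sp.dEps.max())))
    return out


def fit_amplitude_exponent(amplitudes) -> float:
    """Exponent alpha of amplitude ~ T^-alpha by log-log least squares."""
    T = np.array([t for t, _ in amplitudes])
    A = np.array([a for _, a in amplitudes])
    if np.any(A <= 0):
        raise ValueError("amplitudes must be positive for a log-log fit")
    slope = np.polyfit(np.log(T), np.log(A), 1)[0]
    return -float(slope)
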