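"""The anomalous UV MCD line shape of deoxy-heme.

Evaluates the two-band pi -> pi1*/pi2* model with its default deoxy
parameters, classifies the line shape, and fits the temperature exponent
of the peak amplitude.
"""

import numpy as np

from hemeqmc.mcd import (
    MCDBandModel,
    amplitude_vs_T,
    band_polarization,
    classify_lineshape,
    fit_amplitude_exponent,
    mcd_spectrum,
)

band = MCDBandModel()   # pi at -3 eV; pi1* half-filled, pi2* empty; 0.3 eV FWHM
sp = mcd_spectrum(band, T=150.0, B=1.0)
i_max, i_min = np.argmax(sp.dEps), np.argmin(sp.dEps)
print(f"band polarization p(150 K, 1 T) = {band_polarization(150.0, 1.0):.3e}")
print(f"positive peak at E = {sp.E[i_max]:.2f} eV, "
      f"dip at E = {sp.E[i_min]:.2f} eV")
print(f"classification: {classify_lineshape(sp)}")

flipped = mcd_spectrum(MCDBandModel(coupling_sign=-1), T=150.0, B=1.0)
print(f"with the Fe-pi1* coupling sign flipped: "
      f"{classify_lineshape(flipped)}")

amps = amplitude_vs_T(band, B=1.0, T_list=np.linspace(100.0, 400.0, 7))
alpha = fit_amplitude_exponent(amps)
for T, a in amps[::3]:
    print(f"T = {T:5.1f} K: peak amplitude {a:.3e}")
print(f"fitted amplitude exponent: T^-{alpha:.3f}")
print("\nPeak-before-dip ('anomalous') ordering is the optical fingerprint")
print("of the antiferromagnetic Fe-pi1* coupling — the pi* bands behave as")
print("if they had negative g-factors — and the 1/T amplitude is the Curie")
print("law of the polarized ground state.")
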