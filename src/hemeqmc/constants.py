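"""Physical constants and unit conventions.

Energies are in eV, temperatures in kelvin, inverse temperature beta in
1/eV, magnetic moments in Bohr magnetons (mu_B) with g = 2, so the z-moment
of one orbital is (n_up - n_down) mu_B and susceptibilities come out in
mu_B^2/eV.
"""

#: Boltzmann constant in eV/K.
K_B = 8.617333e-5

#: Bohr magneton in eV/T (used only by the MCD polarization factor).
MU_B_EV_PER_T = 5.7883818060e-5


def beta_from_temperature(T: float) -> float:
    """Inverse temperature (1/eV) for a temperature in kelvin."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return 1.0 / (K_B * T)


def temperature_from_beta(beta: float) -> float:
    """Temperature in kelvin for an inverse temperature in 1/eV."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return 1.0 / (K_B * beta)
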