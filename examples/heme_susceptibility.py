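"""Deoxy- versus oxy-like heme clusters: total spin susceptibility.

Generates the two synthetic five-orbital Fe(3d) + 60-host-state fixtures
and compares chi_t(T) at scaled-down (elevated) temperatures, where a
desk-scale run resolves the direction of the physics: the high-spin
deoxy-like cluster has the larger, near-Curie susceptibility; the
low-spin-leaning oxy-like cluster with its Fermi-level acceptor state is
systematically below it.
"""

import numpy as np

from hemeqmc import ImaginaryTimeGrid, run_qmc
from hemeqmc.observables import SusceptibilityCurve, curie_fit
from hemeqmc.synth import HemeFixtureSpec, make_heme_like

deoxy, _, dinfo = make_heme_like(HemeFixtureSpec(variant="deoxy-like", seed=7))
oxy, _, _ = make_heme_like(HemeFixtureSpec(variant="oxy-like", seed=7))

T_list = [3000.0, 4500.0, 6000.0]
chi = {"deoxy": [], "oxy": []}
err = {"deoxy": [], "oxy": []}
for i, T in enumerate(T_list):
    for name, model in (("deoxy", deoxy), ("oxy", oxy)):
        grid = ImaginaryTimeGrid.from_temperature(T, dtau=0.125)
        r = run_qmc(model, grid, n_warmup=150, n_sweeps=400, n_bins=8,
                    measure_interval=2, seed=40 + i)
        chi[name].append(r.chi_t)
        err[name].append(max(r.chi_t_err, 1e-12))
        extra = ""
        if name == "deoxy":
            fe_pi1 = r.fe_host_corr[dinfo["pi1_states"]].sum()
            extra = f"  <M_Fe M_pi1*> = {fe_pi1:+.3f} muB^2"
        print(f"{name:5s} T={T:5.0f} K: chi_t = {r.chi_t:6.2f} "
              f"+- {r.chi_t_err:.2f} muB^2/eV  M_Fe = {r.m_fe:.2f} muB{extra}")

fit = curie_fit(SusceptibilityCurve(T=np.array(T_list),
                                    chi=np.array(chi["deoxy"]),
                                    err=np.array(err["deoxy"])))
print(f"\ndeoxy Curie fit: M_eff = {fit.M_eff:.2f} muB "
      f"(reduced chi^2 = {fit.red_chi2:.2g})")
print(f"chi_oxy / chi_deoxy = "
      f"{np.mean(np.array(chi['oxy']) / np.array(chi['deoxy'])):.2f}")
print("\nNegative <M_Fe M_pi1*> is the antiferromagnetic Fe-porphyrin")
print("correlation; the oxy/deoxy ratio < 1 reflects the collapse of the")
print("Fe moment and the Fermi-level screening in the oxygenated cluster.")
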