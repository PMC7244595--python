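# Methods

## Model

`hemeqmc` treats one heme group as a multi-orbital Anderson impurity
model: five correlated Fe(3d) orbitals (labels xy, xz, yz, z², x²−y²)
hybridized with a manifold of noninteracting host molecular-orbital
levels.  The interaction keeps the full density-density structure —
intra-orbital U, inter-orbital opposite-spin U' = U − 2J (free-atom
relation) and inter-orbital parallel-spin U'' = U' − J — and omits the
transverse Hund terms (spin flip, pair hopping), which a discrete
auxiliary-field solver cannot treat.  Total S_z is therefore conserved
exactly.  Host levels are taken as already diagonal (a one-particle
eigenbasis), so the one-body matrix is an arrowhead; hybridizations are
real.  Work is grand canonical: μ shifts all one-body energies, and
`tune_mu` bisects μ until ⟨N⟩ matches a target electron count (bisection
rather than Newton so QMC noise cannot destabilize it).

Units: energies in eV, temperatures in K with k_B = 8.617333×10⁻⁵ eV/K,
β in 1/eV, moments in μB with g = 2 (M_z of one orbital is n↑ − n↓ in
μB), susceptibilities in μB²/eV.

## Solver

The Hirsch-Fye algorithm discretizes β into L slices (τ_l = l·Δτ) and
decouples each of the n + 2n(n−1) density-density pairs (45 for n = 5)
with one Ising field per slice: e^{−ΔτW(n_a−½)(n_b−½)} =
const·Σ_{s=±1} e^{λs(n_a−n_b)}, cosh λ = e^{ΔτW/2}.  The one-body
counterpart of rewriting U n_a n_b in the symmetrized form — a Hartree
shift of +½ΣW on every spin-orbital — is folded into the bath
propagator, so the simulated Hamiltonian is exactly the literal
density-density model the ED module diagonalizes.

The bath Green's function is built from the eigen-decomposition of the
full arrowhead matrix, i.e. every host state is kept exactly; the matrix
the solver manipulates is only (n_orb·L)² per spin.  Sign conventions
follow g_ab(τ) = −⟨T c_a(τ) c_b†(0)⟩ with equal times read as τ→0⁺
(g = n − 1 on the diagonal), which turns the textbook Dyson equation for
a fixed field configuration into G = [1 + (1 + g0)(e^{V(s)} − 1)]⁻¹ g0.
Single-field flips are accepted from determinant ratios (scalar per spin
block for opposite-spin pairs, a 2×2 determinant for same-spin pairs;
heat-bath by default, Metropolis selectable — the choice affects only
autocorrelation) and applied as rank-1 updates.  G is rebuilt from
scratch every `clean_interval = 50` sweeps; the fast-update drift is
monitored against a 10⁻⁶ tolerance.  Configuration-weight signs are
tracked, estimators are always sign-reweighted (⟨O⟩ = ⟨O·sgn⟩/⟨sgn⟩),
errors come from a delete-one jackknife over ≥ 4 (default 16) bins, and
runs with |⟨sgn⟩| < 0.05 are flagged unreliable.  Single-orbital models
are provably sign-free and the code reproduces ⟨sgn⟩ = 1 there.

Measurements use the fixed-field Wick theorem.  Host observables are
never simulated: the full-cluster equal-time Green blocks follow from the
impurity one through the exact embedding identity
G_full = g_full + g_{full,imp} [g⁻¹(G − g)g⁻¹]_imp g_{imp,full}, so the
site-resolved moment-correlation matrix ⟨M_z,p M_z,q⟩ over all
host + impurity sites costs O(N²L) per measurement regardless of solver
size.  χ_t uses S_z conservation, χ_t = β⟨M_z,t²⟩; a τ-resolved
correlator and its integral are also available as an internal
cross-check.

### Known numerical behaviour

- Trotter error is O(Δτ²) for equal-time estimators;
  `extrapolate_dtau` removes it by a weighted quadratic fit over ≥ 3
  Δτ values.  The decoupling is exact (any Δτ) in the atomic limit,
  since all factors commute there.
- The τ-displaced entries of the fixed-field Green's function built on an
  exact (non-Trotterized) bath carry a systematic offset of a few percent
  relative to the equal-time ones at Δτ·U ≈ 0.1–0.5 that does not
  extrapolate away (verified by exhaustive field enumeration, which also
  confirms the sampler is exact: QMC equals the enumerated average on
  identical discretizations).  The free and atomic limits are exact.
  χ_t therefore always uses the conservation (equal-time) estimator,
  which is validated against ED; the τ-integrated route is kept as a
  cross-check with a 10% allowance.
- Degenerate inputs: λ = 0 pairs propose freely and never change G;
  attractive channels (W < 0, i.e. U < 3J) are refused because the real
  discrete decoupling does not exist there.

## Exact diagonalization

`hemeqmc.ed` diagonalizes clusters of up to 6 sites (12 spin-orbitals)
in the occupation basis, block-diagonal in (N↑, N↓) — both conserved
because only density-density interactions are present.  Thermal traces
shift by the ground energy for overflow safety.  A second, deliberately
independent construction path (dense Jordan-Wigner/Kronecker operator
strings) cross-validates the blocked builder.  ED is the oracle for every
QMC estimator, for μ tuning and for the toy-fixture correlation signs; it
is not a production solver.

## Observables

- `effective_moment`: M_eff = √(3 k_B T χ), the convention under which a
  free spin S gives g√(S(S+1)) μB — S = 2 ↔ 4.90 μB, S = ½ ↔ √3 μB.
  The instantaneous alternative √(3⟨M_z²⟩)·(1 μB) is exposed as
  `QMCResult.m_t_instantaneous`; both are reported because either could
  be the moment a figure plots.
- `curie_fit`: weighted least squares of χ = C/T.  When the single-regime
  reduced χ² exceeds 5 and some low/high split improves it at least
  twofold, a crossover is reported with per-regime moments and T* at the
  split midpoint.  Thresholds are heuristics chosen once; with exact
  Curie data the fit is an exact round trip of the generator.
- `project_moment_density`: atomic moment at site A is
  Σ_states w_{A,state} ⟨M_z,state M_z,t⟩ / √⟨M_z,t²⟩, with normalized
  projection rows; correlating against the **total** moment (not Fe
  alone) keeps the map well defined when the Fe moment collapses (the
  oxygenated case), and makes the atomic moments sum exactly to the total
  moment estimator — an identity asserted in the tests.  Host sites
  antiferromagnetically locked to a dominant Fe moment come out negative.
- `moment_vs_mu_scan`: M_t(μ) = √(3 k_B T χ_t(μ)) with a free
  (closed-form), ED or QMC backend.

## The MCD band model

The UV absorption of deoxy-heme near 3 eV is the porphyrin π→π* band.
Two partially occupied π* bands matter: π1* (nearly half-filled, spin
polarized parallel to the applied field through its antiferromagnetic
coupling to Fe) and π2* (nearly empty, centred 0.3 eV higher).  Spin
selection makes LCP light feed π→π1* and RCP light π→π2*, so

    Δε(E) = A·p·[(1−f1)·G(E; E_π+E1, w1) − (1−f2)·G(E; E_π+E2, w2)]

with G a unit-area Gaussian (Lorentzian selectable), widths read as FWHM,
and p = ±tanh(g μB B / 2 k_B T) the Curie-law polarization whose sign
encodes the antiferromagnetic locking (the "negative g-factor" of the π*
bands).  Width-as-FWHM is a deliberate reading of "width ≈ 0.3 eV": with
σ = 0.3 eV the two bands overlap so strongly that the leading positive
peak is swallowed.  With the default fillings (f1 = 0.5, f2 = 0) the
spectrum rises first and then dips — the anomalous ordering — though the
dip in this two-Gaussian stand-in is deeper than the peak; the
classification (`classify_lineshape`) keys only on the ordering of the
extrema and is amplitude-invariant.  ∫Δε dE = A·p·(f2 − f1): the unequal
fillings are exactly what keeps the integral nonzero.  Spin-orbit
coupling is not modelled explicitly; it enters only through the selection
rules.  The thermal tanh polarization can be overridden by a value
derived from the QMC Fe-π1* correlation to chain the solver into the
optics.

## The inter-heme algebra

With n hemes of single-heme moment M_single and equal pair correlations,
a molecule-level susceptibility read as independent hemes reports
M_ind² = M_single² + (n−1)⟨M1M2⟩.  `pair_correlation_from_moments`
inverts this; it reproduces ≈1.9 μB² against the bare S = 2 moment and
≈4.3 μB² against the screened 4.1 μB heme moment, and is monotone:
stronger local antiferromagnetic screening implies stronger inter-heme
ferromagnetism.  The equal-pair-correlation form is a reconstruction
validated by those two round trips; no microscopic inter-heme coupling is
modelled.

## Synthetic parameter generator

The first-principles ε_m, ε_dv, V_mv of the real clusters are not
published, so `hemeqmc.synth` emulates their structure; all generators
are pure functions of (spec, seed).

- **Host manifold** (default n_host = 60 over [−25, +10] eV): a uniform
  grid with bounded jitter (controlled level spacings rather than fully
  random draws), plus the special states: three bonding π levels near
  −3 eV, three π1* levels spanning a 0.3 eV window centred on μ_F
  (nearly half-filled), three π2* levels on [0.15, 0.45] eV (nearly
  empty), and — oxy only — one acceptor state at +0.05 eV (within the
  0.15 eV scale of the Fermi-level physics).
- **Hybridizations**: Gaussian with scale 0.35 eV decaying away from μ_F
  (decay 3 eV) so the screening physics concentrates at the Fermi level;
  π/π1*/π2* states couple through the π-symmetry (xz, yz) channels at
  0.35/0.5/0.4 eV; the oxy acceptor couples to the t2g channel at
  1.6 eV — the resonant screening channel.
- **Fe levels**: a t2g/e_g pattern split by a crystal field (0.8 eV
  deoxy-like → high-spin d⁶; 3.9 eV oxy-like → low-spin-leaning with a
  thermally reduced but finite moment), rigidly shifted so the d⁶
  configuration is charge-stable mid-gap at μ = 0.  The shift is computed
  by exact enumeration of all 2¹⁰ atomic occupation patterns — no
  mean-field approximation.
- **Projection matrix**: π/π* rows spread over the 20 carbon sites
  (C 2p_z character), the oxy acceptor over O1/O2 and the nitrogens,
  generic hosts over N + C, Fe(3d) rows onto the Fe site; rows sum to 1.
- `make_toy_cluster` provides the ED-sized fixtures (particle-hole
  symmetric, Kondo-screening and free regimes); `make_curie_dataset`
  generates exact or noisy Curie data, optionally with a moment crossover
  at a set T*.

### What the scaled-down runs show — and what they do not

Desk-scale QMC cannot reach the physical temperature range of the real
clusters (room temperature means β ≈ 39 eV⁻¹, i.e. hundreds of time
slices under 45 auxiliary fields).  The shipped study conditions run at
elevated temperatures (k_BT ≈ 0.2–0.5 eV, L ≈ 16–40 at Δτ = 0.125) with
a few hundred sweeps, where the **direction** of the physics is resolved:
the deoxy-like cluster shows a formed moment with near-Curie χ_t(T) and
robustly negative Fe-π1* correlations; the oxy-like cluster sits below it
in χ_t at every temperature; and the curvature of ⟨M_z,t²⟩(μ) at μ_F
turns negative as T is lowered — the Fermi-level moment suppression — 
while at high T it is not.  A literal local minimum in a pointwise
M_t(μ) scan is not resolvable on top of the monotone host-filling
background at these temperatures, so the dip is asserted as that
temperature-dependent curvature.  Quantitative headline values of the
real system (Fe moment ≈ 4.6 μB, total ≈ 4.1 μB at 150 K, the oxy
crossover near 300 K, χ_t ≈ 150 μB²/eV) require the unpublished
first-principles inputs and physical temperatures and are **not**
reproduced by the synthetic fixtures; passing tests demonstrate the
correctness of the machinery and the sign structure of the physics, not
agreement with experiment.

## Problem sizes used by the shipped checks

- Solver-vs-ED: three toy fixtures (1–2 orbitals, 2 host levels) at
  β = 2 eV⁻¹, Δτ ∈ {0.5, 0.25, 0.125}, 48k–144k sweeps, 16 jackknife
  bins, independent seeds per Δτ.
- Exhaustive enumeration: 2¹⁰ configurations at Δτ = 0.1 with U ≤ 1 eV,
  where the residual Trotter error sits well below the 0.1% band.
- Heme-like runs: n_host = 60, five orbitals, T ∈ {2500…6000} K,
  Δτ = 0.125, 400–700 sweeps × 8 bins, measurements every 2 sweeps.

## Limitations

- No transverse Hund terms, no analytic continuation to real
  frequencies, no continuous-time solver, and no attempt to compute
  transition dipoles ab initio.
- The MCD model is a two-band stand-in with a thermal polarization; the
  measured optical absorption is not folded in.
- The τ-integrated susceptibility estimator inherits the displaced-time
  discretization offset described above.
- Inter-heme physics is bookkeeping, not a microscopic multi-heme model;
  cooperativity scenarios are out of scope.
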