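# Methods

## The full model

Receptor–ligand binding is modelled as three reversible mass-action steps,

```
R + L ⇌(d⁺,d⁻) RL* ⇌(e⁺,e⁻) RL ⇌(k⁺,k⁻) C
```

where `RL*` is the encounter complex (within reaction distance), `RL` the
oriented complex and `C` the chemically bound complex. The deterministic
dynamics are the five coupled ODEs of mass action; receptor and ligand
totals are conserved exactly along trajectories, and the equilibrium
satisfies detailed balance step by step (RL*/([R][L]) = K_D, RL/RL* = E,
C/RL = K_A). The model is well mixed: the diffusion step is a rate
constant, not a spatial field, and rates are force independent.

**Units.** 3D concentrations are molar; 2D concentrations are mol µm⁻², so
the 2D diffusion on-rate carries µm² mol⁻¹ s⁻¹. All unimolecular rates are
s⁻¹. A pair of helpers converts 2D concentrations to molecules µm⁻² for
display. Because realistic 2D diffusion affinities are of order 10¹⁸–10¹⁹
µm² mol⁻¹ (per-molecule areas divided by the Avogadro constant), several
tests and examples use rescaled, unitless-magnitude parameter sets; the
algebra is invariant under this rescaling.

**Numerics.** Integration uses LSODA with rtol 1e-10 and atol
1e-12 × max(totals): the timescale-separated regimes that justify the
effective models are stiff by construction. The closed-form equilibrium
reduces, via the three detailed-balance relations and conservation, to a
quadratic in [C]; the numerically stable smaller root is taken and a brentq
bisection over [0, min(totals)/σ] serves as fallback (σ is the complexed
mass per unit of C). Off-rates of zero are allowed in integration
(irreversible funnel) but refused in the equilibrium solver, where
intermediate species would have no finite limit.

**Stochastic counterpart.** A Gillespie direct-method engine propagates
integer molecule counts with the bimolecular propensity d⁺·n_R·n_L/Ω, where
Ω converts counts to concentration. It is exact and seed-reproducible. Its
replicate mean differs from the ODE solution by the usual O(1/Ω) mean-field
correction for nonlinear propensities; consistency checks therefore operate
with ligand in excess (pseudo-first-order-like conditions), where the bias
sits below the Monte-Carlo resolution of a few thousand replicates.

## Effective models

Each assay class resolves only part of the scheme; the package encodes the
four corresponding reductions both as closed forms and as reduced ODE
systems.

* **PBA** (thermal fluctuation): rotation is internally equilibrated within
  the lumped pre-binding species ⟨RL⟩ = RL* + RL, of which a fraction
  E/(1+E) is binding competent. Hence k_on = k⁺E/(1+E) ≈ E k⁺ for E ≪ 1 and
  k_off = k⁻ exactly — the TF assay reads the true unbinding rate.
* **PBB** (thermal fluctuation alternative; bulk/3D FRET): the binding step
  is internally equilibrated — multiple bind/unbind events occur before
  de-orientation — within ⟨C⟩ = RL + C, of which a fraction 1/(1+K_A) can
  de-orient. Hence k_on = e⁺, k_off = e⁻/(1+K_A).
* **FRET** (single-molecule, 2D): donor/acceptor optics resolve only the
  meta-states ⟨R⟩ = R + RL*, ⟨L⟩ = L + RL*, ⟨C⟩ = RL + C. With diffusion
  and binding fast relative to the observable orientation transition,
  k_on = K_D e⁺ (ligand independent) and k_off = e⁻/(1+K_A).
* **SS** (adhesion frequency, SPR): only bound vs unbound is resolved; both
  pre-binding steps are fast. With Δ = d⁻e⁻ + d⁻k⁺ + e⁺k⁺:
  k_on = d⁺e⁺k⁺/Δ, k_off = d⁻e⁻k⁻/Δ, K_a = K_D E K_A. The on-rate obeys
  1/k_on = 1/(K_D E k⁺) + (d⁻+e⁺)/(d⁺e⁺), i.e. it interpolates
  harmonically between the reaction-limited and transport-limited
  asymptotes and never exceeds either.

Consequences used throughout: the FRET and SS 2D affinities differ exactly
by (K_A+1)/K_A; in the reaction-limited 2D regime the SS constants decompose
as log k_on = log k⁺ + log(K_D E), log k_off = log k⁻, log K_a = log K_A +
log(K_D E), so panel trend lines of effective and fundamental constants
share slopes and log-ranges, with only the on-rate and affinity lines
shifted by log(K_D E); in the transport-limited 3D (SPR) regime k_on = d⁺
is ligand independent and log k_off = −log K_A + log(d⁻/E), mirroring the
affinity — the origin of the opposite 2D/3D correlation signs.

**Reduction oracle.** Because the closed forms are easy to mistranscribe,
`validate_reduction` is the arbiter: it scales a model's fast steps so
their relaxation is exactly `s`-fold faster than the slow steps' (matching
off-rate geometric means before applying the factor), integrates the full
model, projects it onto the model's grouped observables and compares with
the reduced system run from `reduce_to_effective` constants. Deviations
shrink ≈ 1/s. For SS (and, mildly, FRET) the projection hides the
intermediate species, so the deviation converges to a floor set by the
equilibrium intermediate occupancy K_D·L_tot(1+E); oracle tests therefore
choose totals giving occupancy ≈ 1e-4, well below the 1e-2 working
tolerance.

**Inversion and observability.** `invert_effective` returns per-constant
determinacy instead of failing wholesale: PBA determines (k⁺, k⁻) given E;
PBB/FRET determine e⁺ and — given e⁻ — K_A but never k⁺ or k⁻ individually
(the FRET on-rate carries no ligand information); SS determines (k⁺, k⁻)
given the transport/rotation constants, provided the measured on-rate lies
below the transport limit d⁺e⁺/(d⁻+e⁺), which is a hard identifiability
boundary.

## Transport constants

The 2D encounter on-rate uses the diffusion-limited 2D capture law with its
logarithmic geometry dependence, d⁺ = 2πD·N_A/ln(b/a) (D membrane
diffusivity, b mean inter-receptor spacing, a encounter radius); the SPR
flow-cell transport coefficient uses the cube-root Lévêque law
k_m = 1.282·(vD²/(hL))^¹ᐟ³ converted to volumetric units through the
encounter cross-section A_c = πa². Both are pinned by golden regression
values; what the framework's conclusions rely on is only that they are
ligand independent, which holds structurally (no operation in the module
accepts a binding constant). The 2D rotational equilibrium constant
defaults to E²ᴰ = 0.04; no 3D default exists — E³ᴰ must be configured or
estimated, never guessed.

## Synthetic assays

Generators are pure functions of (parameters, seed) and their noiseless
outputs equal the corresponding model solutions.

* **TF lifetimes**: i.i.d. exponential with rate k_off (no added noise —
  the distribution is the signal).
* **AF curves**: bonds in the contact area form an immigration–death
  process (formation rate ν = k_on·m_r·m_l·A_c/N_A, per-bond death k_off),
  whose bond count at contact end is exactly Poisson with mean
  (ν/k_off)(1−e^{−k_off t}); adhesion means ≥ 1 bond and frequencies are
  binomial over cycles. The default generator samples this exact law; a
  Gillespie mode (`method="ssa"`) simulates the same process event by
  event and is cross-checked against it. The Poisson form assumes
  receptor/ligand depletion in the contact is negligible (bond numbers of
  order one against hundreds of free molecules).
* **Sensorgrams**: closed-form two-phase 1:1 kinetics (association toward
  the Langmuir plateau at rate k_on·c + k_off, exponential dissociation at
  k_off) with additive Gaussian noise.
* **FRET traces**: the projected full-model trajectory (⟨L⟩ → donor,
  ⟨C⟩ → acceptor) scaled by channel gains, with additive Gaussian noise.
  No photophysics (bleaching, blinking) or instrument drift is modelled.
* **Ligand panels**: k⁺ and k⁻ log-spaced with exact fold-ranges (defaults
  10³ and 10, both increasing with potency — the implied K_A fold-range is
  their ratio, 10²) and potency 1/EC₅₀ coupled to K_A by default.
  Lognormal jitter, when requested, perturbs interior ligands only so the
  requested fold-ranges stay exact. The default six ligands carry the
  conventional altered-peptide-ligand names (OVA most potent … R4 least);
  their parameter values are synthetic, not literature values.

What passing tests show about real data is limited accordingly: the
generators emulate the *structure* of each readout (distributional law,
two-phase schedule, meta-state observability, panel fold-ranges), not
instrument artefacts, surface heterogeneity, rebinding, or force-dependent
(catch/slip) kinetics — all out of scope. Surface densities and contact
areas default to round placeholder values (hundreds of molecules µm⁻²,
A_c = 3 µm²); analyses that depend on them take them as explicit inputs.

## Inference and case analyses

Lifetimes are fitted by the exponential MLE (inverse mean, SE = k̂/√n);
sensorgrams by Levenberg–Marquardt least squares in log-parameters with
starts from the dissociation log-slope and association plateau; adhesion
curves by binomial maximum likelihood in (log n_∞, log k_off) with
Nelder–Mead multi-start and observed-information standard errors. Fits
report convergence honestly; flat or saturated readouts are flagged
degenerate/non-identifiable rather than forced.

Trend lines are ordinary least squares of log₁₀(constant) on
log₁₀(potency); in the conventional potency-vs-constant scatter an
intercept difference between equal-slope lines is a shift along the
constant axis. "Much less than" conditions (e.g. k⁺ ≪ e⁻ for the PBA
description of the TF assay) are operationalised as a ratio ≤ 1e-2,
configurable. PBB is rejected for the TF assay by solving, per ligand, for
the e⁻ its off-rate equality would require and checking whether a single
ligand-independent value can serve — on any panel with varying K_A it
cannot.

The rotational constants are estimated from matched panels:
E²ᴰ = (K_a^FRET − K_a^AF)/K_D per ligand (exact in the noiseless algebra),
with the implied K_A = K_a^AF/(K_a^FRET − K_a^AF); the estimate is declared
invalid when any K_A ≥ 1, where the two affinities nearly coincide and the
subtraction is ill-conditioned. Given a matched bulk-FRET (3D) panel, the
off-rate ratio transfers e⁻ across dimensions and the bulk on-rate supplies
e⁺³ᴰ, yielding E³ᴰ.

## Problem sizes and determinism

Simulation-based checks run at: 20 random draws × 4 models × 3 separation
factors for the reduction oracle; 10⁴ lifetimes, 2,000 adhesion cycles per
contact time and 500-point 1%-noise sensorgrams × 100 seeds for parameter
recovery; 2,000 Gillespie replicates at ≥ 100 receptor counts for
stochastic–deterministic consistency. Every stochastic operation takes an
explicit seed (config runs derive per-assay seeds deterministically from
one global seed), so identical inputs give identical numeric outputs on one
platform.

## Known limitations

Well-mixed kinetics only; no force dependence, no conformational-change
extension of the binding step, no multi-step binding; the AF generator's
pseudo-first-order assumption breaks at very high affinities or densities
(mean bond numbers approaching the free-molecule count); SS inversion
degrades near the transport limit, where the effective on-rate becomes
insensitive to k⁺; experimental EC₅₀ values are treated as an abstract
potency covariate — no dose–response model is fitted.
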