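# kinetrans

**Translate between fundamental and assay-effective receptor–ligand kinetic
constants in 2D and 3D.**

Measurements of T-cell receptor (TCR) binding to its peptide–MHC (pMHC)
ligand disagree across techniques: surface plasmon resonance (SPR, 3D)
reports off-rates that fall with ligand potency, while membrane-to-membrane
(2D) assays — adhesion frequency, thermal fluctuation, single-molecule FRET —
report on- and off-rates that *rise* with potency. `kinetrans` implements a
kinetic framework that reconciles these observations: every assay is an
incomplete observation of one underlying three-step binding scheme, and the
"rate constants" it reports are *effective* constants — specific combinations
of the fundamental ones, different for each assay class.

## The model

Binding is resolved into translational diffusion, rotational orientation and
chemical docking:

```
R + L  ⇌(d⁺, d⁻)  RL*  ⇌(e⁺, e⁻)  RL  ⇌(k⁺, k⁻)  C
```

with step affinities K_D = d⁺/d⁻, E = e⁺/e⁻ and K_A = k⁺/k⁻. Diffusion and
rotation are ligand independent but dimension dependent; k± are ligand
specific. Four effective models describe what each assay class resolves
(derived by quasi-steady-state reduction and verified numerically by a
built-in reduction oracle):

| model | assay class | k_on | k_off | K_a |
|-------|-------------|------|-------|-----|
| PBA  | thermal fluctuation | k⁺E/(1+E) | k⁻ | K_A·E/(1+E) |
| PBB  | TF alt., bulk FRET (3D) | e⁺ | e⁻/(1+K_A) | E(K_A+1) |
| FRET | single-molecule 2D FRET | K_D e⁺ | e⁻/(1+K_A) | K_D E(K_A+1) |
| SS   | adhesion frequency (2D), SPR (3D) | d⁺e⁺k⁺/Δ | d⁻e⁻k⁻/Δ | K_D E K_A |

with Δ = d⁻e⁻ + d⁻k⁺ + e⁺k⁺. The package provides the forward mapping, its
(partial) inversion with explicit per-constant determinacy, reduced ODE
simulators, a full-model ODE/Gillespie engine, synthetic generators for the
four assay readouts, fitting routines, and the pairwise case analyses
(trend-line algebra, rotational-constant estimation).

## Worked example

`examples/effective_constants.py` maps one 2D parameter set
(k⁺ = 0.1 s⁻¹, k⁻ = 0.5 s⁻¹, pre-binding steps fast, E²ᴰ = 0.04) to what each
assay would report:

```
fundamental: k+ = 0.1, k- = 0.5, K_A = 0.2
model      k_on_eff    k_off_eff      K_a_eff  determines
PBA       0.0038462          0.5    0.0076923  k_minus, k_plus
PBB             400       8333.3        0.048  K_A, e_plus
FRET            400       8333.3        0.048  K_A, e_plus
SS            0.004      0.49999        0.008  k_minus, k_plus
```

The thermal-fluctuation (PBA) and adhesion-frequency (SS) off-rates both
equal k⁻ (0.5 s⁻¹) — which is why those two assays agree — while the FRET
off-rate is e⁻/(1+K_A), a number that contains no k⁻ at all. The
`determines` column is the observability result: FRET can never recover k⁺
or k⁻, only the orientation rate and (given e⁻) the affinity.

Other examples: `simulate_full_model.py` (ODE integration vs closed-form
equilibrium), `validate_reductions.py` (numerical QSSA oracle),
`synthesize_and_fit.py` (synthesize → fit → invert round trip),
`case_analyses.py` (model selection, trend lines, E²ᴰ estimation). A thin
CLI wraps the same functions:

```
kinetrans reduce --config demo.yml         # effective-constant table
kinetrans cases  --config demo.yml         # case-analysis verdict report
kinetrans trends --config demo.yml         # log-log trend-line table
```

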