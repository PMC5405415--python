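"""Round trip: fundamental constants -> synthetic assays -> recovered constants.

Generates a bond-lifetime sample (TF), an adhesion-frequency curve (AF)
and a noisy sensorgram (SPR) from known fundamental constants, fits the
effective constants back from each readout and inverts them to the
fundamental ones given the ligand-independent transport/rotation rates.
"""

from kinetrans import (
    EffectiveConstants,
    EffectiveModelKind,
    FundamentalConstants,
    fit_adhesion_curve,
    fit_lifetimes,
    fit_sensorgram,
    invert_effective,
    reduce_to_effective,
    sample_tf_lifetimes,
    synthesize_af_curve,
    synthesize_sensorgram,
)

SS2D, SS3D = EffectiveModelKind("SS", "2D"), EffectiveModelKind("SS", "3D")

# --- TF: bond lifetimes read k- directly (PBA: k_off = k-) ----------------
k_minus_true = 0.5
fit = fit_lifetimes(sample_tf_lifetimes(k_minus_true, 10_000, seed=1))
print(f"TF:  true k- = {k_minus_true}, fitted {fit['k_off']:.4f} +- {fit.stderr['k_off']:.4f} 1/s")

# --- AF: adhesion frequency, 2,000 touch cycles per contact time ----------
shared2d = {"dimension": "2D", "d_plus": 1.26e23, "d_minus": 1.0e4,
            "e_plus": 400.0, "e_minus": 1.0e4}
true2d = FundamentalConstants(k_plus=0.1, k_minus=0.5, **shared2d)
eff2d = reduce_to_effective(true2d, SS2D)
curve = synthesize_af_curve(eff2d, 1000, 1000, 3.0,
                            [0.25, 0.5, 1, 2, 4, 8, 16], 2000, seed=2)
fr = fit_adhesion_curve(curve)
known2d = {k: shared2d[k] for k in ("d_plus", "d_minus", "e_plus", "e_minus")}
inv = invert_effective(
    EffectiveConstants(SS2D, k_on=fr["K_a"] * fr["k_off"], k_off=fr["k_off"]), known2d
)
print(f"AF:  true k+ = {true2d.k_plus}, k- = {true2d.k_minus}; "
      f"recovered k+ = {inv['k_plus']:.4f}, k- = {inv['k_minus']:.4f} 1/s")

# --- SPR: 1% noise sensorgram, 1:1 two-phase fit --------------------------
shared3d = {"dimension": "3D", "d_plus": 1.0e6, "d_minus": 1.0,
            "e_plus": 10.0, "e_minus": 10.0}
true3d = FundamentalConstants(k_plus=5.0, k_minus=0.05, **shared3d)
eff3d = reduce_to_effective(true3d, SS3D)
sg = synthesize_sensorgram(eff3d, 1e-6, 60.0, 300.0, 500, R_max=100.0,
                           noise_sd=1.0, seed=3)
fr3 = fit_sensorgram(sg)
inv3 = invert_effective(EffectiveConstants(SS3D, k_on=fr3["k_on"], k_off=fr3["k_off"]),
                        {k: shared3d[k] for k in known2d})
print(f"SPR: true k+ = {true3d.k_plus}, k- = {true3d.k_minus}; "
      f"recovered k+ = {inv3['k_plus']:.3f}, k- = {inv3['k_minus']:.4f} 1/s")
# Each assay only reports effective constants; the inversion uses the
# ligand-independent transport/rotation rates to reach the fundamental ones.
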