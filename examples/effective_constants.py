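"""Map one fundamental parameter set to the constants each assay reports.

The same molecule pair measured by four assay classes yields four
different "on/off-rate constants": this prints them side by side, plus
the observability of the underlying fundamental constants per model.
"""

from kinetrans import (
    EffectiveModelKind,
    FundamentalConstants,
    invert_effective,
    reduce_to_effective,
)

# thermal-fluctuation / adhesion-frequency regime: pre-binding fast, E^2D = 0.04
params = FundamentalConstants(
    "2D", d_plus=1.0e4, d_minus=1.0e4, e_plus=400.0, e_minus=1.0e4,
    k_plus=0.1, k_minus=0.5,
)
known = {k: getattr(params, k) for k in ("d_plus", "d_minus", "e_plus", "e_minus")}

print(f"fundamental: k+ = {params.k_plus}, k- = {params.k_minus}, K_A = {params.K_A}")
print(f"{'model':6s} {'k_on_eff':>12s} {'k_off_eff':>12s} {'K_a_eff':>12s}  determines")
for tag in ("PBA", "PBB", "FRET", "SS"):
    eff = reduce_to_effective(params, EffectiveModelKind(tag, "2D"))
    inv = invert_effective(eff, known)
    det = ", ".join(sorted(inv.values)) or "nothing"
    print(f"{tag:6s} {eff.k_on:12.5g} {eff.k_off:12.5g} {eff.K_a:12.5g}  {det}")
# Note the PBA off-rate equals k- exactly (the TF assay reads the true
# unbinding rate), while the FRET off-rate e-/(1+K_A) does not involve
# k- at all -- different assays determine different constants.
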