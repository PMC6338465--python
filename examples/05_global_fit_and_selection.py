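"""Global fit of all six cycles and SSE-ranked model selection.

Simulates a reduced two-geometry study from the Brownian-ratchet-by-
binding truth, fits every candidate scheme to both datasets at once
(chemical rates shared between contexts, translocation rates free per
context), and prints the ranking plus the winning scheme's parameters.
"""

from ratchetfit.conditions import (geometry_in_complex, geometry_isolated,
                                   make_study_traces)
from ratchetfit.fitting import select_model
from ratchetfit.pipeline import process_traces

traces = make_study_traces(seed=5, n_traces=6)
dataset = process_traces(traces)
g_op, g_hp = geometry_in_complex(), geometry_isolated()

ranking = select_model([dataset, dataset], [g_op, g_hp],
                       mode="shared_chemistry", n_starts=6, seed=5,
                       weights="sem")

print("scheme ranking (best first, by the minimized chi-square):")
for f in ranking:
    print(f"  {f.scheme_id:<14} chi2 = {f.objective:>8.0f}  "
          f"SSE = {f.sse:>8.0f}  R^2 = {f.r2:.4f}")

best = ranking[0]
r_op = best.rates["opposing_force"]
r_hp = best.rates["hairpin_assisting"]
print(f"\nbest scheme: {best.scheme_id}")
print(f"  step size delta       = {r_op.delta:.2f} bp")
print(f"  effective catalytic   = {r_op.k_c_eff:.0f} /s")
print(f"  K_eq (in complex)     = {r_op.k_eq:.3f}")
print(f"  K_eq (isolated)       = {r_hp.k_eq:.1f}")
print(f"  K_eq shift            = {r_hp.k_eq / r_op.k_eq:.0f}-fold")
print(f"  destabilization dG    = {r_hp.dG_dest:.2f} kBT")

print(
    "\nThe ratchet-rectified-by-binding cycle should rank first (its"
    "\nhydrolysis-placed sibling is a close runner-up - the two are hard to"
    "\ntell apart at this data size), and the fitted K_eq values should"
    "\ndiffer by roughly the 200-fold shift built into the truth."
)
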