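"""Simulate passive-mode traces and run the trace-analysis chain.

Generates a small synthetic study (Brownian-ratchet-by-binding truth) in
both assay geometries, processes it with the standard parameters (250 Hz
smoothing, 100 ms velocity windows, tenth-length median filter, 3/2 pN
force bins), and prints the binned force-velocity table at 2 mM ATP.
"""

from ratchetfit.conditions import make_study_traces
from ratchetfit.pipeline import process_traces

traces = make_study_traces(seed=11, n_traces=5, atp_grid=(3.5e-4, 2e-3))
print(f"simulated {len(traces)} traces "
      f"({sum(t.geometry == 'opposing_force' for t in traces)} opposing, "
      f"{sum(t.geometry == 'hairpin_assisting' for t in traces)} hairpin)")

dataset = process_traces(traces)
t = dataset.table
t2mm = t[t["atp"] == 2e-3]
for geom, grp in t2mm.groupby("geometry"):
    print(f"\n{geom}, [ATP] = 2 mM:")
    print(f"{'F bin':>6} {'F mean':>7} {'v (bp/s)':>9} {'sem':>6} {'n':>4}")
    for _, r in grp.sort_values("f_bin").iterrows():
        print(f"{r.f_bin:>6.1f} {r.f_mean:>7.2f} {r.v_mean:>9.1f} "
              f"{r.v_sem:>6.1f} {r.n:>4.0f}")

print(
    "\nOpposing traces sweep force upward as the tether shortens, so the"
    "\nvelocity column falls with force; hairpin bursts sweep downward and"
    "\nslow as the fork restabilizes. Each row is a mean +- s.e.m. over the"
    "\nensemble of per-trace curves."
)
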