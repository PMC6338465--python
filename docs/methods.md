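# Methods

`ratchetfit` models how a DNA helicase couples its ATPase cycle to
translocation, and how an external force probes that coupling in
passive-mode optical-tweezers assays. This note documents the models, the
numerical choices, and the synthetic study conditions in enough detail to
reproduce or criticize them.

## The candidate mechano-chemical cycles

The chemistry is the minimal three-step ATPase cycle

    R + T  <=>[k+b, k-b]  R.T  -->[kh]  R.D.Pi  -->[kr]  R + D + Pi

with second-order ATP binding (`k+b`, M⁻¹s⁻¹), reversible unbinding
(`k-b`), and irreversible hydrolysis (`kh`) and product release (`kr`).
Product rebinding is not modeled ([ADP] = [Pi] = 0). A processive motor
additionally advances by a step of `δ` base pairs once per cycle. Two
binary questions generate the candidate set:

* **Mechanism.** A *power stroke* (PS) ties the step to one chemical
  transition: that transition itself carries the motion. A *Brownian
  ratchet* (BR) lets the enzyme fluctuate thermally between pre- and
  post-translocation states (attempt rates `k+tr`, `k-tr`, zero-force
  equilibrium constant `K_eq = k-tr/k+tr`) and uses a chemical step to
  trap the forward excursion; structurally this inserts one extra state
  immediately before the rectifying step.
* **Placement.** The translocation accompanies ATP binding, hydrolysis,
  or product release.

Crossing the two gives exactly six schemes (`br-binding` … `ps-release`),
each a single-loop continuous-time Markov chain of 3 (PS) or 4 (BR)
states.

**Steady state.** Occupancies solve `πQ = 0`, `Σπ = 1` (one column of
`Qᵀ` replaced by ones; batched `numpy.linalg.solve`, shape `(…, S, S)` with
S ≤ 4). Velocity is `δ` times the net flux through the
translocation-carrying transition. The supplement-style closed-form
Michaelis-Menten expressions are *not* transcribed; `v_max` is found by
scanning [ATP] decade-by-decade until the relative change per decade is
below 1e-6 and `K_M` by Brent bracketing of `v = v_max/2` to 1e-8 relative
tolerance. Because every cycle has a single loop and a single
ATP-proportional rate, `1/v` is exactly affine in `1/[ATP]`, so the
Michaelis-Menten form holds identically — the numerical route is exact, not
approximate, and is validated against independently derived closed forms
in limits (three-step chain; rapid-equilibrium ratchet).

**Force coupling.**

* *Opposing geometry* (enzyme translocates against the tether tension):
  Bell factors on the translocation transition, forward
  `exp(−F·x‡·0.34 nm/kBT)` and backward `exp(+F·(δ−x‡)·0.34 nm/kBT)`,
  with `x‡` the distance to the transition state (default `x‡ = δ`, a
  fully forward-loaded barrier; independently fittable). The bp→distance
  conversion is 0.34 nm/bp and `kBT = 4.11 pN·nm` (25 °C), both
  configurable. For PS schemes coupled at an irreversible step only the
  forward factor exists.
* *Hairpin geometry* (force destabilizes the fork ahead): the forward
  translocation rate is multiplied by `P_open(F)`; force does not
  otherwise enter the cycle.

## Fork mechanics

dsDNA follows the high-force extensible Marko–Siggia interpolation
`x = L·[1 − ½√(kBT/(F·Lp)) + F/S]` with `Lp = 40 nm`, `S = 1000 pN`; the
inverse (extension → contour at known force) is the exact algebraic
rearrangement. Samples below 0.5 pN are outside the formula's domain and
are masked, never extrapolated. ssDNA is a freely-jointed chain with Kuhn
length 1.5 nm and contour 0.59 nm/nt; its stretching free energy has the
closed form `(l_c/b)·ln(sinh u/u)` kBT per nucleotide, `u = bF/kBT`
(series-expanded at both ends for numerical safety).

`P_open` is a single-exponential zipper: opening `j` bp costs
`j·Δg(F)` with `Δg = dg_bp − dG_dest − 2·w_ss(F)`, where `dg_bp` is the
sequence-averaged pairing free energy (default 2.3 kBT), `dG_dest` the
enzyme's destabilization energy applied uniformly per open bp, and
`w_ss(F)` the FJC stretching energy of one released nucleotide (two per
open bp). Then `P_open = Σ_{j=n}^{m} e^{−jΔg} / Σ_{j=0}^{m} e^{−jΔg}`
with `n` the helicase step (default 3 bp) and window `m = 20`. All four
structural choices (uniform energies, per-bp destabilization, 2 nt/bp,
single-exponential zipper) are deliberate minimal-model decisions; the
alternatives (nearest-neighbor sequence energies, first-bp-only
destabilization) are out of scope. Nothing here resolves which exact
prior formulation the field's individual labs use; the dependencies —
fork stability, enzyme destabilization, force — are the modeled content.

## The trace simulator

`gillespie_run` is an exact SSA over the scheme's states, embedded in
passive-mode mechanics: two fixed traps of combined stiffness `k_eff`
(default 0.4 pN/nm) hold a tether whose composition depends on the assay.
Opposing layout: a dsDNA contour that shortens by `δ·0.34 nm` per step.
Hairpin layout: fixed dsDNA handles plus two released ssDNA nucleotides
per unwound bp. After every position-changing event the force is re-solved
from `F = k_eff(separation − x_tether(F))` (safeguarded Newton, |residual|
< 1e-9 pN) and the force-modulated rates are refreshed; chemical events
leave the force untouched. The chain is relaxed to its stationary phase
for 0.2 s before recording starts, because a measured trace begins
mid-activity — starting at the cycle origin would under-count the first
analysis window by up to one step. Kernels are numba-jitted when
available and run identically (same random stream) as pure Python.

`render_trace` samples the piecewise-constant event record at
`f_s = 2500 Hz`, adds white Gaussian noise (default σ = 2 nm) to the
extension, and propagates it to the force channel with gain `−k_eff`
(both channels are read from the same bead positions). Bead
hydrodynamics, QPD filtering, and trap anharmonicity are not modeled, so
the noise floor is white rather than Lorentzian — a known idealization.

An optional Bell off-rate `k_off = k0·exp(F/f_scale)` terminates traces;
it is off for oracle runs.

**Study conditions.** The reference contexts emulate the two assays at
the published scales (the underlying single-molecule data are not
publicly deposited, so microscopic truth rates were chosen once to
reproduce the derived quantities, and are not tuned thereafter):

| parameter | in complex | isolated |
|---|---|---|
| k+b (M⁻¹s⁻¹) | 5e6 | 5e6 |
| k−b, kh, kr (s⁻¹) | 300, 200, 370 | same |
| k+tr, k−tr (s⁻¹) | 1e5, 1e4 | 1e5, 2e6 |
| K_eq | 0.1 | 20 (200-fold shift) |
| δ, x‡ (bp) | 3.3, 3.3 | same |
| dG_dest (kBT) | — | 0.6 |

These give a zero-force velocity of ~410 bp/s at 2 mM ATP, `K_M` ≈ 65 µM,
and a half-velocity force of ~21 pN in the opposing assay, and a
fork-limited sigmoid (≈4 bp/s at zero force, plateau ~255 bp/s near
15 pN) in the hairpin assay. The [ATP] design is {20, 100, 350, 1000,
2000} µM. Opposing traces start at 5 pN and run for ≤3 s or until the
50 pN cap; hairpin traces are *bursts* — the isolated enzyme is poorly
processive, so its activity appears as ~1 s unwinding events — generated
with a constant 0.8 s⁻¹ off-rate and per-trace starting forces drawn
uniformly from 6–15 pN (activity engages the fork at varying tension).
Simulated traces share none of the real data's drift, sequence
heterogeneity, or multi-tether artifacts; closure results therefore
validate the estimator chain, not instrument-specific systematics.

## Trace processing

The chain reproduces standard passive-mode practice: moving-average
smoothing from 2500 Hz to 250 Hz (window 10 samples, shrinking at the
edges); conversion of extension to enzyme progress in bp (eWLC inversion
for the opposing layout; for the hairpin layout
`(x − x_handles(F)) / (2·x_nt(F))`, since each unwound bp releases two
nucleotides — inverting the hairpin extension through the dsDNA eWLC
would mis-scale velocities ~2.5-fold); OLS slopes in non-overlapping
100 ms windows with the window-mean force; a running median filter of
one-tenth the per-trace window count; and 0–60 pN force bins of 3 pN
(opposing) / 2 pN (hairpin).

Three estimator details matter and were verified against the analytic
surface:

* **Entry-force binning.** A window is assigned to a force bin by the
  force at its *start*. In a self-driven sweep the time spent near a
  force depends on the enzyme's own stochastic velocity, so binning by
  the window-mean force over-represents slow excursions (length-biased
  sampling); the entry force is fixed by the past and independent of the
  window's own fluctuation. The window-mean force is still what is
  reported per bin and used for model evaluation.
* **Median-filter edges.** The filter is applied only where the full
  window fits; edge windows pass through unfiltered. Shrinking or
  reflected edge windows drag the ends of a trending sequence toward its
  interior, biasing the first and last windows of every trace. Note the
  median filter intrinsically under-estimates velocities below about one
  step per window (δ/0.1 s ≈ 33 bp/s) when applied to long slow
  stretches, because the per-window slope distribution is then sharply
  peaked at zero; burst-like traces keep the filter length at 1–3 where
  this matters least.
* **Ensemble averaging.** Each trace's binned curve is computed first and
  the per-bin mean ± s.e.m. is taken across traces (trace-level values
  are independent; pooled windows are serially correlated through the
  median filter). The between-trace s.e.m. is floored by the pooled
  s.e.m. so that a handful of coincidentally similar traces cannot
  produce a near-zero error bar. Pooled averaging remains available.

Per-force Michaelis-Menten fits across [ATP] are weighted least squares
(`1/sem²`) via `scipy.optimize.curve_fit` with absolute errors; their 68%
intervals are calibrated (coverage 0.68 ± 0.1 in the self-check).

## Global fitting and model selection

Fitting minimizes the discrepancy between the binned velocities and the
scheme's analytic surface evaluated at each bin's mean in-bin force.
Rates are searched in log10 with bounds 1e-2–1e8 s⁻¹ (binding
1e3–1e9 M⁻¹s⁻¹), `δ ∈ [0.5, 10] bp` linear, `dG_dest ∈ [0, 5] kBT`;
multi-start via a scrambled Halton sequence (prefix property makes the
best-of-n objective monotone in n), default 50 starts (the validation
studies use 6–8, which the replicate checks show is sufficient at this
data size), `scipy.optimize.least_squares` (TRF). Identical seeds give
identical results. Parameter uncertainties by residual bootstrap (200
resamples, refit from the optimum).

Three sharing modes when both geometries are fitted: `joint` (all rates
shared), `separate` (all microscopic rates duplicated per context; step
size always shared), and `shared_chemistry` (chemical rates shared,
translocation rates per context). The default objective is the plain
unweighted SSE; a `1/sem²` chi-square is available (`weights="sem"`) and
is what the package's own validation studies use, because bin s.e.m.
ranges over ~1–40 bp/s and the unweighted estimator is badly inefficient
exactly where the ratchet parameters live (the slow, near-stalled bins).
Model selection fits all six schemes and ranks by the minimized
objective; the full ranking is always reported.

**Identifiability, measured.** Two structural degeneracies surfaced in
the replicate studies and are reported rather than hidden:

* With `K_eq ≫ 1` the hairpin dataset alone constrains only the product
  `K_M0·K_eq` (the crossover `K_eq/P_open ≈ 1` lies outside the data), so
  a fully `separate` two-context fit cannot recover the K_eq *ratio*.
  `shared_chemistry` pins `K_M0` from the opposing data and restores the
  contrast; it is also the parameterization matched to the hypothesis
  under test (the partner subunits shift the ratchet equilibrium, not the
  chemistry). A soft trade-off between `dG_dest` and the hairpin `K_eq`
  (both scale the low-`P_open` suppression as `e^{n·dG}`; only the
  saturation knee separates them) leaves the single-study ratio with a
  ~0.4 ln-unit spread, so the contrast study aggregates three replicate
  studies by geometric mean.
* `br-hydrolysis` is a near-degenerate runner-up to `br-binding`
  (objective margins 1.00–1.10 at the reference data size): rectification
  one step later produces almost the same force-dependence of `K_M`
  within the measured force range. Selection still ranks the generating
  scheme first in ≥90% of replicates; distinguishing the two decisively
  would need data deeper into the stalled regime.

## Validation studies and problem sizes

`ratchetfit.studies` packages the self-checks; `scripts/acceptance.py`
runs them all. Sizes were chosen to make each check statistically
meaningful at interactive runtimes: oracle equivalence over all
6 schemes × 2 geometries × 5×5 (F, [ATP]) cells with 200 clamped runs per
cell (~30 productive steps per run, expected events capped at 1e4/run so
that flip-flop-dominated ratchet cells stay tractable); closure with 10
traces per condition; recovery/selection with 8–10 replicate studies;
context contrast with 3 replicates of 20 traces per condition. The
3-s.e.m. agreement criteria are z-tests: with correct error bars ~0.3% of
cells fail by chance, and the observed rates (≥95% pass everywhere,
typically ≥98%) are consistent with that.

## Known limitations

* The auxiliary (non-catalytic) ATP sites of the real enzyme are absorbed
  into effective binding/unbinding rates; no explicit multi-site model.
* One motor, one strand: no two-subunit coupling, no ssDNA loop, no
  sequence-resolved stepping.
* The hairpin model treats `P_open` quasi-statically and ignores
  spontaneous full unzipping above the critical force.
* Dissociation kinetics are phenomenological (single Bell/constant
  off-rate) and used only to shape trace lengths.
* Closed-form logistic behavior of `v(F)` is exact for PS schemes and for
  BR schemes only in the fast-fluctuation, forward-loaded limit; outside
  it the ratchet's curve is not a pure logistic, which is precisely what
  the global fit exploits.
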