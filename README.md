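# ratchetfit

Mechano-chemical analysis of DNA helicases in passive-mode optical
tweezers: does the motor translocate by a **power stroke** or as a
**Brownian ratchet**, and which step of the ATPase cycle carries the
motion?

A translocating helicase runs the minimal cycle

    R + T  <=>[k+b, k-b]  R.T  -->[kh]  R.D.Pi  -->[kr]  R + D + Pi

advancing δ base pairs per turnover. Crossing the two mechanisms with the
three possible placements of the translocation step (with binding,
hydrolysis, or release) gives six candidate cycles. All six predict
Michaelis-Menten kinetics in [ATP], v = v_max·[T]/(K_M + [T]), but they
disagree on how force enters v_max(F) and K_M(F):

* against an opposing force the translocation rates pick up Bell factors
  exp(−F·x‡/kBT) and exp(+F·(δ−x‡)/kBT), shifting a ratchet's
  equilibrium constant as K_eq → K_eq·exp(F·δ/kBT) ≡ K_eq·exp(F/F0);
* with a DNA hairpin under tension ahead of the motor, force instead
  *assists* by opening the fork: the forward translocation rate is
  multiplied by P_open(F), the probability that at least one step's worth
  of base pairs is transiently unpaired.

The package implements the six cycles with exact steady-state solutions,
the fork/tether mechanics (extensible worm-like chain, freely-jointed
ssDNA, zipper P_open), an exact Gillespie simulator of passive-mode
traces (fixed traps, force re-solved after every step, 2,500 Hz
rendering with measurement noise), the standard trace-analysis chain
(250 Hz smoothing, contour conversion, 100 ms velocity windows, median
filter, 3/2 pN force bins with ensemble averaging), and multi-start
global fitting of all six schemes with SSE-ranked model selection. It is
aimed at single-molecule biophysicists who want to fit or simulate
force-velocity surfaces v(F, [ATP]) — the reference conditions emulate
the bacterial RecBCD helicase's fast subunit probed both inside the full
complex and in isolation.

## Worked example

Fit all six cycles to a simulated two-assay study (truth: Brownian
ratchet rectified by ATP binding, 200-fold ratchet-equilibrium shift
between contexts):

```
$ python examples/05_global_fit_and_selection.py
scheme ranking (best first, by the minimized chi-square):
  br-binding     chi2 =       55  SSE =     9425  R^2 = 0.9898
  br-hydrolysis  chi2 =       56  SSE =     9626  R^2 = 0.9895
  br-release     chi2 =      575  SSE =   107827  R^2 = 0.8829
  ...

best scheme: br-binding
  step size delta       = 3.21 bp
  effective catalytic   = 137 /s
  K_eq (in complex)     = 0.096
  K_eq (isolated)       = 64.1
  destabilization dG    = 1.18 kBT
```

The generating scheme wins; the fitted step size (truth 3.3 bp), the
in-complex K_eq (truth 0.1), and the catalytic rate (truth 130 s⁻¹) come
back close, while a single small study leaves the isolated K_eq with a
broad spread — the package's contrast study averages replicates for that
number. The logistic stall-force readout of the same conditions:

```
$ python examples/06_logistic_force_velocity.py
logistic fit to the simulated 2 mM force-velocity curve:
  v0     =    402.9 +- 16.3 bp/s
  F_half =     20.6 +- 0.4 pN
  F0     =     3.55 +- 0.17 pN (kBT/delta = 3.66 pN for the 3.3 bp truth)
```

F_half is the force at half-maximal velocity (an operational stall
force); F0 = kBT/δ ties the steepness of the decline to the step size.
The other examples cover the candidate cycles (01), force-dependent
Michaelis-Menten parameters in both assays (02), fork mechanics (03),
and trace simulation plus processing (04).

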