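# jargas

Desk-scale toolkit for automated anaerobic jar gassing systems — the
instruments that cultivate obligate anaerobes by cyclically evacuating a
sealed culture jar and refilling it with an anaerobic gas mixture, with a
Pd/Al2O3 catalyst sachet recombining residual O2 with H2 into water.

It is written for instrument engineers and catalysis-minded
microbiologists who want to reason quantitatively about such a system:
how fast the jar atmosphere becomes anaerobic, what the palladium surface
is doing, and how to reconcile a first-principles rate model with what
the instrument's pressure sensor actually measures.

## What it computes

* **Gas exchange** — each evacuation-replacement cycle retains
  `(P_atm - P_vac) V / (R T)` moles of jar atmosphere and adds
  `P_vac V / (R T)` moles of cylinder gas; the jar mole-fraction vector
  follows `x(c+1) = (n_ret x(c) + n_add x_cyl)/(n_ret + n_add)` with a
  mass-fraction readout.  Air reaches 4.953% O2 after one cycle of the
  reference jar and ~0.2% after three.
* **Pd(111) microkinetics** — a six-step Langmuir-Hinshelwood mechanism
  (dissociative O2/H2 adsorption by Hertz-Knudsen collision theory,
  TST surface steps, irreversible H2O desorption) solved as a stiff
  mean-field coverage ODE to steady state, with turnover frequency,
  Campbell degree-of-rate-control (DRC) coefficients, apparent activation
  energy `-R dln(TOF)/d(1/T)` and gas reaction orders.
* **TOF estimation** — catalyst-test pressure loss to moles of condensed
  water (`dn = dP V/(R T)`) and turnover frequency (`TOF = dn/dt`), and
  the measured Arrhenius curve `k_system(T)` through the test point and a
  292 K reference rate on a 0.5 K grid.
* **Extremum seeking** — a discrete cosine-dither optimizer that tunes
  `(E_act, beta)` of `k(T) = beta exp(-E_act/RT)` to minimize the RMSE
  against `k_system`, gradient-free and fully deterministic.
* **Scherrer sizing** — `L = K lambda/(beta cos theta)` for XRD peaks of
  the catalyst pellets.

## Worked example

```python
import jargas as jg

# jar atmosphere over three evacuation-replacement cycles
traj = jg.simulate(jg.reference_config(), jg.AIR, 3)
print([round(100 * s.composition["O2"], 3) for s in traj.states])
# [23.195, 4.953, 1.046, 0.22]  (mass-% O2; cycle 0 is air's mass readout)

# what the palladium surface is doing at lab temperature
model = jg.build_reference_model()
state = jg.steady_state(model, jg.reference_conditions(295.15))
print(state.dominant_species, round(state.coverages["H*"], 3))
# H* 0.733   (hydrogen blocks the surface; TOF 8.67e-4 per site per s)

# measured turnover of catalyst test 4, and its Arrhenius identification
from jargas.io import packaged_test_log
test = packaged_test_log()[3]
tof = jg.turnover_frequency(test).tof           # 1.2252e-05 mol/s
k_sys = jg.build_k_system(tof, test.t_tof, 8.38e-6)
fit = jg.fit_arrhenius(k_sys, jg.ArrheniusParams(95535.0, 1.03e13))
print(fit.converged, fit.iterations, f"{fit.final_cost:.2e}")
# True 106346 1.00e-04
```

The fit drives the model curve within the 1e-4 RMSE termination band of
the measured curve; the (E_act, beta) pair reaching it is not unique
(Arrhenius compensation over the narrow 291-310 K window), so judge the
fit by the curve, not the parameters.

The same analyses are available from a shell:

```sh
jargas simulate-exchange --cycles 3 --out traj.csv
jargas estimate-tof --out tof.csv
jargas fit-es --test-id 4 --out fit.json
jargas scherrer --two-theta 38.3253 --fwhm 0.2431
# L = 36.134 nm = 361.34 angstrom
jargas synth-log --seed 7 --out synthetic.csv
```

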