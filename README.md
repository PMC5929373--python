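# ehkin — branched-scheme kinetics of epoxide hydrolase catalysis

Potato epoxide hydrolase (StEH1) hydrolyses *trans*-disubstituted epoxides
through a covalent alkylenzyme intermediate.  Because the catalytic aspartate
can attack either oxirane carbon (benzylic C1 or homobenzylic C2), the
mechanism is *branched*: two Michaelis-complex conformers (ES, E′S) feed two
non-interconvertible alkylenzymes whose hydrolyses release the two product
diol enantiomers.  Which branch carries the flux — and therefore the
regioselectivity and enantiomeric excess of the product — is decided by the
interplay of the microscopic rate constants, not by binding alone.

`ehkin` is a small library (plus CLI) for kineticists working on this class
of enzymes.  It provides:

* **`scheme_model`** — the branched mechanism as a mass-action ODE system
  (E ⇌ E′, E+S ⇌ ES ⇌ E′S, alkylation k₂/k₋₂, lumped hydrolysis k₃, conformer
  exchange k₅/k₋₅), analytic steady-state parameters of the reduced linear
  scheme (kcat = k₂k₃/(k₂+k₋₂+k₃), Km = K_S(k₋₂+k₃)/(k₂+k₋₂+k₃)), relaxation
  (eigenvalue) analysis under pseudo-first-order conditions, and the Eyring
  relation ΔG‡ = RT·ln(k_B T/(h k)) in both directions.
* **`transient_fitting`** — the stopped-flow analysis pipeline: single/double
  exponential fits with floating endpoint (multistart + Levenberg–Marquardt),
  extra-sum-of-squares F-test order selection, hyperbolic
  k_obs(S) = k₂S/(K_S+S) + (k₋₂+k₃) and decreasing two-step
  k_obs(S) = k_lim + k_rev/(1+S/K_app) regressions, microscopic-rate
  extraction from (k₋₂+k₃) and kcat with delta-method errors, and
  single-turnover hydrolysis-rate determination.
* **`flux_prediction`** — branch flux fractions fᵢ = e^(−ΔGᵢ‡/RT)/Σⱼe^(−ΔGⱼ‡/RT)
  from activation free energies of the committing (hydrolysis) step,
  cross-checked by integrating the full ODE scheme to substrate exhaustion;
  regioselectivity (% C1) and enantiomeric excess.
* **`synthetic_data`** — generators for every input the pipeline consumes
  (noisy averaged fluorescence-quench traces, k_obs series, initial-rate
  tables) plus packaged fixtures with the published rate constants of
  wild-type StEH1 and four laboratory-evolved variants against both
  enantiomers of *trans*-methylstyrene oxide (**1a**) and *trans*-stilbene
  oxide (**1b**), and the published simulated free-energy barrier sets.

## Worked example

Simulate a wild-type multiple-turnover stopped-flow experiment at 1500 µM
(S,S)-**1a**, fit the transient, and predict the product distribution:

```python
from ehkin import (kinetic_fixture, ReactionConditions, NoiseModel, gen_trace,
                   fit_trace_auto, eyring_barrier, steady_state_params,
                   barrier_fixture, branch_fractions_from_barriers)

rates = kinetic_fixture("wild_type", "SS-1a").rate_set()
cond = ReactionConditions(E_total=4.0, S_total=1500.0)
trace = gen_trace(rates, cond, NoiseModel(sigma=0.02, seed=7))
fit, sel = fit_trace_auto(trace)
print(sel.order, fit.k_obs)

print(steady_state_params(370, 170, 110, 470).kcat)
print(eyring_barrier(370), eyring_barrier(110))

pred = branch_fractions_from_barriers(barrier_fixture("wild_type", "SS-1a"))
print(pred.regioselectivity, pred.ee)
```

prints (abridged):

```
chosen order: 2 (F = 269468)
k_obs,1 = 568 ± 2 s⁻¹
k_obs,2 = 17.7 ± 0.0 s⁻¹
kcat from micro rates: 62.6 s⁻¹ (measured 63 ± 3)
ΔG‡(alkylation) = 14.2 kcal/mol,  ΔG‡(hydrolysis) = 14.9 kcal/mol
C1 flux fraction: 0.9993 → regioselectivity 99.9% C1, ee 99.9%
```

The two fitted observed rates are the relaxation eigenvalues of the branched
scheme (the fast phase is alkylenzyme formation/decay, the slow phase the
Michaelis-complex interconversion); the turnover number recomputed from the
microscopic rates matches the measured one; and the 4.4 kcal/mol gap between
the two hydrolysis barriers makes attack at the benzylic carbon effectively
exclusive — one diol enantiomer from two coexisting alkylenzymes.

The same stages are scriptable from a shell:

```sh
ehkin report --variant wild_type --substrate SS-1a
ehkin gen-data --variant wild_type --substrate SS-1a --what trace --out trace.csv
ehkin fit-trace --trace trace.csv
ehkin predict-flux --variant wild_type --substrate SS-1a
```

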