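# Methods

## The kinetic model

The scheme is a branched extension of the three-step hydrolase mechanism.
Nine species are tracked: free substrate S, two free-enzyme conformers E and
E′, their Michaelis complexes ES and E′S, the two covalent alkylenzymes EA
and E′A, and the two product diol pools P1 and P2.  Reactions:

* E ⇌ E′ — a substrate-independent conformational step (k₀, k₋₀, s⁻¹);
* E + S ⇌ ES and E′ + S ⇌ E′S — binding, realized explicitly with a shared
  association rate k_on (µM⁻¹ s⁻¹) and k_off = k_on·K_S (resp. k_on·K_S′);
* ES ⇌ E′S — interconversion of the Michaelis complexes (k₅, k₋₅);
* ES ⇌ EA and E′S ⇌ E′A — alkylation/de-alkylation (k₂, k₋₂ and primed);
* EA → E + P1 and E′A → E′ + P2 — hydrolysis lumped with product release
  (k₃, k₃′).  The alkylenzymes do not interconvert directly.

The tetrahedral-intermediate substeps of hydrolysis are not resolved: the
decomposition of that intermediate is far faster than its formation, so k₃
operationally covers everything from attack of the catalytic water to
product release.  No pH or temperature dependence is modelled beyond the
Eyring relation.

**Rapid equilibrium as an emergent property.**  The experimental analysis
treats binding as a pre-equilibrium characterized by K_S alone.  Rather than
hard-coding that assumption, the ODE realizes binding with a finite
k_on (default 1000 µM⁻¹ s⁻¹, near the diffusion limit), so the rapid-
equilibrium limit is something the model *exhibits* (and the tests verify —
the slowest chemistry relaxation matches the hyperbolic k_obs expression to
<1% when binding is ≥100-fold faster than chemistry) rather than something
it presumes.

**Defaults for unreported parameters.**  K_S′ (binding to E′) is never
measured and defaults to K_S.  Only the sum k₅+k₋₅ is measurable (from the
decreasing substrate dependence of the slow transient phase); it is split
50/50 into k₅ = k₋₅ by default — a documented convention, not a measurement.
The free-enzyme conformer step is likewise only observable as a sum; k₀ =
k₋₀ = 0 by default (single free conformer) unless set.  The experimental
literature attributes the decreasing k_obs phase sometimes to k₀+k₋₀ and
sometimes to k₅+k₋₅; the decreasing-fit routine therefore returns a neutral
"S→0 intercept" and leaves the labelling to the caller.

**Integration.**  `scipy.integrate.solve_ivp` with LSODA and an analytic
Jacobian; rtol 1e-8, atol 1e-10 µM (the rates span ~10⁻² to 10⁶ s⁻¹ once
binding is explicit, so the system is stiff).  Enzyme and substrate mass
balances are checked on every trajectory and reported as residuals; the test
suite requires ≤1e-6 relative.  Integration failures raise; NaNs are never
returned silently.

## Transition-state analysis

ΔG‡ = RT·ln(k_B T/(h k)) with transmission coefficient 1,
R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, and the assay temperature 303.15 K as
default.  The inverse (rate from barrier) is exact to machine precision in
round-trip, which the property tests pin down.  Derived barriers are
conventionally reported to 0.1 kcal/mol.

## The fitting pipeline

**Exponential fits.**  F(t) = endpoint + Σᵢ Aᵢ e^(−k_obs,i·t), order 1 or 2.
Starting values come from a variable-projection grid search: candidate rates
log-spaced 4 per decade over 10⁻²–10⁴ s⁻¹ (pairs of candidates for order 2),
amplitudes and endpoint solved by linear least squares at each candidate,
best SSE polished by Levenberg–Marquardt (lmfit).  Parameter standard errors
come from the regression covariance.  Fits flag near-zero amplitudes and
rates with SE exceeding the estimate; points before the instrument dead time
(default 2 ms in generated data) are excluded.

**Order selection.**  Extra-sum-of-squares F-test,
F = ((SSE₁−SSE₂)/Δdf)/(SSE₂/df₂), with α = 0.05 by default (configurable;
the source analysis states no α).  Its type-I error is verified empirically
(≈0.04 at α = 0.05 over 500 synthetic single-phase traces — the test is
mildly conservative for nonlinear models, as expected).  The F-test alone
will, on very clean data, accept a *degenerate* second phase — two nearly
equal rates or a vanishing amplitude absorbing tiny systematic curvature —
so the convenience `fit_trace_auto` additionally requires the two rates to
differ by ≥3× and each phase to carry ≥5% of the total amplitude, the
practical resolvability limit for sums of exponentials.

**k_obs regressions.**  Hyperbolic (k₂, K_S, intercept k₋₂+k₃) and
decreasing two-step (k_lim, k_rev, K_app; intercept = k_lim+k_rev at S→0)
forms, inverse-variance weighted when the series carries standard errors.
A series trending the wrong way is redirected to the other model with an
explicit error.  When K_S exceeds the sampled concentration range the
extrapolation inflates the k₂/K_S standard errors; this is flagged, not
rejected — it is exactly the behaviour of the real data, where solubility
caps the range.

**Microscopic-rate extraction.**  With s = k₋₂+k₃ from the intercept and the
measured kcat, k₃ = kcat·(k₂+s)/k₂ and k₋₂ = s − k₃ (the inversion of the
steady-state kcat expression).  Feeding the result back through the kcat
formula reproduces the input exactly, by construction; the tests assert this
as an identity.  Standard errors propagate by the delta method assuming
independent inputs; no bootstrap by default.  A negative implied k₋₂ is
flagged, never silently clipped.

**Single-turnover k₃.**  With [E], [S] ≫ K_S and [E] ≥ [S], all substrate is
bound, the alkylation burst completes early, and the fluorescence recovery
is fitted with one exponential from the quench minimum (after discarding one
lifetime of a first-pass estimate to avoid fast-phase mixing).  A caveat the
implementation makes explicit: the recovery decays at the slow eigenvalue of
the committed ES ⇌ EA → E+P subsystem,
λ = (σ − √(σ² − 4k₂k₃))/2 with σ = k₂+k₋₂+k₃, which equals k₃ only when
k₂ ≫ k₋₂, k₃.  For the stilbene-oxide parameter sets (k₂ ≈ 6×k₃) the
identification k_obs ≈ k₃ is ~20% low, so tests validate the recovered rate
against λ, and the saturation sweep (1×–20× K_S) is checked for monotone
approach to it.  Published single-turnover k₃ values should be read as
observed recovery rates in exactly this sense.

## Flux prediction

Two routes, deliberately independent:

1. **Boltzmann partition** over the activation free energies of the
   committing step: fᵢ = e^(−ΔGᵢ‡/RT)/Σⱼ e^(−ΔGⱼ‡/RT).  The committing step
   defaults to hydrolysis — for this enzyme hydrolysis is rate-determining
   and the alkylenzymes can drain back to the (exchanging) Michaelis
   complexes — but alkylation-committed partitioning is available for the
   regime where ring opening is irreversible.
2. **ODE committed flux**: barrier-derived rate constants integrated to
   ≥99.9% substrate conversion; fractions are the final P1/P2 split.

When realizing a barrier set as rate constants, the alkylenzyme stability is
set to a common shallow −2 kcal/mol on both branches.  This is a deliberate
modelling choice: the simulated (EVB) reaction free energies for ring opening
are known to be unphysically exothermic (the source analysis itself treats
the two steps' energetics separately for this reason), and a deep alkylenzyme
well would freeze the branch ratio at the alkylation step, contradicting the
measured k₋₂ > k₃ ordering.  With the shallow well, de-alkylation outpaces
hydrolysis, the alkylenzymes pre-equilibrate, and the ODE route agrees with
the Boltzmann partition to <0.1 percentage points (the test bound is 1 point,
valid whenever hydrolysis barriers exceed alkylation barriers by ≥2 kcal/mol
and conformer exchange is not rate-limiting).

Regioselectivity is reported as % flux through the branch labelled C1; the
mapping from branch label to diol enantiomer is configuration, not inference
(the S_N2 inversion makes it 1:1 for these substrates).  Enantiomeric excess
is |f₁−f₂|/(f₁+f₂)×100.  Barrier standard errors propagate to fraction
intervals by seeded Gaussian resampling (10⁴ draws).

## The synthetic-data generator

The generator emulates stopped-flow fluorescence-quench experiments: the
signal is F(t) = F₀ − q·(EA+E′A)/E_tot (the alkylenzymes quench the
intrinsic protein fluorescence; whether the Michaelis complexes also quench
is untested experimentally, so a q_complex term exists but defaults to 0).
F₀ = 1 and q = 0.3 are arbitrary — no absolute fluorescence scale is
published — and q multiplies *occupancy* so the signal is independent of the
enzyme load.  Noise is additive Gaussian, expressed relative to the trace's
peak-to-trough amplitude (so "1% noise" means SNR 100 at any concentration);
the default σ = 5% gives single-trace SNR 20 and ≈50 after the standard
six-trace average.  Averaging n replicate traces is verified to shrink the
residual s.d. by √n.  Everything is deterministic per seed.

Sampling: 1000 log-spaced points from the 2 ms dead time to ten lifetimes of
the slowest relaxation eigenvalue.  Two regime-specific corrections matter:

* **Multiple turnover** — the window is capped where ~10% of the substrate
  would be consumed, because the exponential description (and the eigenvalue
  oracle) presumes constant [S].  For the same reason the k_obs-series
  generator defaults to E = min(S)/100, far below the E ≤ S/10 floor that
  defines pseudo-first-order conditions; occupancy-normalized quench means
  the lower enzyme load costs no signal.
* **Single turnover** — the recovery is *driven by* substrate exhaustion, so
  the clamped-[S] relaxation analysis cannot set the window; the committed-
  subsystem eigenvalue λ above does.

What the generator does *not* emulate: photobleaching, mixing artifacts,
conformer-specific spectral differences, pipetting error between
concentrations, or day-to-day instrument drift.  Passing the recovery tests
therefore shows the pipeline is a consistent estimator under the model's own
noise, not that real data of this quality would give errors this small.

The packaged fixtures (`data/rate_tables/`, one YAML per enzyme-variant /
substrate-enantiomer pair) carry only values actually published; dashes,
"not saturating", "too fast" and upper bounds are encoded as qualifiers and
raise on access.  Nine of the twenty rows carry the complete microscopic
rate set needed to simulate.  `data/barriers/` holds the published simulated
(EVB) barrier sets for wild type and the first evolved variant with both
methylstyrene-oxide enantiomers; these are consumed as inputs and never
recomputed here.

## Problem sizes used in the test suite

Acceptance-level checks run at desk scale: the eigenvalue-agreement sweep
covers all nine complete fixtures at S = 2·K_S; the full-pipeline recovery
uses 12 concentrations spanning 30–1500 µM with 6-trace averages at 1%
relative noise and a fixed seed; the F-test calibration uses 500 synthetic
traces of 250 points; flux cross-validation integrates to ≥99.9% conversion
of 100 µM substrate.  These sizes were chosen so each statistical assertion
has comfortable power while the whole suite stays interactive.

## Known limitations

* The steady-state Km predicted from K_S·(k₋₂+k₃)/(k₂+k₋₂+k₃) disagrees with
  the independently measured Km for the wild-type (S,S)-methylstyrene-oxide
  reaction (≈202 vs 77 µM); the source data do not reconcile the two, and no
  derived quantity here relies on that identity.
* The 50/50 split of k₅+k₋₅ and the −2 kcal/mol alkylenzyme stability are
  conventions; conclusions that depend on them (slow-phase amplitudes, ODE
  flux with barrier-derived rates) should be read accordingly.
* Fit standard errors are asymptotic (covariance-based); for strongly
  correlated parameters (k₂, K_S under extrapolation) they understate the
  skew of the sampling distribution.
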