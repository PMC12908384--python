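# Methods

## Population model

The full model tracks radiation-sensitive tumour cells (S), radiation-
resistant tumour cells (R), and natural-killer cells (N) in a co-culture
well:

```
dS/dt = r_S S (1 − (S + α_SR R)/K_S) − λ_SN S N
dR/dt = r_R R (1 − (R + α_RS S)/K_R) − λ_RN R N
dN/dt = r_N N (1 − N/K_N)
```

Assumptions: both tumour types grow logistically against their own carrying
capacity, with cross-type crowding entering through the dimensionless
competition coefficients α_SR (effect of R on S) and α_RS; NK cells kill each
tumour type at mass-action rates λ_SN, λ_RN and grow logistically with **no
feedback from the tumour populations** — there is no tumour→NK stimulation or
NK exhaustion term. That independence makes the N channel a closed-form
logistic, which the solver exploits (below). Radiation is not modelled as an
explicit dose term in the full model: each treatment arm (untreated, RT, NK,
RT+NK) simply carries its own fitted rate parameters.

### Units

Time is in hours (the assay images every 6 h) and all rates are per hour.
Abundances are in units of 10⁵ cells, which puts the NK carrying capacity at
K_N = 1 and tumour capacities at order 1; the 2000-cell tumour seed is 0.02
in these units. The NK kill rates are per (unit N · hour). Only the products
λ·N are identifiable from tumour counts, so fixing K_N = 1 sets their scale
without affecting signs.

### Parameters and bounds

| parameter | meaning | bounds | default handling |
|---|---|---|---|
| r_S, r_R, r_N | intrinsic growth rates (per h) | [0, 1] | fitted; r_N ≡ 0 in no-NK arms |
| K_S, K_R | carrying capacities (10⁵ cells) | (0, 10] | fitted in the untreated arm, then fixed |
| K_N | NK carrying capacity | — | fixed at 1 |
| α_SR, α_RS | competition coefficients | [−15, 15] | fitted (negative = facilitation) |
| λ_SN, λ_RN | NK kill rates (per unit N·h) | [−15, 15] | fitted in NK arms, else ≡ 0 |

The interaction bounds deliberately admit negative values: a negative α is
facilitation rather than competition, and the fitted confidence ranges can
straddle zero.

## Synthetic co-culture generator

The generator emulates the live-imaging competition assay: wells seeded with
2000 tumour cells at resistant fractions f ∈ {0, 0.1, 0.25, 0.5, 0.75, 0.9,
1}, counts for the two fluorescence channels every 6 h for 150 h (26 time
points), 12 replicates, four treatment arms, and — in NK-containing arms —
NK cells at a 5:1 effector:target ratio, giving N(0) = 0.1 in 10⁵-cell
units. The two tumour channels are observed; N(t) never is.

Observation noise is multiplicative lognormal, unit mean, with coefficient
of variation 0.10 applied independently per observation: imaging counts have
roughly proportional error and must remain nonnegative. Fits consume
unnormalised counts (normalising by the t = 0 value is treated as a plotting
convention only).

What the generator does **not** emulate: well-position and edge effects,
segmentation errors that correlate across time within a well, cell-cycle
synchronisation after irradiation, and any tumour→NK feedback. Passing the
recovery tests therefore shows the inference machinery is correct and
well-conditioned under the stated design and noise law — not that the model
is identifiable under arbitrary real-data pathologies.

## Staged fitting

A "fitting batch" is one replicate: residuals (model − observation,
unweighted, both channels equally) are concatenated over all seven fractions
and 26 time points (364 values) and minimised by trust-region-reflective
bounded least squares. Carrying capacities are weakly identified once
treatment suppresses growth, so fitting is staged:

1. **Untreated** per replicate, free: r_S, r_R, K_S, K_R, α_SR, α_RS
   (NK terms zeroed).
2. **Treated arms** per replicate with K_S, K_R fixed at the untreated
   across-replicate means. RT frees the growth rates and α's; NK and RT+NK
   additionally free r_N, λ_SN, λ_RN.

Each fit starts from a data-driven heuristic — the log-linear early slope of
the purest available well per channel for rates, its observed plateau for
capacities, generic magnitudes (α = 1, λ = 0.05, r_N = 0.02) for
interactions — plus multiplicative lognormal jitter in ×[0.5, 2] for the
remaining multistarts (8 by default; the best loss is kept, and more starts
can never worsen it). Summaries report the across-replicate mean and
SEM = sd/√n over converged replicates; nonconverged replicates are dropped
with a warning, and fixed parameters are reported with zero SEM.

Holdout validation splits replicates into train/validation sets, fits on the
training side, and scores the mean parameters on held-out replicates.

## Double-bind diagnostics

Per arm: the score λ_RN − λ_SN (positive ⇔ NK preferentially kills the
resistant type), its dispersion computed per replicate and then summarised
(not from the parameter means alone), the cost of resistance r_S − r_R, and
the interaction class of (α_SR, α_RS) with a dead zone of ±0.05 around zero
(the published quadrant plot draws no explicit dead zone; 0.05 is small
against every fitted α here). Sign convention: positive α inside
(· + α·)/K is suppressive, so both > tol is competition, both < −tol is
mutualism, and one-sided suppression is named after the *suppressed*
population (α_SR > tol alone ⇒ sensitive antagonism).

## Reduced model

For treatment-design intuition the model is reduced to shared-capacity
logistic growth with a radiation effect δ, kill rate λ, and double-bind
parameter B:

```
dS/dt = r_S (1 − δ·rt) S (1 − (S + R)/K) − λ S (1 − B)·nk
dR/dt = r_R           R (1 − (R + S)/K) − λ R B·nk
```

B routes the kill effect: B = 0 targets only sensitive cells, B = 1 only
resistant cells. One published rendering of the resistant-cell kill term
reads λ·S·B; since B is defined as re-targeting the kill effect toward
resistant cells (and strong binds visibly suppress R), the per-capita
reading λ·R·B is the default here, with the literal variant available
behind a `literal_eq5` flag for auditability. The cost fraction c enters
only as a constructor for r_R = r_S(1 − c).

Sweeps use λ = 0.05 per hour and K = 10⁵ cells with, by choice (the source
figures print neither), a 500 h horizon and 1000 seeded cells at 10%
resistant; treatment flags are constant within a run (continuous dosing),
and sequential schedules are composed by chaining runs with state handoff.
δ > 1 is meaningful: the net sensitive growth rate goes negative, i.e.
radiation kills rather than merely slows. The definitional limits (B = 0
leaves the R equation without any NK term; B = 1 likewise for S) are exact
at the rate level for every state; as trajectories they are exact only where
the crowding term does not couple the populations, which the tests realise
with K ≫ S + R.

## Numerical choices

* Integration: adaptive explicit Runge–Kutta (RK45), rtol 10⁻⁸, atol 10⁻¹⁰,
  evaluated on the experimental grid; values driven marginally negative by
  solver error are clipped to zero.
* During fitting, N(t) is evaluated with the logistic closed form and only
  (S, R) are integrated, stacked across the seven fractions in one solve;
  a test asserts this path agrees with the full three-species integration.
* Optimiser: `scipy.optimize.least_squares` (TRF) with ftol = xtol = gtol =
  10⁻¹², Jacobian-based scaling; bounds as in the table above, with the
  capacity lower bound at 10⁻³ (100 cells) to keep the box finite.
* Ties and degenerate inputs: empty wells (f = 0 or 1) contribute one
  all-zero channel and are the purest rate/capacity information; a dataset
  without the untreated arm cannot be staged and is rejected.

## Problem sizes

The bundled analyses and tests use the full experimental design (4 arms ×
7 fractions × 12 replicates × 26 time points) for generation and the noisy
recovery check, with 2 multistarts per fit — on this synthetic design the
data-driven heuristic start converges to the global optimum reliably, and
the full 8-start default is exercised in the self-consistency script.
Noiseless self-consistency runs use a single replicate, since without noise
all replicates are identical.

## Known limitations

* No tumour→NK feedback: likely present in reality (tumour cells stimulate
  NK proliferation) and acknowledged as a model limitation.
* λ and r_N share a mild ridge — only λ·N(t) enters the tumour equations —
  so NK-arm kill/growth estimates carry wider tolerances (5%) than the
  untreated parameters (1–2%) even noiselessly.
* The observation-noise law is chosen, not measured; real imaging error is
  likely autocorrelated within wells.
* The reduced model's B is phenomenological; it does not map mechanistically
  onto ligand expression.
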