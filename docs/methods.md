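# Methods

## The model

Relative retinal function is modelled as the sum of an oxygen-consumption
term and a mechanical-stress term, clamped below at zero:

```
ERG%(F, IOP) = max(0, F·OER(F) + IOP_M(IOP))
OER(F)       = a·exp(b·F) + 1 − a·exp(100·b)
IOP_M(IOP)   = 0                for IOP ≤ t
             = m·(IOP − t)      for IOP > t
```

All flow/ERG/pO₂/consumption quantities are percentages of the baseline
operating point (IOP 10 mmHg, MAP 93 mmHg ⇒ OPP 83 mmHg), so 100 means
baseline; OER is a fold change with baseline 1.  These conventions are
converted only at module boundaries — mixing them is the chief bug risk in
this problem, so every public function documents its scale.

Modelling assumptions worth keeping in mind:

- Arterial oxygen content is constant during the acute challenge, so oxygen
  delivery is proportional to flow and consumption reduces to `F·OER(F)`.
- The OER–flow law is pinned exactly through (100 %, onefold); its vertical
  span is `a` and the flow increment halving the exponential term is
  `−ln2/b` (≈ 37 % flow at the calibrated `b`).
- Mechanical stress depends on IOP only — not on MAP or flow — so a single
  hinge applies to every blood-pressure arm.
- Measured relative blood flow is an *input* to the ERG model.  The model
  never predicts flow from pressure; a flow–OPP curve exists only inside
  the synthetic-data generator.
- Negative predicted amplitudes are unphysical, hence the clamp at 0 %.
  There is no upper clamp: hyperperfusion simply drives `OER` below onefold
  and consumption back toward ~100 %.

### Parameters

| name | meaning                              | units        | calibrated default |
|------|--------------------------------------|--------------|--------------------|
| a    | OER responsiveness (vertical span)   | fold         | 4.03               |
| b    | OER exponential decay rate           | per % flow   | −0.019             |
| t    | mechanical-stress threshold          | mmHg         | 50.0               |
| m    | mechanical-stress slope above t      | % ERG / mmHg | −0.70              |

Validity domain enforced by `ModelParams`: `a > 0`, `b < 0`, `t ∈ [10, 120]`,
`m ≤ 0`.  The calibrated defaults (`TABLE1_PARAMS`) are the best-fit vector
obtained on high-blood-pressure pressure-challenge data, and are used as the
generating truth of the synthetic cohorts and the fixed parameters of the
prediction (cross-cohort) modes.

## Fitting

`fit_model` minimises the sum of squared ERG residuals over the box
`a ∈ (0, 20], b ∈ [−0.2, 0), t ∈ [10, 120], m ∈ [−5, 0]` (open edges closed
by ε = 1e−9).  The hinge at `t` makes the objective only piecewise smooth,
so the fit is a multi-start procedure: 16 Latin-hypercube start points by
default, each solved with bounded trust-region least squares
(`scipy.optimize.least_squares`, trf, tolerances 1e−14), keeping the
lowest-SSE solution with ties broken by the smaller parameter norm.
Records are sorted internally, so results are exactly independent of input
order.  On noise-free staircase data this recovers the generating vector to
machine precision; on an 8-record noisy instance it matches or beats an
exhaustive 36.7-million-point lattice search of the same box.

`t` is flagged `t_at_bound` when the fitted threshold sits on the box edge
or no record's IOP exceeds it — in either case the data carry no information
about the mechanical component and the threshold value should not be
interpreted.

## Bootstrap confidence intervals

95 % intervals are percentile (2.5/97.5) over `n_boot` replicates
(default 1000), with case resampling of records as the default —
robust to heteroscedastic ERG noise — and residual resampling available.
Replicates that fail to refit are dropped and counted; more than 20 %
dropped raises a warning.

Replicate refits warm-start at the full-data optimum *and* at the optimum
with the threshold shifted down/up by 1.5× the median IOP spacing of the
data.  This matters: the SSE profile in `t` has knots at the observed IOP
values, and a single warm start stays trapped in the full-data knot
interval, understating the replicate spread of `t`.  With single warm
starts, simulated coverage of the 95 % interval for `t` was ≈ 88 % at the
generator's default conditions; with the threshold-perturbed starts it is
≈ 93–95 % for all four parameters (measured over independent simulated
cohorts).  Full multi-start replicate refits give no further benefit at
many times the cost.

## Goodness of fit

`chi_square_gof` computes `χ² = Σ((obs − pred)/SEM)²`,
`Q = Q(df/2, χ²/2)` (regularised upper incomplete gamma), with
`df = n − 4` when the four parameters were fitted to the same data and
`df = n` in pure-prediction mode.  Grades follow the conventional cutoffs —
poor below 0.001, acceptable from 0.001 through 0.1 (both boundaries
inclusive), good above 0.1 — exposed directly as `grade_q`.

Two caveats discovered by simulation and worth knowing when grading real
data:

- **Errors in variables.**  Measured flow is the model's input, so its
  measurement noise propagates into the prediction.  Judging predictions
  against the ERG SEM alone is over-dispersed; `prediction_sem` returns
  `sqrt(SEM_erg² + (∂ERG/∂F)²·SEM_flow²)` and should be used for
  prediction-mode χ² whenever flow SEMs are available.
- **Estimated SEMs.**  With SEMs estimated from n animals, the squared
  standardised residual has expectation (n−1)/(n−3), not 1 (about 5/3 at
  n = 6), so Q is conservative-to-poor even for a correct model at small n.

## Derivation of putative OER and IOP_M

With pO₂, flow and ERG recorded simultaneously and normalised to the
IOP = 10 baseline, treating tissue pO₂ as a surrogate for oxygen consumption
(extracted oxygen fully utilised, no lag or diffusion correction) gives
`OER = pO₂/F` and `IOP_M = ERG − pO₂`.  The baseline record maps to (1, 0)
by construction.  Points with flow ≤ 2 % of baseline are flagged and carried
as NaN rather than dropped: the ratio diverges as flow vanishes, and real
recordings show no usable points there.  Noise can make derived IOP_M
slightly positive; values are reported unclipped and consumers decide.
On noise-free synthetic data the derivation reproduces the generating OER
and stress curves pointwise to machine precision — the idealised form of the
agreement the simultaneous-measurement experiment tests.

## Synthetic cohorts

The generator emulates the acute pressure-challenge protocol: IOP stepped
10→120 mmHg in 5 mmHg increments (23 steps) with MAP clamped at 159, 104 or
61 mmHg, n = 6 animals per arm by default (11 in the simultaneous-measurement
configuration used in the derivation examples/tests).

- **Flow–OPP curve**: piecewise linear with an autoregulatory plateau at
  OPP 50–90 mmHg (MAP 60–100 at baseline IOP), declining linearly to zero
  flow at OPP 0 and rising at 1.7 %/mmHg above the plateau, normalised to
  100 % at the OPP-83 reference.  The default slope puts the high-MAP arm
  near 200 % flow at its baseline, the hyperperfusion characteristic of
  acute hypertension.  Anchors are configurable per cohort.  The curve is
  a deliberately simple stand-in: real pressure-challenge flow at high IOP
  falls toward zero even at high MAP, faster than an OPP-linear decline.
- **Channels**: true flow from the curve; pO₂ as the model-implied
  consumption of the true flow; ERG from the full model.  Additive Gaussian
  noise (default SD 8 percentage points per channel — the magnitude of
  typical between-animal SEM bars at n ≈ 6) is applied per animal and
  truncated at zero; pO₂ noise is applied after the consumption mapping
  (sensor noise, not physiological noise).  Group means with
  SEM = SD/√n accompany the per-animal records.
- The zero-truncation matters at low MAP: once OPP ≤ 0 the channels pile up
  at the floor and group means are biased upward, which is why frozen-model
  grades degrade on the low-pressure arm (mirroring the marginal Q values
  such cohorts produce in practice).

What passing tests on these cohorts does **not** show about real data: the
generator has no within-step dynamics, no drug-specific vasoactive effects,
no recovery phase, no retinal/choroidal separation, homoscedastic noise,
and a flow–OPP shape chosen for structural plausibility rather than fitted
to measured traces.

## Problem sizes and numerical choices

- Parameter-recovery and bootstrap experiments use the full 23-step
  staircase; the Monte-Carlo coverage check uses 200 simulated cohorts with
  200 bootstrap replicates each, and the optimizer-vs-grid check enumerates
  the bounds box at lattice spacing (0.25, 0.002, 2.5, 0.05).
- All stochastic stages derive child seeds from a single top-level seed via
  `numpy.random.SeedSequence`; identical seeds give byte-identical cohorts
  and bit-identical fits.
- Degenerate inputs: empty record lists predict to empty arrays; SEM ≤ 0 or
  df ≤ 0 raise; a baseline ≤ 0 cannot be normalised and raises; a cohort of
  one animal emits NaN SEMs.

## Known limitations

- The hinge makes `t`'s sampling distribution lumpy at the data's IOP
  spacing; at 5 mmHg steps, sub-millimetre claims about the threshold are
  not supported.
- Percentile intervals (chosen for simplicity) are first-order; BCa or
  profile-likelihood intervals would be preferable for strongly asymmetric
  cases but are out of scope.
- χ² grading inherits the small-n SEM caveat above; grades on n < 6 arms
  should be read qualitatively.
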