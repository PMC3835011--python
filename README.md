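# ergflow

Quantitative modelling of retinal function under acute ocular-perfusion-pressure
challenge.

Retinal function — measured as the electroretinogram (ERG) b-wave amplitude —
is markedly more resistant than ocular blood flow to acute reductions of
ocular perfusion pressure (OPP = MAP − IOP).  `ergflow` implements a model in
which this disconnect is explained by two mechanisms:

1. **Oxygen extraction ratio (OER).**  As flow falls, the tissue extracts a
   larger fraction of delivered oxygen.  OER follows an exponential law in
   relative flow *F* (% of baseline), pinned through the baseline point
   (100 %, onefold):

   `OER(F) = a·exp(b·F) + 1 − a·exp(100·b)`

   with `a` the responsiveness (vertical span, fold) and `b < 0` the decay
   rate (per % flow).  Relative oxygen consumption is `F·OER(F)`.

2. **IOP mechanical stress (IOP_M).**  When OPP is lowered by raising IOP,
   neurons additionally experience a pressure load, modelled as a two-line
   hinge: zero up to a threshold `t` (mmHg) and linear with slope `m`
   (% ERG per mmHg, negative) above it.

Predicted relative ERG amplitude is the sum of both, clamped at zero:

`ERG%(F, IOP) = max(0, F·OER(F) + IOP_M(IOP))`

The package is aimed at ocular physiologists and modellers who need to fit
this model to pressure-challenge data, grade the fit, derive the model's
components from simultaneous pO₂/flow/ERG measurements, or benchmark the
whole analysis on synthetic cohorts with known ground truth.  It provides:

- `ergflow.model` — the forward model (pure functions, calibrated defaults
  `a=4.03, b=−0.019, t=50.0, m=−0.70` in `TABLE1_PARAMS`);
- `ergflow.fitting` — bounded multi-start least-squares fitting, case/residual
  bootstrap 95 % confidence intervals, χ²/Q goodness-of-fit grading
  (Q < 0.001 poor, 0.001–0.1 acceptable, > 0.1 good);
- `ergflow.derive` — putative OER (= pO₂/flow) and IOP_M (= ERG − pO₂) from
  baseline-normalised simultaneous measurements;
- `ergflow.simulate` — synthetic cohorts on the 10→120 mmHg IOP staircase
  with MAP clamped high/moderate/low (159/104/61 mmHg), an autoregulatory
  flow–OPP curve and Gaussian measurement noise;
- a thin CLI (`ergflow simulate | fit | derive | gof | recover`) over the same
  functions.

## Worked example

```python
from ergflow import CohortConfig, TABLE1_PARAMS, bootstrap_ci, fit_model, generate_cohort

animals, summary = generate_cohort(CohortConfig(seed=42))   # high-MAP arm, n=6
fit = fit_model(summary, seed=1)
boot = bootstrap_ci(summary, fit, n_boot=500, seed=2)
```

Running `python examples/02_simulate_and_fit.py` (which does the above)
prints:

```
parameter   truth     fitted    95% CI
  a         4.030     3.509   [2.933, 5.062]
  b        -0.019    -0.017   [-0.022, -0.015]
  t        50.000    51.518   [48.514, 56.246]
  m        -0.700    -0.756   [-0.866, -0.694]

SSE = 108.5; chi2 = 10.6 on 19 df; Q = 0.937 (good)
```

Each bootstrap interval brackets the generating value; the threshold is
recovered to ~1.5 mmHg at realistic noise; and Q = 0.937 says the remaining
misfit is fully explainable by the per-point SEMs.  The other scripts in
`examples/` walk through the forward model's operating points, the
derivation of OER/IOP_M from simultaneous measurements, and cross-cohort
prediction with frozen parameters.

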