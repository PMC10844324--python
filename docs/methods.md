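# Methods

`chronobind` implements a family of generative observer models for
*intentional binding* — the subjective compression of the interval
between a voluntary action (a keypress) and its sensory outcome (a
tone) — together with the machinery needed to fit those models to
Libet-clock timing reports and to verify, on synthetic data, that
their parameters and identities are recoverable.

## The generative model

All times are in milliseconds in an *operant frame*: the action occurs
at `t*_A = 0` and the outcome at `t*_O = t_AO` (0, 250 or 500 ms in the
default design).  Perception is noisy and biased; the internal percepts
are

    tau_A ~ N(b_A, sigma_A^2),      tau_O ~ N(t_AO + b_O, sigma_O^2).

In single-event *baseline* blocks the maximum-likelihood report is the
raw percept, so the baseline error distributions identify
`(b_A, sigma_A)` and `(b_O, sigma_O)` directly; these four values are
estimated per observer from their own baseline trials (sample mean and
SD with `ddof=1`) and enter every model as fixed parameters.  The
package defaults for synthetic observers, `b_A = -52.22`,
`sigma_A = 61.56`, `b_O = 18.27`, `sigma_O = 61.56` ms, are the
baseline statistics of an average human observer in this paradigm
(anticipatory keypress reports, lagged tone reports).

In *operant* blocks the two events co-occur and the models differ in
how reports are formed.

### Bayesian causal inference (BCI)

A BCI observer carries a prior probability `P(xi=1) = p_causal` that
the action caused the tone, and, conditional on causality, a Gaussian
*coupling prior* over the action-outcome interval with mean `mu_AO` and
SD `sigma_AO`.  The *unity* prior is the special case `mu_AO = 0`
(causally linked events are expected to be essentially simultaneous).
Without a causal link the joint timing prior is flat over a
normalization range `T`.  `sigma_AO = 10` ms and `T = 250` ms are fixed
constants of the family, never fitted (`sigma_AO` is not identifiable
in this design).

Conditional on the causal scenario, the MAP timing estimates are

    xi=1:  t_A = tau_A + (sigma_A^2/sigma_tot^2) d,
           t_O = tau_O - (sigma_O^2/sigma_tot^2) d,
    xi=0:  t_A = tau_A,  t_O = tau_O,

with `d = tau_O - tau_A - mu_AO` and
`sigma_tot^2 = sigma_A^2 + sigma_O^2 + sigma_AO^2`.  The causal
estimates shrink the perceived interval toward `mu_AO`; when the
percepts inform an interval *shorter* than the prior the shift reverses
sign and the model predicts repulsion rather than compression.

Two quantities govern the scenario choice, both depending on the
percepts only through `d`:

- the **joint-posterior peak ratio**
  `r = [p/(1-p)] * T/(sqrt(2 pi) sigma_AO) * exp(-d^2/(2 sigma_tot^2))`,
  the ratio of the causal to acausal peak values of the unnormalized
  joint posterior over (t_A, t_O, xi);
- the **marginal causal posterior**
  `P(xi=1|tau) = expit( logit(p) + log[T/(sqrt(2 pi) sigma_tot)] - d^2/(2 sigma_tot^2) )`,
  obtained by integrating the joint posterior over the timing
  variables.

Both closed forms are verified in the test suite against brute-force
2-D grid maximization/evaluation of the joint density.  At the prior
boundaries the ratio degenerates gracefully (`p=0 -> r=0`,
`p=1 -> r=inf`) because bounded optimization visits the bounds.

The four decision strategies are:

| strategy | rule |
| --- | --- |
| joint posterior (JP) | causal estimates iff `r > 1` |
| model selection (MS) | causal estimates iff `P(xi=1|tau) > 0.5` |
| model averaging (MA) | posterior-weighted average of the two estimates |
| probability matching (PM) | causal estimates iff `P(xi=1|tau) > u`, `u ~ U[0,1]` per trial |

Crossed with the two priors these give eight BCI models (JPup ... PMcp).

### Non-inference models

- **Mandatory integration (MIup, MIcp)**: `p_causal` fixed at 1 —
  cue fusion without causal inference.  All four strategies coincide,
  so only the prior type distinguishes models; MIup has *no* free
  parameters, MIcp fits `mu_AO`.
- **Fixed criterion (FC)**: report the midpoint `(tau_A + tau_O)/2`
  whenever the *signed* perceived gap satisfies
  `tau_O - tau_A <= phi`, otherwise the target percept.  The signed
  comparison is kept deliberately: a negative perceived interval always
  integrates.
- **False report (FR)**: with probability `p_fr` the observer reports
  the *non-target* event's percept.  (The source description of this
  rule prints the two branches in the reverse order of its own prose;
  the implementation follows the prose and the `p_fr = 0 ->` correct
  report limit.)
- **Null**: operant reports are raw percepts; no binding.

A single uniform draw per trial drives both the PM scenario choice and
the FR report swap; this is the minimal reading of "sampled on each
trial" and keeps the per-trial randomness one-dimensional.

### Free parameters and bounds

| parameter | meaning | range | models |
| --- | --- | --- | --- |
| `p_causal` | prior causal probability | [0, 1] | JP/MS/MA/PM |
| `mu_AO` | coupling-prior mean (ms) | [0, 500] | *cp models |
| `phi` | integration criterion (ms) | [0, 1000] | FC |
| `p_fr` | false-report probability | [0, 1] | FR |

## Synthetic experiment

`DesignSpec` reproduces the study design: 2 baseline cells (keypress,
tone) + 2 targets x 3 intervals operant cells, 60 trials each, 480
trials per observer, 76 observers at full scale.  Baseline trials
report the raw target percept; the tone baseline is stored at
`t_AO = 0` so report and error coincide — the tone's physical onset
within a trial is irrelevant to every model, which only sees the error
distribution.  Seeding is hierarchical (master seed -> per-observer
streams -> per-cell streams), so any observer or cell is reproducible
in isolation.

What the generator does *not* emulate: clock rendering and the
angle-to-ms conversion, keypress latencies, practice trials, observer
exclusion, and any trial-order or learning effects — trials are
exchangeable within a cell.  Passing tests therefore demonstrate
algorithmic correctness and identifiability under the model's own
assumptions, not robustness to the artifacts of real clock data.
Per-observer heterogeneity of the sensory parameters is off by default
(recovery uses the fixed average-observer baselines); pass your own
`ObserverParams` per observer to vary them.

## Likelihood and fitting

Only the null and mandatory-integration models have closed-form
response densities, so the per-trial likelihood is simulation-based:
for each operant condition cell, `n_mc` percept pairs (and one uniform
draw each) are pushed through the model's response rule and the density
of the simulated *errors* is estimated at the observed error.

- **Density estimator**: Gaussian KDE with Silverman's bandwidth,
  computed by linear binning (grid step = bandwidth/4, kernel truncated
  at 4 bandwidths and renormalized) and linear interpolation — the
  standard fast KDE, accurate to well under a percent of the exact KDE
  at these sample sizes.  A fixed-width histogram estimator (default
  5 ms) is available via `FitConfig(density="hist")`.
- **Floor**: each trial's density is floored at `1e-10` /ms so a stray
  report cannot produce an infinite objective; the floor is orders of
  magnitude below any plausible density (a baseline-width Gaussian
  peaks near `6.5e-3` /ms).
- **Common random numbers**: the MC percepts are drawn once per fit
  from seeds derived from `FitConfig.seed` and reused at every
  parameter value, making the objective deterministic; two identical
  calls to `fit_model` return identical results.
- **Baselines**: baseline trials do not enter the search — they fix the
  sensory parameters and contribute their exact Gaussian log-likelihood
  as a model-independent constant.
- **Search**: bounded global maximization over the ranges above.
  One-parameter models use a deterministic coarse scan (41 points) with
  bounded Brent refinement between the best point's neighbors;
  two-parameter models use seeded differential evolution (Sobol
  initialization, population multiplier 12, up to 100 generations,
  relative convergence tolerance 1e-3, no gradient polish — the
  objective is piecewise constant at the scale of single MC samples).
  These budgets were chosen as the smallest that stop making any
  difference to the optimum on this 1-2 dimensional objective;
  `FitConfig.restarts` adds independent restarts if desired.  Optimizer
  failure is flagged in `FitResult.diagnostics`, not raised.
- **Model comparison**: `AIC = 2k - 2 LL` with `k` the number of free
  parameters (0-2).  `FitConfig(aic_k_offset=1)` switches to the
  convention that also counts the shared baseline noise model, which is
  the convention consistent with the published group-level table this
  package's arithmetic is checked against.  Model ranking is unaffected
  by the offset since it shifts every model equally.
- **Group-level fits** share the free parameters across all observers
  in the table while keeping each observer's own baseline parameters;
  individual-level fitting is simply a per-observer call.

## Recovery analyses

**Parameter recovery** samples each model's free parameters uniformly
from their ranges, simulates a full session per ideal observer, refits
the generating model, and reports Pearson's r between sampled and
recovered values per model-parameter pair (with the t statistic of the
test of no correlation, reported descriptively and never used for
gating).  MIup is excluded (nothing to recover), leaving 15 pairs from
11 models.

Recovery fits condition on the *known* generating sensory parameters
rather than re-estimating them from the simulated baseline blocks: on
synthetic data the baseline distribution is known exactly, and
re-estimation from 60 trials per event perturbs the integration weight
`sigma_A^2/sigma_tot^2`, whose error is amplified by the physical
interval (≈570 ms of predicted-mean leverage at the 500 ms condition).
That perturbation systematically penalizes the zero-parameter MIup in
favor of any model with a compensating free parameter and is an
artifact of the estimation step, not of the models.  Fitting *real*
data (the `fit_model` default and the `fit` CLI) estimates the
baseline parameters from each observer's own baseline trials, where no
ground truth exists.  The model-selection variants recover `p_causal` and
`mu_AO` poorly by construction — their hard posterior threshold makes
whole regions of parameter space observationally equivalent — and this
is expected to drag the mean r visibly below the other BCI variants.
The same truncation effect shapes the predicted binding pattern: for
`p_causal < 1` integration shuts off once the physical interval pushes
the expected discrepancy far beyond `sigma_tot`, so compression
*decreases* again at long intervals; only the mandatory-integration
limit compresses monotonically with interval length.

**Model recovery** fits all 12 candidate models to every dataset from
parameter recovery and tabulates AIC winners as a 12x12 column-
stochastic confusion matrix (columns = generating model).  AIC ties are
broken toward fewer free parameters, then lexicographic model id.  The
expected structure — strong diagonals for MI/FC/FR, mutual confusion
between the JP and MS strategies (their decision rules differ only in
the threshold constant applied to the same discrepancy statistic) — is
asserted by the structural tests.  A further equivalence worth knowing
about: JPup and FC make almost identical predictions in this design
(an integrate-or-not threshold on the perceived gap, with a fused
report whose weight, 0.493 at equal sensory noises, is nearly the FC
midpoint; the rules differ only in the rarely-visited lower tail of
the gap distribution), so JP-generated data is often credited to FC
and vice versa at any Monte-Carlo resolution — their AIC margins are
fractions of a unit.

### Problem sizes

Desk-scale defaults are 20 simulated observers per model and
`n_mc = 20,000` MC pairs (the CLI's `--full` flag restores the study
scale of 76 observers and 100,000 pairs); the structural model-recovery
test runs at 4 observers per generating model with `n_mc = 4,000` and a
lighter optimizer budget, which is sufficient for the coarse structure
it asserts.  These sizes are the package's verification defaults; all
of them are plain parameters.

## Known limitations

- The coupling prior is Gaussian and symmetric; asymmetric interval
  priors (log-normal, gamma) are out of scope, as is fitting
  `sigma_AO`.
- The KDE slightly oversmooths strongly bimodal response distributions
  (e.g., FR with moderate `p_fr`), which is conservative: it flattens
  the likelihood rather than sharpening spurious structure.
- Pearson correlations on bounded parameters compress near the range
  edges; recovery r is therefore a summary, not an unbiased estimate of
  estimator quality.
- Inferential statistics on behavioral summaries (ANOVA, pairwise
  tests) are deliberately excluded; `binding_indices` ends at
  descriptive per-observer indices.
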