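# bidlearn

Computational models of how buyers learn what to bid in a repeated
double auction, for researchers in behavioural economics and
computational cognitive neuroscience who want a fully synthetic,
end-to-end testbed: task simulation, model fitting, model comparison,
and trial-level learning-signal regressors for downstream neuroimaging
analyses.

## The task and the models

A buyer repeatedly bids `b ∈ {0.0, 0.1, …, 10.0}` MU in three market
types — seller competition (SC: 2 sellers), no competition (NC: 1v1)
and buyer competition (BC: a rival buyer). The highest buyer bid
transacts when it is at or above the lowest seller ask, paying `10 − b`;
otherwise nothing. Markets loop in blocks of three for 24 blocks, with a
lottery excluding one trial in six.

Seven models of bid learning share one interface (policy over the 101
bids, update rule, per-bid likelihood):

- **Model-free RL** — Rescorla–Wagner updates
  `Q(i) ← Q(i) + α(r − Q(i))` on the chosen action with a softmax
  `P(i) ∝ exp(β Q(i))`, on an 11-tile coarse action space (`rw_coarse`)
  or the native grid (`rw_fine`); action values initialized from a
  rescaled Beta prior fit to pooled first-trial bids.
- **Counterfactual RL** (`counterfactual_rl`) — auction logic updates
  unchosen actions: accepted ⇒ every `i ≥ b` moves toward its foregone
  payoff `10 − i`; rejected ⇒ every `i ≤ b` moves toward 0.
- **Directional learning (DL)** — no value function, just a preferred
  bid `A` per market, nudged down after acceptances and up after
  rejections, with Gaussian (`dl_gauss`) or asymmetric two-sided Laplace
  (`dl_naive`, `dl_lepto`) choice noise. The delta-rule variants track
  the preferred bid value `V = 10 − A` via `V ← V + α(r − V)`;
  `dl_lepto` adds a mixture weight `k` putting mass `k` on explorative
  bids strictly below `A`.
- **Null** — uniform over the 101 bids.

Fitting is fixed-effects (one parameter vector yoked across subjects) or
random-effects maximum likelihood with bounded L-BFGS-B inside a
basin-hopping loop, compared by `BIC = 2·NLL + p·ln(n)`. Enactment
replays a fitted DL model through observed sessions, forced to the
subject's choices, and emits per-trial regressors: the preferred bid
value (PBV), the ±1 directional signature (DS) and the pseudo
reward-prediction error `reward − PBV`, z-scored across subjects.
See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Simulate a 3-subject cohort with the default leptokurtic-DL generator,
summarize it, fit the Gaussian DL model and export regressors:

```
$ bidlearn simulate --seed 3 --subjects 3 --out demo.tsv
wrote 3 sessions to demo.tsv

$ bidlearn metrics --data demo.tsv --out metrics.tsv
transaction rates: SC=98.4%, NC=94.7%, BC=95.2%
first-bid means: SC=5.13, NC=5.17, BC=6.17; F(2,6)=6.60, p=0.03
wrote per-subject metrics to metrics.tsv

$ bidlearn fit --model dl_gauss --data demo.tsv --hops 3 --seed 1 --out fit.json
dl_gauss [ffx] NLL=605.01 BIC/subject=406.80

$ bidlearn enact --model dl_gauss --params fit.json --data demo.tsv --out regressors.tsv
wrote 180 trial rows to regressors.tsv
```

The metrics line reads: this synthetic cohort transacts most reliably in
SC and least in BC, and its first bids already separate the markets
(highest where a rival buyer must be outbid), which a one-way ANOVA over
the three markets confirms. The fit line is the aggregated negative
log-likelihood of all 180 observed bids under the best-fitting Gaussian
DL parameters and its per-subject BIC. Each row of `regressors.tsv`
carries one bid trial's PBV, DS and pseudo-RPE (raw and z-scored), ready
for design-matrix construction.

The same operations are available as library calls (`simulate_cohort`,
`fit`, `rank_models`, `enact`, `subject_metrics`, …); see the module
docstrings.

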