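# Methods

## Model

The package simulates fully connected continuous-time recurrent neural
networks (CTRNNs) of `N` leaky-integrator nodes,

```
tau_i ds_i/dt = -s_i + sum_j w[j,i] V_j,      V_j = sigma(g_j (s_j + theta_j)),
```

with the sigmoid `sigma(x) = 2/(1+exp(-x)) - 1` mapping onto `(-1, 1)`.
Matrix entry `w[i,j]` is the strength *from* node `i` *to* node `j`, so the
input to node `i` sums column `i`; this orientation is fixed once here and
used everywhere.  The bias recenters each node at half its row sum,
`theta_i = -(1/2) sum_j w[i,j]`, computed **once** from the original
weights and held fixed through learning, so the constraint problem the
network is scored against never moves.  (A sensitivity switch to recompute
biases after each weight update exists in `NodeParams.with_bias_from` but
is not used by the experiment harness.)

Trajectories are integrated by forward Euler with step `dt`, valid while
`dt < 2 min(tau)` (enforced at construction).  Two update schemes are
provided: synchronous (all nodes advanced from the pre-step state) and
asynchronous, the default, implemented as a Gauss–Seidel sweep — each
Euler step visits the nodes in a fresh random permutation and every node
update sees the freshest activations and outputs.  The two schemes agree
in the `dt -> 0` limit and the tests assert their endpoint gap shrinks
with `dt`; the asynchronous default follows the convention for attractor
convergence in this model family.  No higher-order integrator is offered:
the method under study is defined with forward Euler, and its
discretization error is part of the studied system.

## Constraint problem and weight conditions

The original weights `alpha` define a constraint-satisfaction problem: an
ordered pair `(i, j)` — self-pairs included, giving `N^2 = 900` constraints
at `N = 30` — is satisfied by an output configuration `V` when
`alpha_ij V_i V_j > 0` strictly.  Zero products count as unsatisfied, so
the all-zero state scores zero.  Scoring always uses the frozen `alpha`,
never the learned working copy.

Four seeded condition families generate `alpha`:

| family | diagonal | off-diagonal | symmetry |
|---|---|---|---|
| SR | U[-1, 1] | U[-0.1, 0.1], mirrored per unordered pair | exact |
| AR | U[-1, 1] | `±0.1 + U[-0.1, 0.1]`, independent per ordered pair | none |
| SM | magnitude 1 | 1 within module, 0.01 between; sign +, p = 0.8, mirrored | exact |
| AM | SM diagonal | SM entry + U[-0.01, 0.01], independent per ordered pair | none |

Modules are contiguous blocks of `module_size = 3` nodes (ten modules at
`N = 30`).  This choice was validated dynamically: three-node modules with
an 80/20 sign mix are individually frustrated, so a fresh SM network holds
tens of attractors (40–96 across probe seeds) — the multistable regime the
mechanism requires — and its before-learning satisfaction mean sits near
62–64%.  Ten-node modules (the "three modules" reading, available as
`module_size=10`) each collapse onto a single internal solution, leaving
the network essentially monostable (one attractor in 7/8 probe seeds,
before-mean ≈ 77%) with nothing for learning to select among.  The sign
rule (positive with probability 0.8) is applied to every unordered pair,
within- and between-module alike.

## Self-optimization

The loop: (S1) draw each activation uniformly from the sampling box;
(S2) relax for `ť = 500` time units (5,000 Euler steps at `dt = 0.1`);
(S3) reinforce the endpoint outputs with one Hebbian increment
`w_ij += delta · V_i V_j` over all ordered pairs, clipping every weight to
`[-1, 1]`.  Reinforcement is applied only at the end of a relaxation:
with unconstrained parameters transients can be long, and the endpoint is
the best estimate of an attractor or at least of a point well inside its
basin.  Self-connections participate in the update like any other weight.
The increment `delta · V Vᵀ` is symmetric, so symmetric weights stay
exactly symmetric and the asymmetry `|w_ij - w_ji|` can never grow under
learning (clipping only shrinks it) — both are property-tested.

Defaults that matter:

- `delta = 0.001` (symmetric families) and `0.0005` (asymmetric): small
  enough that many attractors are sampled before any basin collapses; the
  asymmetric families need the lower rate to avoid committing to early
  suboptimal attractors.  A diagnostic warns when `delta` could drive a
  weight across the clip range within ~10 relaxations.
- sampling box `(-10, 10)`: the box must dominate the bias terms (which
  scale with half the weight row sums, up to ~±1.6 under the modular
  defaults and ~±0.5 random) so the initial *output* signs are sampled
  nearly freely rather than dictated by `theta`.  `(-10, 10)` achieves
  that, samples all probe basins, and yields before-learning statistics
  consistent with the published experiment under all four conditions.
  Narrower boxes bias the initial corner distribution and raise the
  before-learning mean.
- 100 before / 1,000 learning / 100 after relaxations per repetition;
  node parameters per repetition: `tau_i ~ U[1, 10]`, `g_i ~ U[10, 20]`.

## Attractors, convergence, conjugate pairs

A relaxation is marked converged when `max_i |ds_i/dt| < 1e-6` per time
unit at its endpoint; non-fixed-point limit sets are only ever flagged
this way, never classified.  Endpoints are identified by greedy
L-infinity clustering at tolerance 0.05 on `V` (high gains push fixed
points toward hypercube corners, so 0.05 separates corners cleanly while
absorbing integration error).

Because the constraint score and the Hebbian increment are both exactly
invariant under a global output sign flip `V -> -V`, fixed points
typically come in conjugate pairs `(V*, -V*)` that are equivalent as
solutions and are reinforced identically — learning cannot separate them,
and the after-learning landscape collapses onto one conjugate *pair*
(observed visit splits around 80/20 between the two members, the asymmetry
coming from the bias terms).  `cluster_attractors` therefore counts
literal endpoints by default (opposite corners are two clusters) and
offers `identify_sign_flip=True` to cluster on the solution quotient;
single-attractor-dominance statistics use the quotient, where the
dominant solution captures ~100% of after-learning relaxations in the
modular conditions.

## Experiment harness and statistics

A repetition = before stage (no learning, on `alpha`), learning stage,
after stage (no learning, on the learned weights).  Success is judged
per repetition by a two-sided Welch t-test on the before vs after
satisfied-constraint counts — each repetition is an individual experiment
— and the headline statistic is the mean of per-repetition p-values;
pooled stage means, percentages and integer-bin histograms are reported
alongside.  Welch (unequal variance) is the conservative reading of an
unspecified "t-test"; the after-learning samples are often nearly
constant, which Welch handles without a pooled-variance assumption.
Degenerate samples (both constant) give p = 1 when means agree, 0
otherwise.

Seeding is counter-based: cell `(config c, repetition r)` uses
`SeedSequence(master_seed, spawn_key=(c, r, stream))`, so any cell can be
re-run in isolation and a full experiment is reproducible bitwise.

## Problem sizes

The full published design (100 configurations x 100 repetitions x 1,200
relaxations of 5,000 steps) is cluster-scale.  The package's acceptance
script and reproduction tests run the identical per-repetition structure
at desk scale — the tests use 5 weight configurations x 2 repetitions per
condition; the acceptance script uses 8 configurations for the modular
conditions (whose configuration-to-configuration spread is about four
times larger) and 5 for the random ones — sizes chosen to keep a complete
four-condition reproduction within minutes on one core while leaving the
configuration-level variance measurable.  Comparisons against published
means are made within three standard errors computed over configurations
(the dominant variance component).

## Synthetic scope and known limitations

All inputs are internally generated; the weight-condition generators *are*
the study's data layer, and they emulate exactly the four published
condition families — not any empirical connectome.  What passing tests
show is that the mechanism (basin enlargement by Hebbian reinforcement of
visited attractors, and its much stronger effect on modular than on
unstructured problems) is reproduced by this implementation under the
documented conditions; they do not certify behavior for weight ensembles,
gain regimes or sampling boxes far outside those conditions.

Residual quantitative offsets from the published means remain at desk
scale: the before-learning level runs ~2 points high in SM/AM and SR and
~2.5 points low in AR (the published ordering of the two random baselines
is SR < AR; this implementation reproduces SR ≈ 54–56% and AR ≈ 54–57%
with overlapping spreads but does not reliably reproduce that ordering).
Several experiment parameters the offsets are sensitive to are not fully
pinned down by the published description — the exact activation-sampling
bounds, the asynchronous update scheme, and the scope of the modular
sign-probability rule — and the package's choices for each are documented
above.  The qualitative contrasts (the ~9–10-point modular improvement,
its statistical significance, the ~1-point random improvement, and
post-learning single-solution dominance) are robust to these choices.

The learning-rate warning threshold and the run length are fixed, not
adaptive; no stopping rule detects single-attractor collapse early.
Basin fractions are Monte-Carlo estimates over the sampling box, not
volumes of the true basins, and carry binomial standard errors.
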