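# Methods

This note documents the models, numerical choices and known limitations of
`divshift`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Episodic birth-death likelihood

The data are the branching times of a rooted ultrametric tree, treated as the
sufficient statistic of a reconstructed birth-death process.  Rates are
piecewise constant: interval 0 is the youngest, covering ages `[0, t_1)`;
interval `i` covers `[t_i, t_{i+1})` (an age exactly at a shift belongs to the
older interval; the likelihood is continuous there so the convention is
cosmetic).  Incomplete sampling enters as a Bernoulli thinning of tips with
probability ρ at the analysis present.

Both propagators are advanced interval-by-interval in closed form.  Writing
`g(u) = 1 − p0(u)` for the probability that a lineage at age `u` leaves at
least one sampled descendant, with entry values `(g̃, q̃)` at an interval's
young end and `r = λ − μ`:

    g(u)  = g̃ r e^{−m} / E,   E = g̃ λ e^{−m} + (r − λ g̃) e^{s−m},
    ln q(u) = ln q̃ + 2 ln|r| + s − 2 (m + ln|E|),

where `s = −r·x`, `x` the age increment and `m = max(s, 0)` an overflow
guard.  The implementation propagates `g` rather than `p0` because the
crown-conditioning term is `−2 ln g(x_1)`: survival probabilities of order
1e−10 arise for strongly declining-diversity parameter sets, and `1 − p0`
computed by subtraction would lose six or more significant digits there.
(This is observable: with a p0-based formulation the closed-form and ODE
likelihood paths disagree by up to 1e−2 log-units on randomized subcritical
models; with the g-form they agree to better than 1e−8 relative on the same
cases.)

* Critical case: for `|λ − μ| < 1e−8` the exponential forms are replaced by
  their λ = μ limits, `g = g̃ / (1 + g̃ λ x)` and `ln q = ln q̃ − 2 ln(1 + g̃ λ x)`
  — never a 0/0.
* An independent evaluation path integrates `d(ln g)/du = (λ−μ) − λ g` and
  `d(ln q)/du = −(λ+μ) + 2λ(1 − g)` with LSODA at rtol 1e−10; the test suite
  holds the two paths to 1e−6 relative agreement over 1000 randomized models
  and the simulator's branching times to the closed-form density by KS test.
* Conditioning is on the crown age plus survival of both crown lineages
  (`conditioning="crown_survival"`); `"none"` drops the survival factor.
  Conditioning on the observed tip count was considered and not implemented:
  it requires an additional `P(n | crown age)` recursion that no downstream
  quantity here uses, and only likelihood *differences* between nested models
  are ever interpreted.
* Mass-extinction survival probabilities at shift boundaries exist in the
  model type (`p0 → 1 − s(1−p0)`, `q → s·q`) but are fixed at 1 throughout
  the pipeline; only rate shifts are fitted.

## Shift search and model selection

The optimizer works on `(ln λ_i, ln μ_i)` per interval (bounds 1e−6..10 on λ,
1e−9..10 on μ), so the τ = 1 singularity of the reporting parameterization
`(r, τ)` never enters the search space, and `μ > λ` (negative net
diversification) is reachable — the default, matching a shift search that
permits declining diversity.  With `allow_negative_r=False` extinction is
re-parameterized as `μ = λ·expit(z)`.

Shifts are added greedily, one at a time: every age on a 1-Myr grid strictly
inside the (re-based) crown span is tried as the additional shift, all
interval rates re-optimized by L-BFGS-B from two warm starts (the parent
model's rates with the candidate's interval duplicated, and the previous
candidate's optimum); the winning grid age is then re-refined from 5
seeded random restarts.  On fixture and null trees, 30-restart re-optimization
reproduces these optima to < 1e−3 log-units, so heavier restarting during the
scan buys nothing.  Shift times stay on the grid (they are not refined
continuously), matching the grid semantics of the classical routine.

Nested fits are compared sequentially: the m-shift candidate is tested
against the last *accepted* model with χ² df = 3·Δm (two rates plus one shift
time per shift) and accepted at p < α = 0.05; AICc uses
`n_obs = number of branching times in the analyzed (truncated) data`.  The
χ² reference is a convention, not a theorem — the shift time is unidentified
under the null and the statistic is a maximum over grid candidates; see
Limitations.

## Truncation and the sampling fraction

Analyses of a deeply undersampled clade stop at a horizon (here 50 Ma):
branching events younger than the horizon are discarded, ages are re-based so
the horizon becomes the pseudo-present, and ρ becomes the fraction of the
clade's true lineages at the horizon that the tree represents.  That fraction
is derived from present-day richness via the method of moments: the crown
estimator for `r(ε)` at relative extinction ε ∈ {0, 0.5, 0.9}, the
back-projection `N_horizon = N_present / (horizon × r)`, and
`ρ = k_lineages / N_horizon`, conservatively rounded *up* to the next 0.01
(a larger ρ attributes less of an apparent slowdown to unsampled lineages).
The back-projection is implemented exactly in that algebraic form because the
derived quantities downstream assume it; the exponential-decay alternative
`N e^{−r·horizon}` is available behind a flag but is not the default.

## Mk character model

The binary habitat character evolves under the one-parameter symmetric
2-state Markov model, `P(same) = (1 + e^{−2q·Δt})/2`, uniform (½, ½) root
prior, missing tips as flat partials.  Likelihoods use Felsenstein pruning
with per-node scaling; `q` is fitted by bounded 1-D search in `ln q`
(1e−8..100 flips/Myr), with boundary solutions (`q̂ ≈ 0`, invariant data)
flagged and returned as exactly 0 when the q→0 limit is at least as good.
Marginal per-node reconstructions come from an inside-outside pass (below-
and above-partials with separate scale accumulators); for every internal node
the two per-state log-likelihoods log-sum-exp to the total — an identity the
tests assert to 1e−9.  A state is called significant at ΔlnL ≥ 2.0.  At
q = 0, data incompatible with a single state yield −∞, not an error.  A
prune-to-one-per-group utility keyed on a genus map retains, per group, the
tip with the fewest missing states, ties broken lexicographically —
deterministic where a random choice would not be.

## Synthetic data

The generator is event-driven (Gillespie) on the forward time axis from two
crown lineages, with the piecewise-constant rates read off the age axis,
followed by pruning of extinct lineages and Bernoulli ρ-thinning of the
survivors; the reconstructed tree of the sampled tips is assembled from the
event log.  Conditioning is by rejection: realizations that go extinct, leave
fewer than two sampled tips, fall outside an optional tip-count band, or
whose crown lineages are not both represented are redrawn, and the redraw
count is attached to every tree so heavy rejection is visible.  The event
stream and the sampling draws use separate seeded generators, so changing ρ
thins the same trees.

The study-scale fixture (`make_study_fixture`) uses: crown age 180 Myr, one
shift at 103 Ma, older interval r = 0.085, τ = 0.305, younger r = 0.022,
τ = 0.935; present-day sampling ρ = 0.0187, chosen once so that the expected
sampled ingroup is ~250 tips given those rates (≈ 250 sampled of the ≈ 13,400
species the truth model predicts at present) — which also leaves ~3% of the
true lineages at the 50 Ma horizon represented, consistent with the
conservative ρ = 0.03 the truncated analysis then uses; a tip-count
acceptance band of 100–600; per-replicate multiplicative lognormal node-age
jitter with fractional SD 0.02 (re-enforcing parent > child and re-deriving
branch lengths, so trees stay ultrametric), sized from the ~3% relative width
of the dating study's crown-age credible interval; and a binary character
with q = 0.005 flips/Myr from an arid root (≈ 0.9 expected flips per
root-to-tip path: strong conservatism with a few shifts).

What the jitter does *not* emulate: a real dating posterior perturbs node
ages in a strongly correlated, internally consistent way, whereas independent
per-node jitter adds white noise to event times.  Passing fixture tests
therefore demonstrate correctness of the machinery under the stated
generative model, not robustness to the full structure of relaxed-clock
posteriors.

## Problem sizes in the shipped tests

The test suite exercises: 1000 randomized models for the dual-path agreement;
all ≤6-tip trees over 100 random draws for pruning vs enumeration; 50
study-scale fixture replicates for parameter recovery; 200 constant-rate
trees (λ = 0.10, μ = 0.05, ρ = 1, crown 60) for test calibration; and 10⁴
pooled branching times for the simulator/likelihood KS cross-check.  These
sizes keep the full suite within a coffee break on one core while leaving the
Monte-Carlo assertions' error bars well inside the asserted bands.

## Known limitations

* **Finite-sample bias of the net rate.**  On crown-60 constant-rate trees
  (~70 tips after crown-survival conditioning) the median ML net rate is ~13%
  below truth; the bias shrinks with tree size (< 1% at crown 100).  The
  recovery tests assert the tight recovery at the larger size and the bias
  shrinkage explicitly.
* **Deep-interval extinction is weakly identified.**  With ~3% sampling and a
  truncated analysis, the oldest interval contains few events descending from
  few lineages; the MLE occasionally prefers a deep shift with a very high
  old-interval turnover.  On the study fixture this inverts the recovered
  pre/post-shift extinction ordering in roughly a third of replicates even
  though the shift-time mode is recovered to within ±2 Myr — these deep-shift
  optima genuinely beat the truth-located optimum in likelihood, so this is a
  property of the estimator at these data sizes, not of the optimizer.
* **The sequential LRT is anticonservative.**  The one-shift statistic is a
  maximum over ~10² grid candidates; on constant-rate trees the χ²₃ test at
  α = 0.05 rejects at roughly 4× nominal rate.  Model selection here should
  be read as the study's convention, with AICc as the corroborating
  criterion, not as a calibrated hypothesis test.
* Absolute −logL and AICc values depend on the conditioning convention and an
  additive constant; only differences between nested fits on the same data
  are meaningful.
* No diversity-dependent, clade-partitioned, or Bayesian rate models; no tree
  inference or dating; plots are left to the figure-ready TSV outputs.
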