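# Methods

## Model

The package models coded accident cases with a tree-augmented naive Bayes
(TAN) network: a 4-state class node `accident_type` ∈ {S, C, F, L}
(struck-by, collapse, fall, lifting) and one binary node per unsafe
behavior. Every behavior node has the class as a parent and at most one
other behavior; the behavior–behavior edges form a spanning tree. The
joint factorizes as

    P(y, b_1..b_m) = P(y) · Π_i P(b_i | y, b_{pa(i)})

with `pa(i)` the tree parent (absent for the tree root). Assumptions worth
stating plainly:

* Each case contributes one independent draw; behaviors within a case are
  dependent only through the class and the single tree neighbor.
* Time order of behaviors within a case is treated as non-probabilistic:
  it is preserved in the chain records and deliberately discarded in the
  modelled Yes/No matrix. Consequently the final posterior under a fixed
  evidence set is order-invariant by construction (asserted by test), while
  the per-step growth path depends on the insertion order.
* Duplicate behavior codes within one case are rejected as input errors
  rather than collapsed silently — the binarization would hide them.

## Estimation

Structure: all m(m−1)/2 behavior pairs are scored by class-conditional
mutual information in nats, computed from the smoothed empirical
(class × 2 × 2) table; the maximum-weight spanning tree is found by
Kruskal's algorithm. Ties are broken deterministically: higher weight
first, then lower behavior-code indices, so builds are reproducible
bit-for-bit. The tree is oriented away from an orientation root (default:
the lowest-numbered behavior).

Parameters: every CPT cell is `(count + α) / (Σ child counts + 2α)` (`Kα`
in the class prior's denominator), default α = 0.5 per cell. α = 0.5 is
the package's small-cell adjustment: applied to the published class counts
(191/39/33/24) it yields the no-evidence posteriors 66.3 / 13.7 / 11.6 /
8.5%, agreeing with the study's printed 66.3 / 13.7 / 11.6 to one decimal
(its printed lifting value, 8.45%, differs from ours in the second
decimal; the provenance of that rounding is unknowable without the
original software's internals). α = 0 and α = 1 do not reproduce those
figures, which is why 0.5 is the default. A parent configuration never
observed at α = 0 would have a 0/0 cell; it is filled with the uniform
1/2, which affects nothing reachable in the training data.

Classes with zero cases in a training subset are dropped with a warning
rather than smoothed into existence: a prior over never-observed classes
would be pure pseudocount.

One nuance: with α > 0, refitting under a *different orientation* of the
same undirected tree gives a very slightly different joint (per-node
smoothing is not orientation-invariant), so exact orientation-invariance
of the fitted joint is asserted at α = 0. Re-rooting a *fixed* fitted
model, by contrast, re-derives reversed-edge CPTs from the model's own
joint (per-class Bayes inversion) and is exactly joint-preserving at any
α; both properties are under test.

## Inference

Exact only — 37 binary nodes on a tree is closed-form cheap, so there is
no sampling anywhere in the inference path. Forward queries collect
per-class evidence likelihoods by a single sum-product pass over the tree
(unobserved behaviors marginalize out); backward queries are likelihood
ratios of two such passes with the class clamped. A brute-force
joint-enumeration oracle (refusing models above 14 behaviors) provides the
independent cross-check in the test suite; the property suite compares the
two paths on 200 random models to 1e-9.

Evidence semantics: the workflows only ever condition on behavior = Yes,
but the engine accepts No-observations for negative findings. Reports
print percentages to one decimal; machine-readable columns keep full
precision.

## Backward diagnosis

For accident type k, evidence starts at {Y = k}. Each round computes
P(B = Yes | evidence) for every unselected behavior whose occurrence
frequency within type-k cases is ≥ the frequency floor (default 0.08); if
the largest such posterior is below the stopping threshold (default 0.15)
the loop ends, otherwise the argmax (ties → lowest code number) is clamped
to Yes and recorded. Two deliberate choices:

* The frequency floor uses the per-type denominator (cases of that type),
  which is what makes the worked eligibility numbers (e.g. 10/33 ≈ 30.3%
  for machine-operation lapses within struck-by cases) come out; a
  whole-corpus denominator is available behind a flag.
* The floor applies from the first iteration, uniformly, rather than only
  after the first selection.

The trace records every round's full candidate set, so the procedure is
auditable and byte-reproducible. Selected posteriors need not decrease
monotonically — clamping a behavior can raise a tree neighbor's posterior.

## Root-node candidate ranking

A good reporting root occurs in all four accident types, occurs often, and
has a weak accident attribute. The published guidance is informal, so the
ranking here is one defensible operationalization: empirical attribute
strength of behavior B for type k is P̂(Y=k | B=Yes) − P̂(Y=k) from the
matrix, its spread is the maximum absolute strength over types, and
candidates sort by (occurs-in-all-four, spread ascending, total
occurrences descending, code number). Spread outranks raw frequency
deliberately: on the published occurrence tallies this ranks the permit
behavior (B14, spread ≈ 0.08 across 72 occurrences) above the much more
frequent PPE behavior (B12, 109 occurrences but spread ≈ 0.24, being
heavily fall-specific), which is the qualitative judgement the ranking is
meant to encode. If no behavior spans all four types the ranking falls
back to (total, spread) with a warning.

## Synthetic data

The generator emulates the *published marginals* of the study corpus: 287
cases with class mix 191/39/33/24 over {F, C, S, L}, 37 binary behaviors,
sparse background occurrence (default 8% per behavior and class), and
per-type signature behaviors planted as `(behavior, type, lift)` triples
forcing P(B=Yes | Y=k) − P(B=Yes | Y≠k) ≥ lift (checked against the
finished CPTs; infeasible triples raise). Planted behaviors depend on the
class only, so the lift holds exactly; background behaviors get a mild
co-occurrence coupling (default 0.10) along a seeded random tree. Chain
orderings are uniform random permutations of each case's Yes set, because
order carries no probability in the model.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: the true co-occurrence structure of behaviors
within accident types (the study publishes only per-type marginal tallies
for eleven behaviors), report-quality coding noise, duplicate or merged
chains, and any real time-order regularities. Default lifts and the
coupling are invented, calibrated only loosely to the published occurrence
table.

At the study's own scale (n = 287) the diagnosis loop recovers the planted
signature behaviors first but typically appends coupled background
behaviors before the stop threshold binds — much as the study's own groups
run to 6–8 members. Exact recovery of the planted sets is asserted under
well-separated conditions (lifts ≥ 0.3 over a 5% background, coupling 0,
n = 5,000, fixed seed).

## Problem sizes and numerical choices

Test problem sizes were chosen so that every stochastic check is
well-powered at its tolerance: CPT recovery within 0.02 uses n = 20,000
with balanced states and few cells (per-cell standard error ≈ 0.007);
structure recovery of a planted 8-behavior tree uses coupling 0.45 so edge
CMIs are well separated at n = 20,000; the Monte-Carlo check of planted
marginals uses balanced classes so each triple sees ~5,000 conditional
samples. All randomness flows through explicit integer seeds;
`numpy.random.default_rng` throughout. CMI values are clamped at zero
against −1e-16-scale rounding; probabilities are handled in linear space
(products of ≤ 38 factors cannot underflow meaningfully at these sizes).

## Limitations

* The full behavior catalog behind the study (73 behaviors across 19
  types) is unpublished; the default catalog reconstructs the 16
  recoverable labels and ships placeholders for the rest.
* Headline posteriors that depend on the unreleased case-level matrix
  (e.g. the worked-case endpoint posteriors or the published per-root CPT
  table, whose printed rows do not sum to 1 and whose normalization is
  therefore unclear) are *not* reproduced; the package reports properly
  normalized conditionals instead.
* The model is static: no time-sliced network, no latent causes, no
  corrective-measure effect estimates — the catalog's measure labels are
  metadata only.
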