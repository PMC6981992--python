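# accident-bn

Probabilistic analysis of how chains of unsafe worker behaviors transmit
probability to building-construction accidents.

Accident investigation reports typically code each case as a time-ordered
chain of unsafe behaviors (e.g. *install equipment against procedures →
work without a permit → no PPE*) ending in one accident type: fall (F),
collapse (C), struck-by (S) or lifting (L). This package is for safety
researchers and analysts who want to quantify, from a corpus of such coded
cases, (a) how the probability of each accident type grows as unsafe
behaviors accumulate on site, and (b) which *groups* of co-occurring
behaviors are most critical to each accident type.

## The model

Behaviors are binary indicators $B_1,\dots,B_m$ ("did behavior $i$ occur in
the case?") and the accident type is a 4-state class variable
$Y \in \{S, C, F, L\}$. The network is a **tree-augmented naive Bayes
(TAN)** classifier: every behavior node has the class as a parent plus at
most one other behavior, with the behavior–behavior edges forming the
maximum-weight spanning tree under class-conditional mutual information

$$I(B_i;B_j\mid Y)=\sum_{y,b_i,b_j} p(b_i,b_j,y)\,
  \log\frac{p(b_i,b_j\mid y)}{p(b_i\mid y)\,p(b_j\mid y)} .$$

CPTs are estimated from Yes/No counts with a small-cell pseudocount
adjustment, $(n + \alpha)/(N + 2\alpha)$ with $\alpha = 0.5$ per cell, so
rare behavior/accident combinations keep nonzero probability.

* **Forward reasoning** computes $P(Y_k \mid B_c)$ exactly for an evidence
  set $B_c$ of observed behaviors (a sum-product pass over the tree). The
  *accident attribute strength* of a behavior is the increment it adds to a
  type's posterior when observed. The final posterior is invariant to the
  order in which evidence is inserted; the growth path is not.
* **Backward reasoning** computes $P(B_i{=}\text{Yes} \mid Y_k, \cdot)$ and
  drives the iterative **critical-group** search: clamp the accident type,
  repeatedly select the highest-posterior behavior among those occurring in
  ≥ 8% of the type's cases, clamp it to Yes, and stop when every remaining
  posterior falls below 15%.
* **Re-rooting** redraws the same joint distribution with any behavior as
  the tree root (CPTs re-derived by per-class Bayes inversion), leaving all
  inference results unchanged.

Because the original 287-case matrix was never released, the package ships
a **synthetic generator** that emulates the study shape (class mix
191/39/33/24, 37 sparse binary indicators) from a fully specified ground
truth with planted per-type signature behaviors, which makes structure
learning, inference and diagnosis testable end to end.

## Worked example

The one quantity computable without case-level data is the no-evidence
class posterior implied by the published class tallies (F=191, C=39, S=33,
L=24 of 287 cases):

```python
from accident_bn import fit_tan, class_posterior, SmoothingPolicy
from accident_bn.reference_data import counts_matrix

model = fit_tan(counts_matrix(("B14", "B12")), SmoothingPolicy(0.5))
print((class_posterior(model, {}) * 100).round(1).to_dict())
```

```
{'S': 11.6, 'C': 13.7, 'F': 66.3, 'L': 8.5}
```

i.e. with no evidence a case is a fall with probability 66.3%; the 0.5
pseudocount nudges each raw rate (e.g. 191/287 = 66.6%) toward uniform.
On simulated data, feeding the fitted network an ordered chain of
fall-signature behaviors gives the per-step trajectory (percent):

```
                                           S     C     F     L
No evidence                             11.5  16.1  62.1  10.3
P(B14)=1                                25.5  13.0  48.8  12.7
P(B14)=1, P(B11)=1                      16.5   5.2  66.7  11.6
P(B14)=1, P(B11)=1, P(B24)=1             8.9   0.7  85.7   4.8
P(B14)=1, P(B11)=1, P(B24)=1, P(B12)=1   3.7   0.3  94.5   1.5
```

Reversing the insertion order changes the path but ends at the same 94.5%
(difference 0 to machine precision).

## Analysis pipeline

Numbered drivers under `analysis/` replay the full workflow on simulated
data and write their tables under `results/`:

1. `01_simulate_cases.py` — sample a study-shaped dataset from a known
   ground truth (cases, chains, truth record).
2. `02_fit_network.py` — filter cases, extract chains, binarize, learn the
   TAN and report the strongest edges and a re-rooted class conditional.
3. `03_forward_prediction.py` — posterior trajectories under two insertion
   orders of the same evidence.
4. `04_backward_diagnosis.py` — critical group per accident type, compared
   against the generator's planted sets.
5. `05_desk_checks.py` — the printed-tally computations (smoothed prior,
   root-behavior rate, eligibility rates, root-candidate ranking).

A `accident-bn` console command exposes the same steps
(`simulate`, `extract-chains`, `fit`, `predict`, `diagnose`, `report`).

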