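# Methods

## Model

A Bayesian network over features X₁…Xₙ is a DAG plus one conditional
distribution per node; the chain rule P(x) = ∏ᵢ P(xᵢ | pa(xᵢ)) entails the
joint. Three families are implemented, selected by the feature schema:

* **discrete** — all nodes categorical, CPTs over explicit level sets;
* **gaussian** — all nodes continuous; each node is Normal with mean linear
  in its continuous parents;
* **CLG** — mixed; a categorical node may only have categorical parents, and
  a continuous node gets one linear-Gaussian regime per joint configuration
  of its categorical parents, with mean linear in its continuous parents.

Parameters are maximum-likelihood: empirical conditional frequencies for
CPTs; per-regime least squares with the MLE (divide-by-n) variance for
Gaussian families. Structure search is steepest-ascent hill climbing over
single-arc additions, removals and reversals, scored by the fitted
log-likelihood (natural log), starting from the empty graph.

The over-sampler extracts the minority rows, drops the class column, learns
the network, forward-samples (logic sampling, topological order) n synthetic
rows, labels them with the minority class and appends them after the
original rows. n solves (m₊+n)/(M+n) = q with round-half-away-from-zero —
chosen over banker's rounding because the two differ by one row exactly at
half-integers and half-away matches the everyday reading of "nearest
integer". The cost-derived target is q = m₊γ/(m₊γ + m₋); for integer γ the
two formulas compose to n = m₊(γ−1) with no rounding error at all.

## Assumptions

* The class variable is binary after preprocessing, with minority proportion
  strictly below ½; the minority is the expensive class (γ = c₊/c₋ > 1).
* The minority subset is large enough to fit a network (≥ 2 rows; in
  practice far more for a useful fit).
* Synthetic rows are exchangeable with real minority rows for the purposes
  of classifier training — the usual over-sampling premise.

## Numerical and design choices

* **Pure log-likelihood scoring** makes every arc addition weakly beneficial
  on training data, so search termination relies on a strict minimum gain
  ε (default 1e-6, log-likelihood units) and an optional per-node parent cap
  (default unbounded). The unbounded default mirrors common practice for
  this score; the overfitting risk is real and a tree-width-style cap is the
  obvious refinement.
* **Determinism**: ties in the move ranking break on move type
  (add < remove < reverse) then lexicographically on (parent, child);
  topological sorting prefers node declaration order; every sampler takes an
  explicit seed and the CV harness derives fold/over-sampler seeds from one
  master seed via `SeedSequence` spawning, recorded in a per-result ledger.
* **Unseen discrete parent configurations** get a uniform CPT row, flagged,
  so the sampler is total without smoothing observed configurations.
* **Degenerate Gaussian regimes** (fewer than 2 rows, or a singular design)
  fall back to the pooled fit over all rows; standard deviations are floored
  at max(1e-6, 1e-3·sd(child)) so the sampler never emits NaN.
* **Missing data policy**: a missing categorical value becomes the dedicated
  level `__missing__` (collision-checked); a row with a missing continuous
  value is dropped. Strict schema mode (default) treats an undeclared
  categorical value as an error, because silent level growth corrupts CPT
  domains.
* **Decision rule tie**: c₋p₋ = c₊p₊ resolves to "+", favouring
  sensitivity; the strict inequalities of the rule leave equality open.
* **Paired comparison**: Shapiro–Wilk on the differences gates the choice
  (p < 0.05 ⇒ Wilcoxon signed-rank, zeros dropped, exact null when n ≤ 25
  with untied absolute ranks, else continuity-corrected normal
  approximation; otherwise paired t). All-zero difference vectors yield a
  non-significant degenerate verdict; constant nonzero ones a
  degenerate-significant verdict with the sign's direction. Zero-dropping
  (rather than Pratt's method) matches the dominant convention of the
  statistical software this pipeline is modelled on and does change p when
  zeros occur.
* **Folds** are stratified by default: with strong imbalance an
  unstratified split can strand every minority row in one fold and break the
  training-fold over-sampling step. A flag restores plain random folds.
* **Mann–Kendall** uses the tie-corrected variance, a continuity-corrected
  normal p-value, tau-b, and Sen's slope (median pairwise slope per index
  step) with the rank-based normal-approximation 95% CI.
* **SMOTE baseline** is intentionally minimal: Gower-style distance
  (per-feature absolute difference standardized by the minority sd for
  continuous, 0/1 mismatch for categorical), one interpolation coefficient
  per synthetic row, categorical values copied at random from the
  instance/neighbour pair. Which categorical distance the reference R
  implementation uses is undocumented, so this baseline is a documented
  convention, not a reproduction.
* BOSME's continuous outputs are **not clipped** to the observed range: the
  learned Gaussian is the model, and clipping would break its likelihood
  semantics.
* **KL evaluation**: when comparing a learned network to a generator over
  the full joint, estimated cell probabilities are floored at 1e-12 so the
  divergence stays finite when the MLE assigns zero to a configuration
  unseen in training; the floor affects only such zero cells.

## Synthetic data: what it emulates and what it does not

Problems are generated class-conditionally: one random network per class
over a shared schema (random node order; arc probability 2·density/(n−1);
Dirichlet(α=1) CPT rows — uniform over the simplex; CLG parameters uniform
in (−1,1)/(−1,1)/(0.5,1.5)), the negative-class network derived from the
positive one by perturbing CPT logits and Gaussian intercepts with a
divergence knob. This gives exactly computable Bayes-optimal and
cost-optimal rules by enumeration, which is what the Folk-theorem and
Bayes-error tests exploit. The fixture suite mirrors common benchmark
shapes: all-categorical 1728×6 with a 7.75% minority, mixed 462×9 (34.63%),
all-continuous 306×3 (26.47%).

What the generator does *not* emulate: label noise, feature measurement
error, non-Gaussian continuous marginals, feature distributions that no
Bayesian network of the assumed family represents, and covariate shift.
Passing tests therefore certify the machinery and its statistical contracts
on data whose generating process matches the model class — they do not by
themselves establish performance on real tabular data.

## Problem sizes used in tests and the acceptance script

Search-vs-exhaustive checks use 3 binary nodes × 50 rows (25 candidate DAGs)
over 20 seeds; sampling fidelity uses 50,000 draws from 3-node networks
(total-variation threshold 0.02); parameter recovery compares minority
sample sizes 500 and 5000 over 10 seeds; the end-to-end experiment uses a
400-row, 4-binary-feature problem (15% minority, divergence 1.5) with γ=20,
10 runs of stratified 10-fold CV, the in-repo naive Bayes as the classifier,
and no over-sampling as the comparator. These sizes were chosen as the
smallest at which each check is statistically meaningful.

## Known limitations

* Unbounded parents with a pure likelihood score can overfit small minority
  subsets; CPT enumeration is exponential in the number of discrete parents.
* The Wilcoxon exact-p criterion and the Sen CI index convention are one of
  several circulating conventions; both are documented above.
* The Mann–Kendall statistics printed for the published β-score series by
  its original analysis are not reproduced by the standard tau-b /
  median-slope definitions implemented here (exhaustive pair enumeration
  gives τ-b ≈ 0.883 for that series, while its Spearman ρ and p reproduce
  exactly); the variant behind those printed values is unclear, so they are
  not asserted anywhere.
* Logistic regression / random forests / SVM attach through the generic
  estimator adapter contract but are not part of the tested surface; the
  in-repo mixed naive Bayes is the reference classifier.
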