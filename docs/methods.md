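# Methods

## Problem and model

`kgadr` predicts adverse drug reactions (ADRs) as a link-prediction problem
on a typed knowledge graph with four entity kinds — drug, side effect,
target, indication — and three relations, each linking a drug to one
attribute kind (`has_side_effect`, `has_target`, `has_indication`).
Deciding whether a drug causes an ADR is deciding whether an unobserved
`has_side_effect` edge exists, i.e. knowledge-graph completion posed as
binary classification.

### Embedding

Each triple *(h, r, t)* is treated as a three-token sentence, and a
CBOW-style model predicts each token from the other two.  With one-hot
context vectors `x1, x2`, an input matrix `W1` (n × size) and an output
matrix `W2` (size × n), where n counts entities plus relation tokens:

    p(· | x1, x2) = softmax((x1 + x2) · W1 · W2)

Training minimises `−Σ_i log p(target_i | context_i)` over all 3T samples
of a T-triple corpus (each token of each sentence once as target, window
2 over a 3-token sentence).  After training, row i of `W1` is the vector
of token i; `W2` is kept but not exported.

The two context projections are **summed** by default, exactly as the
model equation is written; a `combiner="mean"` flag matches trainers that
average context vectors.  The output objective defaults to the **exact
full softmax** — faithful to the equations and affordable for
vocabularies up to a few tens of thousands — with a negative-sampling
mode (k noise tokens from the unigram^0.75 distribution, default k=5)
for larger graphs.

### Classifier

For a candidate pair the classifier input is the single difference vector
`x = v_ADR − v_drug`, scored by the standard logistic link
`P = σ(w·x + b)`, with `(w, b)` minimising the mean cross-entropy plus an
L2 penalty of strength 1/C (bias unpenalised).  As printed, the source
equation for P lacks the conventional minus sign in the exponent, making
it a *decreasing* function of `w·x + b`; since the training objective is
the standard cross-entropy and `w` absorbs the sign, the standard link is
implemented.  The backing solver is scikit-learn's `LogisticRegression`
(SAG, C=1, at most 10,000 iterations); tests verify the reached objective
against an independent L-BFGS minimisation of the same convex objective
to 1e-4.

### Evaluation

ROC points are traced at every distinct score threshold (prediction
positive when score ≥ threshold, so ties count positive), anchored at
(0,0) and (1,1); AUC is the trapezoidal area, which equals the pairwise
concordance statistic P(score⁺ > score⁻) + ½·P(tie) — asserted exactly in
property tests.  Precision, recall and F use the textbook formulas at
threshold 0.5 (no threshold is fixed by the protocol; 0.5 is the
package's convention), returning 0 with a warning when a denominator is
zero.

## Data protocol

Observed drug–indication pairs serve as classifier negatives (a drug's
indication cannot be its own side effect); drug–side-effect pairs are
positives.  `make_split` holds out `floor(0.1 × #indication pairs)` pairs
as test negatives and an equal number of side-effect pairs as test
positives, both drawn uniformly without replacement from independent
per-purpose random streams derived from the seed.  Held-out edges are
removed from the embedding corpus and from classifier training; target
edges are always retained.  Retained indication pairs are replicated
tenfold (identical duplicate rows) among the training negatives to offset
class imbalance.  Holdout rounding is floor, forced by the published
arithmetic (10% of 13,597 → 1,359).  At the published scale this yields
125,432 training positives, 12,238 × 10 training-negative rows and
1,359 + 1,359 test pairs, which the acceptance script recomputes.

`exclude_conflicts` removes any indication edge whose (drug, attribute)
pair is also asserted as a side effect of the same drug, keeping the
side-effect edge (the safety-conservative reading) and logging removals.
To make such graphs representable at all, the typed store allows exactly
one tail-kind exception: an entity of kind `side_effect` may appear as a
`has_indication` tail, mirroring drug-label vocabularies in which the
same clinical term is one drug's indication and another's side effect.

## Synthetic benchmark

`synthetic.generate` produces a block-model graph: drugs and attributes
of every kind are assigned to `n_clusters` latent clusters round-robin,
and each drug × attribute edge (side effects, targets, indications
independently) is drawn with probability `p_in` within a cluster and
`p_out` across.  Attribute kinds share the drugs' cluster assignment so
targets and indications carry side-effect-relevant information.  Defaults
— 200 drugs, 300 side effects, 100 targets, 100 indications, 5 clusters,
p_in = 0.3, p_out = 0.02 — keep the attribute ratios of a drug-label
graph at a scale where exact-softmax training finishes in about a minute
on one CPU.  `generate_null` repeats the procedure with `p_in = p_out`,
removing all planted structure.  `generate_scale_replica` reproduces the
published entity and pair counts (3,632 / 5,589 / 4,286 / 2,598 entities;
126,791 / 13,851 / 13,597 pairs) with unstructured uniform edges, for
exercising the split bookkeeping at full scale.

Benchmark runs use vector size 64 and 300 epochs (10 epochs for the
short-training comparison), median over three seeds — sizes chosen so the
full pipeline completes in a few minutes; the published operating point
(size 800, 2,500 iterations) is the package default for real-scale runs.

### What the benchmark does and does not show

On the signal graph the pipeline separates held-out positives from
negatives essentially perfectly (AUC ≈ 1.0), and more embedding epochs
never hurt.  But the matched **null** graph also yields AUC ≈ 1.0, not
chance.  The mechanism: because side effects and indications are disjoint
entity pools, every attribute co-occurs with exactly one relation token,
and CBOW training aligns each attribute vector with its own relation's
output direction.  Test positives are always side-effect entities and
test negatives always indication entities, so a classifier trained on
exactly that dichotomy can discriminate by *entity type alone*,
independent of any planted drug–attribute structure.

Consequences worth stating plainly:

* The benchmark's discrimination is dominated by relation-type signature,
  not by recovery of the latent clusters; passing it shows the pipeline's
  plumbing and optimisation work, not that cluster structure is needed.
* The same artefact is plausible in the real protocol whenever the
  indication and side-effect vocabularies are imperfectly shared: using
  indication pairs as negatives rewards any feature that encodes "which
  relation does this attribute usually appear in".  Real-world AUC
  estimates under this design should be read with that caveat.
* Removing the artefact would require drawing indications and side
  effects from one shared id pool, which the typed triple schema (tail
  kind determined by relation) does not represent.  The chance-level
  expectation for the null graph is asserted in the acceptance suite and
  currently fails for this reason; the permutation control (shuffling
  test labels, which breaks the type–label correlation) does sit at
  chance, confirming the evaluation machinery itself is unbiased.

## Numerical choices

* **Initialisation**: `W1 ~ U(−0.5/size, +0.5/size)`, `W2 = 0` (keeps the
  initial softmax uniform, so the initial mean loss is exactly ln n).
* **Optimiser**: minibatch SGD, per-sample gradients summed within a
  batch (default 256) — equivalent to classic per-sample word2vec SGD up
  to within-batch staleness — with the learning rate decaying linearly
  from 0.025 to 1e-4 over total updates.  Setting `batch_size` at or
  above the sample count with a constant rate gives full-batch descent,
  used by the monotone-loss tests.
* **Precision**: weights default to float32 (the word-embedding norm);
  gradient-verification tests run in float64.
* **Determinism**: one `numpy` PCG64 generator seeded by `random_state`
  drives initialisation, shuffling and noise draws; identical inputs and
  seed give bit-identical matrices.  Vocabulary indices are assigned
  relations-first, then entities by first appearance, so two loads of the
  same file embed identically.
* **Degenerate inputs**: empty corpora, single-class training labels,
  unknown tokens, malformed files and non-finite losses all raise with
  specific messages; duplicate triples collapse with a logged count.
* **Ranking ties** break lexicographically by drug id.

## Known limitations

* Entity-type leakage in the evaluation design, discussed above.
* The full-softmax objective is O(n) per sample; beyond a few tens of
  thousands of tokens use `mode="negative_sampling"`.
* Probabilities are not calibrated, and severity is out of scope: the
  model only scores whether a link exists.
* Single-triple sentences only; multi-hop path corpora are not
  implemented.
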