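# kgadr — adverse-drug-reaction prediction by knowledge-graph embedding

Adverse drug reactions (ADRs) surface slowly: clinical trials are too small
and too short to observe rare side effects, so many are discovered only
after approval.  `kgadr` is for computational pharmacologists and
pharmacovigilance researchers who want to *predict* unreported drug–ADR
links from what is already curated about each drug — its known side
effects, protein targets and approved indications — organised as a typed
knowledge graph.

## The model

The data are triples *(h, r, t)* over four entity kinds — drug, side
effect, target, indication — and three relations, each linking a drug to
one attribute kind (`has_side_effect`, `has_target`, `has_indication`).
The question "does drug *d* cause ADR *s*?" is knowledge-graph completion:
does the unobserved edge *(d, has_side_effect, s)* exist?

**Embedding.**  Each triple is treated as a three-token sentence and a
CBOW-style model predicts every token from the other two.  With one-hot
context vectors x₁, x₂, an input matrix W₁ ∈ ℝ^{n×size} and an output
matrix W₂ ∈ ℝ^{size×n} (n = entities + relation tokens),

```
p(· | x₁, x₂) = softmax((x₁ + x₂) · W₁ · W₂)
```

trained by minibatch SGD on the negative log-likelihood
−Σᵢ log p(targetᵢ | contextᵢ), three samples per triple.  Row i of W₁ is
the learned vector of token i.  The exact full softmax is the default
(with a negative-sampling mode for large vocabularies).

**Classifier.**  A candidate (drug, ADR) pair becomes the single feature
vector x = v_ADR − v_drug, scored by L2-regularised logistic regression,
P(link) = σ(wᵀx + b).  Observed drug–indication pairs serve as negatives
(a drug's indication cannot be its own side effect), replicated tenfold to
offset class imbalance; observed drug–side-effect pairs are positives.

**Evaluation.**  A balanced held-out set — floor(10% of indication pairs)
as negatives and an equal number of side-effect pairs as positives,
removed from both the embedding corpus and classifier training — is
scored by ROC/AUC, precision, recall and F.  See `docs/methods.md` for
the full protocol, numerical choices, and an honest analysis of what the
synthetic benchmark does and does not demonstrate.

## Worked example

Generate a synthetic block-model graph (drugs and attributes share latent
clusters, so a drug's targets/indications predict its side effects) and
run the full pipeline — conflict removal, split, embedding, classifier,
evaluation — in one call:

```python
from kgadr import GeneratorParams, generate
from kgadr.pipeline import RunConfig, run_once

kg, truth = generate(GeneratorParams(seed=7))
print("triples:", kg.relation_counts())

cfg = RunConfig(size=64, iters=120, seed=7)
report, embedder, model, bundle = run_once(kg, cfg, seed=7)
print(f"test pairs: {len(bundle.test_pairs)}")
print(f"AUC       : {report.auc:.4f}")
print(f"precision : {report.precision:.4f}")
print(f"recall    : {report.recall:.4f}")
print(f"F-score   : {report.f_score:.4f}")
```

Output:

```
triples: {'has_target': 1547, 'has_indication': 1513, 'has_side_effect': 4541, 'total': 7601}
test pairs: 302
AUC       : 1.0000
precision : 1.0000
recall    : 1.0000
F-score   : 1.0000
```

The 302 test pairs are 151 held-out side-effect edges (positives) and 151
held-out indication edges (negatives), none of which the embedding or the
classifier ever saw.  An AUC of 1.0 means every held-out positive
outscored every held-out negative.  On this benchmark that separation is
easier than it looks: side effects and indications are disjoint entity
pools, and the embedding partly encodes *which relation* each attribute
appears in — a caveat analysed in `docs/methods.md`.

Ranking candidate drugs for one ADR:

```python
from kgadr.classifier import rank_drugs_for_adr
vectors = embedder.vectors()
drugs = sorted(kg.entities_of_kind("drug"))
for p in rank_drugs_for_adr(model, vectors, "S0000", drugs, top=3):
    print(p.drug, p.adr, f"{p.probability:.3f}")
```

```
D0104 S0000 1.000
D0097 S0000 1.000
D0030 S0000 1.000
```

The same pipeline is available stage by stage on the command line
(`kgadr synth | build-kg | split | embed | train | evaluate | rank`), with
every artifact a plain-text file; `kgadr --help` lists the options.  The
defaults of `RunConfig` / `TripleCBOW` (vector size 800, 2,500 epochs,
C = 1) are the real-scale operating point; the small sizes above are for
a desk-scale demonstration.

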