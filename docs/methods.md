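# Methods

## Problem and data model

Given a set of herbs H, a set of protein targets T, and observed
interactions P ⊂ H × T, the task is to rank, for each herb, the targets it
is most likely to interact with among those not already known. Interactions
are split 8:1:1 into train/validation/test at the pair (edge) level by a
seeded uniform shuffle, with `floor` rounding for the validation and test
counts and the remainder to train — the split is therefore a pure function
of (pairs, ratios, seed). When building benchmarks from evidence-scored
interaction exports, pairs are kept when their inferred evidence score
strictly exceeds the threshold (default 0.4616, the database-wide mean used
by SymMap-style resources) and their P-value is strictly below 0.05.

Entity ids are strings namespaced by type (`herb:`, `target:`, …), which
makes herb/target vocabulary disjointness trivial to enforce and lets
knowledge-graph and interaction files share one id space.

## Knowledge-graph embedding pre-training

The knowledge graph is walked as an **undirected, unlabeled** simple graph:
relation types and directions are ignored, because the downstream consumer
only needs structural proximity, and the walk-based objective is type-blind.
Three backends produce the initial features e⁰:

* **DeepWalk** — uniform random walks feeding a skip-gram objective: for
  each walk position i, maximize Π_{j∈[i−w,i+w], j≠i} Pr(v_j | Φ(v_i)).
* **node2vec** — identical pipeline with the second-order transition law
  (weight 1/p to return to the previous node, 1 to nodes at distance one
  from it, 1/q outward). The implementation applies the second-order law at
  every step after the first, so p = q = 1 reduces to the uniform walk
  mathematically rather than by a separate code path.
* **HOPE** — Katz proximity S = (I − βA)^{-1} βA factorized by truncated
  SVD; entity vectors concatenate source and target factors scaled by
  square roots of the singular values. β must satisfy β·ρ(A) < 1 (checked;
  the error reports the computed spectral radius).

The skip-gram likelihood is optimized by negative sampling (5 negatives from
the unigram^0.75 noise distribution) with mini-batched SGD and a linearly
decaying step size starting at 0.025. Two deliberate departures from the
classic word2vec loop: the context window is **fixed** (not randomly
shrunk per position) and updates are applied per mini-batch rather than per
pair. Both make the result an exact deterministic function of the seed at a
negligible cost in embedding quality at the graph sizes involved. Walk
defaults — 10 walks per node, length 40, window 5, 5 epochs — follow common
practice for walk-based embeddings; all are configurable, and the window is
the knob with documented downstream sensitivity. Entities never visited by
walks (isolated nodes) receive seeded random vectors instead of failing,
since large knowledge graphs routinely contain them.

`LINE` and `GraRep` are recognized as deliberately unsupported backend
names with an explicit error. `none` draws standard-normal vectors scaled
by 1/√dim — the no-pre-training ablation.

## Residual linear graph convolution

Only **training-split** edges enter the bipartite adjacency A (herbs first,
then targets, both sorted), so held-out pairs are structurally invisible to
propagation — the same leakage guard applies to the synthetic knowledge
graph, which embeds train positives only.

The canonical normalization is the symmetric
S = D̃^{−1/2}(A + I)D̃^{−1/2} with D̃ the degree matrix of A + I. A second
mode, `product`, implements the per-node coefficient scheme in which a
node's self term is 1/d̃ᵢ and a neighbour contributes a_ij/(d̃ᵢ·d̃ⱼ). The
two are inconsistent with each other as written in the per-node vs matrix
presentations of linear GCN propagation; this package treats the matrix
form as canonical (it is symmetric, its eigenvalues lie in [−1, 1], and it
is the standard choice in parameter-free linear GCNs) and keeps `product`
as a configurable alternative. In the per-node reading, the inner sum for a
target's update runs over the herbs adjacent to that target — the only
type-consistent interpretation.

Propagation is purely linear: E^{k+1} = S E^k W^k with no nonlinearity.
W^k is the identity by default (the parameter-free LightGCN-style
convention, consistent with removing nonlinear activations); learnable
per-layer maps are available behind `learn_weights=True`, initialized at
I + 0.01·N(0,1) so training starts at the identity behaviour. The final
representation is the **unweighted** residual sum e = Σ_{k=0}^{K} e^k
(mode `residual`), or E^K alone (mode `last_layer`, the no-residual
ablation). K = 0 reduces the whole model to scoring on e⁰.

If the pre-trained dimension differs from the GCN dimension, a seeded
random linear projection is applied once at load time and logged; the two
dimensions are equal in every default configuration.

## Training

Scores are dot products of the final herb/target vectors. For each train
positive (h, t⁺), `negatives_per_positive` targets t⁻ are drawn uniformly
from the targets not positive for h **in any split** (rejection sampling) —
excluding only train positives would let genuine held-out interactions be
trained on as negatives. The loss over a batch is
Σ −ln σ(r̂_{ht⁺} − r̂_{ht⁻}) + λ‖Θ‖², where Θ is the E⁰ rows touched by the
batch plus any learnable layer weights, and −ln σ(x) is evaluated as
`logaddexp(0, −x)` so margins beyond ±700 cannot overflow.

Because the model is linear end-to-end, gradients are computed analytically
by reverse-mode through the K-layer propagation (the residual read-out
sends the output gradient into every layer; each layer back-propagates
through Sᵀ and W^kᵀ). The test suite verifies them against central
differences to 10⁻⁴ relative error for all parameter groups.

Optimization is mini-batch Adam (step 10⁻³, batch 1024, λ = 10⁻⁴ by
default — the regularization weight is treated as a tunable since no
canonical value exists; one negative per positive by default). Negatives
are resampled each epoch with a per-epoch seed. Validation HR@10 is
monitored each epoch; training stops after 20 epochs without improvement
and the best-validation state is restored (the post-last-step state is also
kept on the result object). A non-finite loss aborts with a diagnostic
rather than silently producing NaN rankings. With fixed seeds and
single-threaded execution the entire fit is bit-reproducible.

One consequence of Adam worth noting for extreme settings: with a very
large λ the parameters do not converge to exactly zero but orbit a limit
cycle of amplitude O(lr/(1−β₁)) around it, so "collapse" assertions are
made up to that amplitude.

## Evaluation

For each herb with at least one positive in the evaluated split, every
target except the herb's *train* positives is scored (held-out positives
must remain rankable), sorted by descending score with lexicographic
tie-break, and scored by

* HR@K = |top-K ∩ G_h| / |G_h| — note this is a recall at K (denominator
  |G_h|); the name follows the field's convention for this quantity;
* NDCG@K with binary relevance, DCG@K = Σ_{i≤K} (2^{r_i}−1)/log₂(i+1),
  normalized by the ideal gain over **all** |G_h| positives ranked first
  (not truncated at K). The untruncated ideal keeps NDCG@K non-decreasing
  in K and equal to 1 exactly when every positive is retrieved; with the
  K-truncated convention a perfect prefix would score 1 even while
  positives remain unretrieved, and the metric could decrease in K.

Metrics are macro-averaged uniformly over evaluated herbs (micro vs macro
is unspecified in common usage; macro is the package's choice and is
reported together with the number of evaluated herbs). The closed-form
expected HR@K of a uniformly random ranking, min(K, n)/n per herb with n
the candidate count, is provided for calibration. A `novel_only` report
mode additionally hides val/test positives when exporting predictions, for
case-study-style lists of genuinely novel candidates.

### Local-similarity baselines

Common-neighbour indices are defined on unipartite graphs, but a herb and a
target in a bipartite graph share no neighbours by construction. The
package adapts them by **herb-side projection**: herb–herb similarity over
shared target neighbourhoods (CN = |Γ∩Γ′|, Salton = CN/√(kk′),
Jaccard = CN/|Γ∪Γ′|, HPI = CN/min(k,k′), LHN-1 = CN/(kk′),
AA = Σ_z 1/log k_z, RA = Σ_z 1/k_z), and score(h, t) = Σ_{h′∈Γ(t), h′≠h}
sim(h, h′). This projection is a documented design choice, not the only
possible bipartite adaptation. In AA, a common neighbour of degree 1 would
make 1/log k_z undefined; it contributes 0 by convention (such a neighbour
carries no sharing information beyond the pair itself).

## Synthetic benchmark

The planted-block generator is the package's controlled stand-in for a
curated interaction benchmark. Herbs and targets are assigned round-robin
to `n_blocks` latent blocks; a within-block pair is positive with
probability `p_in` = 0.3, a cross-block pair with `p_out` = 0.01, over a
40-herb × 80-target grid in 4 blocks by default — sized so that one herb has
a realistic handful of targets, block recovery is learnable from ~200
training edges, and the full train/evaluate cycle stays in seconds. Every
herb is guaranteed at least one positive (empty herbs get one uniform
same-block target). The companion knowledge-graph generator embeds the
train positives as herb–target triples and wires auxiliary entities
(symptoms, diseases, efficacy terms, ingredients, meridians, properties,
pathways, GO terms) with the same block preference, so knowledge-graph
proximity carries real signal about interactions.

What the fixture does **not** emulate about curated data: heavy-tailed
degree distributions (real benchmarks have hub targets with hundreds of
herbs), correlated evidence noise, typed relation semantics, and scale
(hundreds of herbs × thousands of targets). Passing tests on the fixture
demonstrate that the pipeline recovers plantable structure and that its
components are numerically correct — not that the model attains any
particular accuracy on curated herb–target data.

A useful calibration fact about the fixture: conditional on the revealed
training edges, a herb's held-out within-block targets are exchangeable
with its within-block non-edges, so **no ranker can beat block-perfect
ordering in expectation**. The expected HR@10 of that Bayes-optimal ranking
is ≈ 4.5× the random-ranker expectation under the default parameters; the
trained model's observed lift of ≈ 4.0–4.3× should be read against that
ceiling, not against 1.0.

## Pipeline and reproducibility

One global seed fans out to the split (+11), embedding (+22) and training
(+33) stages, so a single integer reproduces a full run; the manifest
records the config, its hash, the derived stage seeds and library versions,
and rerunning the same config yields byte-identical metrics JSON. Sweeps
over the layer count reuse the pre-trained embedding matrix (the embedding
stage does not depend on K); dimension and window sweeps re-run it. On a
stage failure, artifacts already written are renamed with a `.partial`
suffix and the error propagates with a nonzero exit.

## Known limitations

* Pre-training walks ignore relation types; semantically typed embedding
  schemes (metapath walks, translational KGE) are out of scope.
* The skip-gram and BPR optimizers are single-threaded NumPy; they are
  sized for desk-scale graphs (10⁴–10⁵ entities), not web-scale corpora.
* The bipartite adaptation of the similarity baselines is one of several
  defensible choices; absolute baseline numbers depend on it.
* Early stopping selects on validation HR@10 only; with very small
  validation splits the selection is coarse (ties are common), and the
  best-validation state can be an early epoch.
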