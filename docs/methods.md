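# Methods

## Model

`molpref` learns a latent desirability score for small molecules from
pairwise choices.  Given molecules m_1 … m_n and comparisons of the form
"m_i was chosen over m_j", a scoring function s: M → R is fit such that

    p(m_i ≻ m_j) = σ(s(m_j) − s(m_i)),

the Bradley–Terry / ELO family of paired-comparison models with a neural
parameterization of s.  **Lower scores mean more preferred** throughout the
package.  The underlying score-difference model is sign-symmetric, so the
direction is purely a reporting convention; we fix it once, prominently, and
use it everywhere (score tables, fragment rankings, set discrimination).

s is a feed-forward network over a molecular feature vector: a
2048-dimensional count-based extended-connectivity fingerprint (radius 2)
concatenated with a panel of 2D descriptors (the toolkit's full 2D catalogue
minus the `fr_*` substructure counters; 125 names frozen in the default
spec, config-overridable).  Features are standardized per-feature with
statistics fitted on training molecules only and reused verbatim at
inference, so no information leaks from scoring-time libraries.

Both "legs" of the pair share one parameter set; the pair probability is a
deterministic function of the two scores, which makes the antisymmetry
p(i,j) + p(j,i) = 1 exact by construction rather than approximate.

### Training

Binary cross-entropy on σ(s_j − s_i) against the observed choices, plus a
regularizer λ‖ŝ‖² over the batch scores.  The BCE term depends only on
score *differences* and is translation-invariant; the regularizer pins the
score scale to the origin.  λ defaults to 1e-6 — enough to fix the gauge
without noticeably shrinking the spread.  Under this default the empirical
score distribution stays within |s| ≈ 9; `clamp_score` exposes that boundary
for downstream consumers (e.g. generative-model scoring callbacks) that
would otherwise over-exploit the model far outside its training domain.

Optimization is minibatch Adam (lr 3e-4, batch 32, up to 100 epochs, early
stop after 10 epochs without improvement > `min_delta` = 1e-5).  The linear
head is **zero-initialized**: an untrained model scores every molecule 0,
so the pre-training loss on balanced labels is exactly ln 2 and training
starts from the uninformed state instead of from initialization noise.
Hidden layers (256, 128, ReLU, He init) carry dropout 0.2, the same rate
reused for Monte Carlo dropout at acquisition time.  Training dropout uses
independent per-example masks; fixed config seed ⇒ bitwise-reproducible
parameters.

The network, backpropagation, Adam and dropout are implemented directly in
NumPy; the model is small (~0.6 M parameters) and self-contained, and
owning the forward pass lets inference-time dropout share one mask across
both legs (below).

### Cross-validation

Randomized k-fold (default 5) **over pairs**, not molecules: a molecule may
appear on both sides of the split, matching how repeated responses are
evaluated during data collection.  Held-out performance is AUROC of
predicted pair probabilities against the held-out labels.  Molecule-disjoint
splitting can be had by partitioning the pool before pair generation (the
synthetic benchmark does exactly this for its held-out recovery check).

## Curation

Standardization keeps the largest organic fragment (salt stripping),
neutralizes simple protonation states, and optionally canonicalizes
tautomers (off by default: slow and toolkit-version-sensitive; salt
stripping and neutralization are always on).  Pool filters: molecular
weight 200–1000 g/mol, QED 0.2–0.9, at most 2 rule-of-five violations, no
structural-alert hits.  Choices the thresholds do not pin down:

- **Rule-of-five violations**: count of {MW > 500, cLogP > 5, H-bond donors
  > 5, acceptors > 10} exceeded — the standard operationalization.
- **Fused-ring statistic**: SSSR rings are connected when they share ≥ 1
  bond; `max_fused_system` is the largest connected-component size, so
  anthracene counts 3 and spiro or biphenyl junctions do not fuse.  A
  molecule is "hard" at ≥ 3 fused rings (threshold exposed) or > 10
  rotatable bonds (strict definition: non-ring single bonds between
  non-terminal heavy atoms, amides excluded — counts differ across
  conventions, so the convention is pinned here).
- **Alert set**: the engine is SMARTS-collection-agnostic.  The shipped
  default is a compact set of 12 common reactive/toxicophore motifs (nitro,
  aldehyde, acyl/alkyl halide, epoxide/aziridine, azide, isocyanate,
  peroxide, hydrazine, thiourea, Michael acceptor, quaternary nitrogen);
  a full corporate catalogue can be loaded from a (name, SMARTS) CSV.

Hardness flags do not gate pool membership; they gate *pair* membership:
a pair is rejected only when **both** members are hard, since such
comparisons give annotators no preference handle.

## Pair generation and acquisition

The curated pool is grouped into k clusters (default 1000) by k-means over
binary fingerprints.  Empty clusters (possible when fingerprints collide
exactly, e.g. chain homologues) are re-seeded with the farthest point of the
largest cluster, so every label is populated.  Initial-round batches draw
clusters without replacement — no cluster label repeats within a batch —
then one uniform molecule per cluster, rejecting both-hard draws up to a
retry budget (cluster-size-weighted sampling would be a defensible
alternative; uniform keeps small clusters represented).

Acquisition batches rank uniformly sampled candidate pairs (default 100×
the batch size) by the variance of the predicted score difference over
T = 100 Monte Carlo dropout passes at rate 0.2.  Per pass one mask is
sampled and applied to both legs: the legs share weights, so sharing the
mask makes the uncertainty of an identical pair exactly zero and isolates
disagreement about the *difference*; an independent-mask mode exists for
comparison.  Selection is a greedy descending-variance sweep admitting at
most one comparison between any unordered cluster pair per batch — a
deliberately weaker constraint than the initial-round no-repeat rule,
since later batches must keep drawing from a fixed set of clusters.  Ties
break by (variance, lexicographic pair id), making selection independent of
candidate ordering.

## Agreement statistics

Choices are coded by *molecule identity* within the pair, never by screen
side, so side randomization cannot corrupt agreement; the left/right
positional-bias test (exact two-sided binomial against 0.5) uses the side
coding separately.  Fleiss' κ is computed on the non-redundant shared
pairs, restricted to raters who answered every item (the equal-ratings
table the statistic requires); the redundant repeats feed only per-rater
Cohen's κ.  When chance agreement is 1 (a single category used throughout)
κ is undefined and reported as NaN with a warning.

## Score audits

- **Descriptor correlations**: Pearson r between learned scores and each
  panel descriptor, aggregated as mean ± sd over models trained with
  different seeds, sorted by |mean r|; constant descriptors report r = 0
  with a flag.
- **Set discrimination**: ROC AUC separating each named set from a control
  set with lower score as the positive direction, plus one-way ANOVA across
  all sets.
- **Fragment preference**: BRICS leaf fragments carry attachment atoms the
  model never saw, so a fragment is scored as the mean learned score of the
  molecules containing it (each parent counted once per fragment, even if
  the fragment occurs twice in it — attribution is molecule-level).
  Fragments with fewer than 5 parents (configurable) are omitted to avoid
  over-reading rare motifs.

## Synthetic data

The generator emulates the *shape* of the study inputs, not medicinal
chemistry itself.  A fragment grammar (18 drug-like ring cores × 10 linkers
× 15 terminal rings) produces the passing pool; dedicated violator families
cover each filter predicate — sub-200 Da fragments (`mw_fail`), long greasy
chains with QED < 0.2 (`qed_fail`), permethoxylated terphenyls with three
rule-of-five violations but in-range QED (`ro5_fail`), nitro-decorated
assemblies (`alert_fail`) — plus pool-passing hardness cases (flexible
bis-aryl ethers > 10 rotors; carbazole-like fused tricycles).  Default mix:
80% pass + 4% hardness-flagged + 16% violators, i.e. 84% of the pool passes
the default filters.  Every molecule is verified against the curation module
at generation time before receiving its tag, so subset semantics are
guaranteed by construction rather than assumed.

The labelling oracle is **linear in named descriptors** (default:
−1·QED + 0.4·cLogP + 0.3·rotatable bonds, standardized to zero mean/unit
variance over the fitted pool) — deliberately not fingerprint-based, so
recovery is measured against an interpretable ground truth the model must
reach through its own featurization.  Labels follow
Bernoulli(σ(β·(s*_j − s*_i))) with β = 5 by default; the recovery benchmark
uses β = 20 ("near-deterministic": |Δs*| of 1 ⇒ > 0.999 label certainty).
Simulated raters follow the oracle's deterministic preference with
probability p_c (default 0.85) and flip otherwise, with redundant repeats
and randomized sides so agreement inputs have the full schema.

What passing the synthetic benchmark does **not** show: real annotator
preferences are not linear in three descriptors, are inconsistent in
structured (not i.i.d.) ways, and real pools are far more diverse than a
2700-combination grammar.  The benchmark validates the machinery —
curation semantics, feature plumbing, optimization, uncertainty, and the
statistics — not chemical validity of any learned preference.

## Benchmark problem sizes

The standard synthetic benchmark is 600 molecules (≈ 500 filter-passing,
20% held out molecule-disjoint) and 2000 labelled pairs at β = 20, trained
with a 40-epoch budget (the benchmark converges well before the 100-epoch
default; cross-validation trains six models).  Typical results, recomputed
by `scripts/acceptance.py`: 5-fold CV AUROC ≈ 0.98 and held-out
Spearman(ŝ, s*) ≈ 0.97.

## Numerical choices

- BCE is evaluated as `logaddexp(0, −δ) + (1−y)·δ` on the logit scale —
  exact and overflow-free; the sigmoid uses the two-branch stable form.
- MC-dropout variances are centered on the first pass before the sample
  variance (mathematically a no-op) so degenerate cases (rate 0,
  identical pairs) return exactly 0.0 rather than 1e-31.
- Constant features standardize to exactly 0; non-finite descriptor values
  are imputed to 0 with a logged warning rather than crashing featurization.
- Checkpoints bundle weights + featurizer spec (including normalization
  statistics) in one `.npz` with a JSON metadata block; no pickling.

## Known limitations

- No ties/abstain outcomes: a choice is forced, as in the study design.
- CV by pair shares molecules across folds; use the molecule-disjoint
  pattern of the benchmark when that optimism matters.
- The default alert set is a teaching-sized stand-in for a full catalogue.
- Exact pool counts from a given database are toolkit-version-sensitive
  (standardization and descriptor implementations drift between releases).
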