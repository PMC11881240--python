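# Methods

## Compatibility statistic

A corpus is a list of prescriptions, each a *set* of herb identifiers
(dosage-ignorant; a herb counts once per prescription). For prescription k of
size n_k and unordered pair (i, j):

    C_ij = N_ij / D × 1000,   D = Σ_k n_k (n_k − 1) / 2,

with N_ij the number of prescriptions containing both herbs. Every
prescription contributes exactly C(n_k, 2) co-occurrences to Σ_ij N_ij, so
Σ_ij C_ij = 1000 identically; this conservation is used as a standing
invariant in the tests. A corpus where every prescription is a singleton has
D = 0 and is rejected as degenerate. Prescriptions with identical herb sets
are collapsed to one record on ingestion, so a study entered twice does not
double-count. Clinical use counts (`frequency`) deliberately do **not**
weight C_ij — the statistic counts prescriptions, not uses; frequency only
enters the suitability stratification.

Molecule screening keeps molecules with oral bioavailability ≥ 30
(percent scale) and drug-likeness ≥ 0.18, both boundaries inclusive, and
drops annotation links of removed molecules. The filter is idempotent and
leaves herbs, targets and prescriptions untouched.

## Graph

Node types: herb, molecule, target. Edge types: herb–herb for every pair
with N_ij > 0 (carrying C_ij symmetrically), herb–molecule annotation links,
molecule–target interaction links. All three relations are treated as
undirected for message passing (each stored pair is expanded into both
directions), since neighborhood aggregation has no natural direction here.
Herb–herb connectivity is reported in both conventions — unordered pairs and
the doubled directed count — because published edge tallies for such graphs
are ambiguous about the convention (the totals in the motivating table are
not internally consistent under either reading, so this package reports its
own recount).

Herbs carry no intrinsic features (embeddings are learned); molecules carry
a MACCS-style binary fingerprint (length configurable, default 166); targets
carry a binary vector over whatever functional-term vocabulary the input
provides — no ontology download, no DAG propagation.

## Model

Base features per type: a learned embedding of width `hidden_channels`; for
molecules and targets the intrinsic feature vector is mapped to that width
by a learned linear projection and **added** to the embedding, keeping a
uniform width across types.

Each of the two GCN layers performs a SAGE-style update per relation r into
node type t:

    z_v = Σ_r W_r · CONCAT(h_v, mean_{u ∈ N_r(v)} h_u) + b_t,
    h_v' = ReLU(z_v),

i.e. one (self, neighbor) weight pair per relation and layer, outputs summed
over incoming relations, mean aggregation, and a zero vector for an empty
neighborhood. The mean aggregator is the canonical default for this operator
family. Two layers let herb representations see molecules (one hop) and
targets (two hops).

Pair scoring concatenates the two final herb embeddings, applies a
one-hidden-layer MLP (ReLU hidden, width `mlp_hidden`, default equal to
`hidden_channels`) and a softplus output. Softplus guarantees ŷ ≥ 0, so
HCPI = log₂(ŷ + 1) is always defined, while keeping gradients alive where a
ReLU head would die. Because concatenation is order-sensitive and
compatibility is symmetric, the reported score is the average of both input
orders (and training backpropagates through both). A consequence of the
softplus head worth noting: a zeroed output layer predicts the constant
softplus(0) = ln 2 for every pair, not 0.

Training minimizes MSE over the labeled pairs plus uniformly drawn
zero-label negative pairs (herb pairs that never co-occur), at a 1:1 ratio
per epoch by default, re-drawn each epoch from a per-epoch seeded stream.
Without negatives the regressor sees only positive mass and has no contrast.
Optimization is full-batch Adam (the graphs involved are small enough that a
full-batch step costs milliseconds) for a fixed 60 epochs, the convergence
horizon used for the reference fit. Gradients are exact reverse-mode
derivatives written out by hand and verified against central finite
differences in the test suite (agreement to ~1e-8 relative). A non-finite
loss aborts training with the epoch index.

### Cross-validation

Grid search runs over hidden_channels {64, 128, 256, 512} × learning rate
{1e-4, 1e-3, 1e-2}, five folds. Splits are **edge-level**: the fold's
held-out pairs are removed from (a) the supervision set, (b) the negative-
sampling candidate pool (a held-out positive must not be presented as a
zero-label pair), and (c) the herb–herb message-passing edges, so evaluation
measures generalization to genuinely unseen pairs. Fold assignment is
stratified by label quantile (sorted labels, fold rotation within
consecutive groups) and fully seeded. A configuration that diverges on any
fold, or whose held-out labels are degenerate, reports R² as an explicit
undefined marker (`None` in the API, `/` in exported tables). Both the
held-out R² and the training-fit R² are reported, since a single "model R²"
is ambiguous between the two.

## Derived scores

* HCPI(ŷ) = log₂(ŷ + 1); strictly increasing, zero at zero. Screening keeps
  pairs with HCPI **strictly** greater than the threshold (default 0.5).
* Prescription suitability = log₂(mean + 1) of the mean predicted strength
  over all C(n, 2) pairs of the prescription's resolvable herbs. The +1
  inside the logarithm mirrors HCPI and keeps zero-mean prescriptions
  finite; it is a deliberate choice where a bare log₂(mean) would be
  undefined at zero. By default the pair values are model predictions, so
  clinical prescriptions containing pairs absent from the training corpus
  are still scorable; a raw-C_ij mode is available. Out-of-vocabulary herbs
  are skipped with a warning; fewer than two resolvable herbs yields an
  unscorable marker rather than an error.
* Frequency comparison: prescriptions used strictly more than 10 times form
  the high-frequency group; suitability is compared with a two-sample
  t-test, Welch (unequal-variance) form by default with the pooled form
  behind a flag, since the pooled assumption is rarely defensible for
  clinical strata of very different sizes.

## Enrichment

Per term: upper-tail hypergeometric P(X ≥ k) with N = background size,
K = term size, n = query size, k = hits (so k = 0 gives p = 1 exactly);
Benjamini–Hochberg step-up across all tested terms. The background defaults
to the union of term-annotated ids; the query must be a subset of it. Terms
with K < 2 are untestable and skipped. Enrichment only — depletion is out of
scope.

## Synthetic corpora

The generator emulates a curated corpus of expert prescriptions plus
molecular annotation, with planted ground truth:

* Herbs are partitioned into `n_blocks` contiguous communities. Each
  prescription seeds one block uniformly and samples its herbs without
  replacement with selection odds multiplied by `within_block_boost` (≥ 1)
  for the seeded block. Boost 1 gives a null corpus; boost ≥ 5 plants
  strong, recoverable community structure. The block model is the simplest
  generator with controllable pair affinity matching the premise that herbs
  cluster into synergistic combinations.
* Default scale mirrors the reference corpus profile: 122 herbs, 72
  prescriptions of 5–15 herbs, a pool of 360 molecules of which ≈ 65% pass
  the OB/DL screen (≈ 234 survivors), 657 targets, 40 functional terms.
  OB and DL are drawn from uniform ranges straddling the 30 / 0.18
  thresholds — only threshold behavior matters for testing the filter, so
  no attempt is made to fit realistic pharmacokinetic distributions.
* Clinical records reuse the corpus herbs (same block structure), replace a
  fraction `oov_fraction` (default 5%) of member slots with out-of-
  vocabulary herbs, and draw use counts from a geometric distribution
  (p = 0.15), which populates both the > 10-use and ≤ 10-use strata.
  Frequencies are drawn **independently of composition**, so the expected
  outcome of the frequency-group comparison on synthetic data is a null
  (non-significant) result; the pipeline tests assert the mechanics, not an
  effect the generator does not plant.

What the generator does *not* emulate: real chemistry (fingerprints are
i.i.d. sparse bits, not substructure keys), dosage, herb taxonomy, realistic
OB/DL distributions, shared molecules inducing herb similarity beyond
chance, or any dependence of clinical frequency on quality. Passing tests
therefore demonstrate that the machinery recovers planted co-occurrence
structure, not that it predicts real pharmacology.

## Problem sizes and numerical choices

The recovery benchmark used in tests and in `scripts/acceptance.py` is a
4-block × 10-herb corpus with 200 prescriptions of 4–8 herbs and boost 10; a
20-herb variant backs the faster unit tests, and the 12-configuration grid
is exercised at reduced epochs where only the table's shape is under test.
On the recovery corpus the two-group structure bounds attainable held-out R²
at roughly 0.72 (binomial sampling noise in per-pair counts is irreducible);
the cross-validated best configuration sits close to that ceiling.

All arithmetic is float64. Random streams use numpy Generators seeded
explicitly; per-epoch negative sampling derives its stream from
(seed, epoch), and cross-validation offsets the model seed per fold. Pairs
are stored sorted so (i, j) and (j, i) are one key; exports sort rows so
seeded runs are byte-identical. Isolated nodes aggregate a zero vector.
`.npz` is used for graph and model bundles with a JSON header embedding
config and training log.

## Known limitations

* The trainer is CPU-only, full-batch numpy; it is sized for corpora of
  hundreds of herbs, not tens of thousands.
* Negative pairs are assumed to have true strength 0; in a sparsely sampled
  corpus a never-co-occurring pair may simply be unobserved.
* Edge-level CV still shares herb embeddings between train and test pairs;
  generalization to entirely unseen *herbs* is not evaluated (the design
  question is pair-level prediction within a fixed vocabulary).
* The HCPI screening threshold (0.5) and frequency cut (10 uses) are
  conventions of the analysis, not fitted quantities.
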