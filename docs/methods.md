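# Methods

## The model

`molcanvas` implements a blank-filling (canvas-rewriting) language model
for molecular strings.  A *canvas* is a sequence of filled tokens and
numbered blanks (`$k`), framed by `FIRST`/`LAST` sentinels.  Generation
starts from a canvas holding a single blank and repeatedly applies one of
four rewriting actions to a blank until none remain:

| action | effect |
|---|---|
| `E`    | replace the blank with token E |
| `_E`   | replace with E and open a new blank on its left |
| `E_`   | replace with E and open a new blank on its right |
| `_E_`  | replace with E and open blanks on both sides |

The action distribution on a canvas factorizes in three stages computed
from one pass of a bidirectional transformer encoder: a *location* head
(linear + softmax over the representations of the current blanks), a
*token* head (linear + softmax over the non-special vocabulary), and a
*creation* head (a two-layer perceptron on the concatenation of the
selected blank's representation and the chosen token's embedding, softmax
over the four left/right combinations).  The joint distribution over all
applicable actions therefore sums to one; the test suite asserts this to
1e-6 on random canvases.

## Training objective

For a training sequence `x` of length `n`, a prefix length `t` drawn
uniformly from `{0, ..., n-1}` and a fill order `sigma` drawn uniformly
from the n-permutations, the canvas `c_t` keeps the first `t` positions of
the order (each maximal run of missing positions collapses to one blank)
and the loss estimator is

    L(x, sigma, t) = -log(n!) - n/(n-t) * sum_{j=t+1..n} log p(a_j | c_t; theta)

where `a_j` is the action that fills position `sigma_j`: its blank is the
one covering the position, and it opens a left (right) blank exactly when
another missing position lies before (after) it inside the same run.  All
`n - t` targets are evaluated against the same canvas `c_t`, so one
encoder pass serves the whole example.  The `-log(n!)` term is free of
`theta`; it is included in reported values but contributes no gradient.
Minimizing this estimator maximizes a lower bound on the marginal
log-likelihood of `x` under all generation orders; an independent
brute-force enumeration of the same quantity (exhaustive over sequences of
length <= 3, all orders and prefixes) agrees with the implementation to
1e-8 in the tests.

Optimization is Adam on minibatches, each example carrying its own
`(sigma, t)` draw; `n_orders` (default 1) controls how many Monte-Carlo
draws per example enter a step — raising it reduces gradient variance at
proportional cost, which matters for the small-corpus memorization runs in
the test suite.  A global gradient-norm cap (default 1.0) guards against
the occasional large `n/(n-t)` weighting, and an optional cosine schedule
decays the learning rate tenfold over the run (used in the overfitting
experiments; the default is a constant rate).  Everything is seeded:
identical config and seed give bit-identical checkpoints and samples.

## Architecture and defaults

The encoder is a pre-norm transformer: learned token and absolute position
embeddings, multi-head self-attention, GELU feed-forward blocks
(`d_ff = 2 * d_model`), and a final layer norm.  Model defaults are 6
layers, width 256, 8 heads; the desk-scale configuration used throughout
the tests and the acceptance script is 2 layers, width 128 (or 64 for the
memorization runs), 4 heads — the mechanism is scale-free and the small
models exercise every code path.  All tensor math runs in float64 through
the package's own reverse-mode autodiff module (`molcanvas.autodiff`),
whose gradients are verified against central finite differences
operation-by-operation.

Numerical choices: softmax and log-softmax subtract the row maximum;
special tokens are masked out of the token head with an additive -1e30;
padded cells are masked out of attention the same way and never receive
probability; `PAD`-masked batching pads canvases to the batch maximum.
The initial whole-sequence blank is encoded as `BLANK_0`, blanks opened by
rewriting as `BLANK`; blank display ids renumber left-to-right after every
action.  Checkpoints are single `.npz` archives (parameters, vocabulary,
config, RNG state) with a versioned header; save/load round-trips preserve
predictive distributions bit-exactly.

## Representations

Three string representations are supported, with atom-level tokenizers
that reproduce their input exactly under concatenation:

* **SMILES** — single-character tokens except two-letter halogens (`Cl`,
  `Br`) and bracket expressions (`[nH]`, `[H]`), which are single tokens.
  The canonical drug-like vocabulary has 13 atom, 3 bond (`- = #`), 6 ring
  (`1`-`6`) and 2 branch tokens plus the 7 specials
  (`PAD UNK FIRST LAST EOS BLANK BLANK_0`).  Two-digit `%nn` closures are
  rejected; `UNK` substitution is available as an opt-in lenient mode.
* **DeepSMILES** — converted syntactically: branches keep only closing
  parentheses (one per branch atom) and ring closures become a single
  digit counting atoms back along the current path (`%nn` above 9).
  Conversion errors are syntactic; semantic (valence) errors survive and
  are the adapter's verdict, which is the point of the representation
  comparison.
* **Robust strings (SELFIES-style)** — the package's own dialect of the
  derivation-grammar idea: bond-prefixed atom tokens for C/N/O/S/F/Cl/Br,
  `[Branch1/2]` and `[(=)Ring1/2]` symbols with explicit index tokens
  `[0]`-`[15]` (two index tokens encode Q = 16*hi + lo).  The decoder is a
  total function — over-valent bonds are capped (valences C4 N3 O2 S6,
  halogens 1), inapplicable symbols are skipped — so any token sequence
  containing at least one atom token decodes to a valence-legal molecule.
  Aromatic systems are encoded kekulized and re-perceived by RDKit on
  decoding.  The dialect is deliberately self-contained; its strings are
  not interchangeable with other SELFIES implementations, and sequences
  with no atom token decode to the empty string (not a molecule), which is
  why measured validity of sampled sets can in principle fall marginally
  below 100% for a barely trained model.

Pair encoding (the SmilesPE idea) is a byte-pair encoding over atom-level
tokens: merges are learned by descending pair frequency with
lexicographic tie-breaking and applied greedily in learned order;
token-text concatenation is invariant.  It applies to SMILES and
DeepSMILES, not to the robust-string dialect.

## Sampling and tinkering design

Sampling applies temperature uniformly to all three heads' logits;
`greedy` mode takes the stage-wise argmax and is the temperature-to-zero
limit of `sample` mode (asserted at 1e-3 in the tests).  Generation is
capped at `max_actions` (default 100) and by the encoder's position-table
length; capped canvases are flagged incomplete, excluded from metric sets
and counted separately.  Every result carries its full trajectory, which
replays through `apply_action` to exactly the returned string.

Tinkering design masks part of an existing molecule (`make_template`, or
the `<mask>` text form), completes only the blanks (`infill`; unmasked
tokens are provably untouched), and ranks substitutions
(`suggest_substitutions`): for the blank with the highest location
probability, the joint token x action-kind probabilities are enumerated,
sorted, and formatted as a substitution table.

## Metrics

The distribution-learning suite follows the benchmark conventions:
validity (adapter-parsed fraction, decoding SELFIES/DeepSMILES first),
unique@k over the first k valid canonical forms, novelty against a
canonicalized training set, IntDiv_p with the |G|^2 denominator including
self-pairs (Morgan fingerprints, radius 2, 1024 bits by default), SNN,
BRICS-fragment and Bemis-Murcko-scaffold cosine similarities, and a
Frechet distance over a pluggable featurizer.  The matrix square root in
the Frechet distance is computed as Tr((S_G S_R)^{1/2}) =
Tr((S_G^{1/2} S_R S_G^{1/2})^{1/2}) via eigendecomposition with negative
eigenvalues clipped at zero.  The default featurizer is a fixed vector of
ten cheap RDKit descriptors, because ChemNet weights are outside this
package's scope: Frechet values are therefore *not* comparable to
published ChemNet-based FCD numbers, and reports carry the featurizer
name.  All pairwise metrics are tested against brute-force double loops.

One property claim worth a caveat: adding an exact duplicate to a set does
*not* always lower IntDiv (duplicating an outlier adds low-similarity
cross pairs).  The tests assert the true invariants — duplicating the
whole set leaves IntDiv unchanged; mass-duplicating one member drives it
down.

## Synthetic data and what it shows

The workbench ships two corpora so nothing is downloaded: a packaged list
of ~120 drug-like molecules (restricted to C/N/O/S/F/Cl/Br chemistry,
single-digit ring closures, no charges or stereocenters; every entry
round-trips through both codecs), and a seeded random generator in the
robust-string dialect whose outputs are valid by construction.  The random
corpus emulates the *grammar* of molecular strings — token statistics,
branching, rings, size spread (an organic-leaning token mix keeps chains
from terminating on halogens) — but not the property distributions,
synthesizability or scaffold diversity of a real training set.  Passing
tests on these corpora demonstrate that the mechanism works (the model
learns string grammar, memorizes small corpora, shifts property
distributions under biased training); they say nothing about sample
quality at benchmark scale, which requires the full public corpora and is
out of scope here.

The conditional pipeline trains on the top fraction (default 50%) of a
corpus by a property (RDKit logP/tPSA/QED, or an injectable proxy such as
heavy-atom count for adapter-free runs) and succeeds when the generated
property median is strictly closer to the biased-set median than to the
whole-corpus median.  The learning-curve runner snapshots the model at
chosen epochs and evaluates each snapshot on validity, unique@k, IntDiv
and scaffold similarity.

## Problem sizes used

Desk-scale runs were chosen so the whole suite and the acceptance script
run comfortably on a single CPU: 2-layer width-128 models, corpora of
120-1,000 molecules, 1,000-sample evaluations, and a 10,000-step
memorization run (2-layer width-64) for the overfit-recovery check.  With
those sizes the overfit model regenerates 19/20 = 95% of its corpus by
greedy single-mask infilling over every position; the residual molecule
differs from a near-twin in the corpus at few enough positions that some
single-blank contexts stay ambiguous at this training budget.

## Known limitations

* The robust-string dialect covers neutral, radical-free organic
  chemistry over C/N/O/S/F/Cl/Br; charged or exotic species cannot be
  encoded (decoding never produces them).
* Greedy de novo generation from a multi-molecule model is not expected to
  reproduce a particular training molecule: ties among fill orders make
  the argmax path corpus-dependent.  Memorization claims are therefore
  tested via single-mask infilling, where the conditional is deterministic.
* `EOS` is reserved in the vocabulary but plays no role in the loss or in
  generation; termination is governed entirely by blank exhaustion and the
  action cap.
* No beam search, no constrained decoding, no property-guided decoding at
  sample time; the conditional mechanism is biased training data only.
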