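# Methods

## Problem and scope

`chemtaste` predicts the taste class of a small molecule — sweet, bitter,
sour, umami, or undefined — from its SMILES string, in the fixed label
order used throughout the package. "Undefined" absorbs tasteless and salty
compounds and anything without a clear structural taste association: salty
perception is mediated by ion properties, not molecular shape, so it is
not a structural class. Multi-taste molecules (e.g. bittersweet compounds)
are represented as duplicate rows sharing a canonical SMILES with
different labels.

The package covers the full workflow: dataset curation, classifier
training, test-time-augmentation confidence, integrated-gradients
interpretability, and an evaluation suite for imbalanced multi-class
problems.

## Curation

Raw molecule-taste CSVs pass through a fixed filter cascade:

1. **invalid** — strings that do not parse into a molecular graph;
2. **multi-fragment** — entries with two or more *uncharged* fragments
   (typically tastant + solvent). Charged fragment pairs such as Na⁺/Cl⁻
   are deliberately left for the next stage so each removal has a single
   cause;
3. **charged** — any formally charged atom, including zwitterions with
   zero net charge (missing counter ions or inconsistent protonation);
4. **overweight** — molecular weight ≥ 2000 Da ("below 2000 Da" is read
   strictly, ties removed);
5. **duplicate** — rows collapsing on the (canonical SMILES, label) pair.
   Rows that share a canonical SMILES but differ in label survive: that is
   the multi-taste convention, not duplication. The first occurrence's
   source tag wins.

The order is pinned so removal counts are attributed deterministically;
the curation report conserves `n_input = n_output + Σ removed`. An
optional corrections table (canonical SMILES → label) is applied after
standardization and before deduplication, mirroring manual label fixes.

Canonicalization is RDKit's default sanitization plus canonical SMILES
writer; the convention identifier is stored in every model archive so a
dataset records exactly which algorithm produced its canonical strings.
Stereo descriptors are preserved in strings but not otherwise interpreted.

Train/test splitting groups rows by canonical SMILES before the seeded
shuffle, so the duplicate rows of a multi-taste molecule can never
straddle the boundary; the test size is the rounded fraction of molecule
groups (default 0.15).

## Classifiers

Four backends share one surface (`train`, `predict_proba`,
`predict_label`); all produce a normalized probability vector over the
five classes, argmax ties resolving to the lowest label index.

* **gbt** — XGBoost over 1024-bit radius-2 Morgan fingerprints, optionally
  concatenated with 15 molecular descriptors. The descriptor registry
  defaults to an adjacency/topology-flavored set (connectivity indices,
  ring counts, H-bond counts, TPSA, logP …) and accepts any user list —
  the choice is configuration, not code.
* **rf** — scikit-learn random forest, 150 trees.
* **balanced_rf** — 150 trees, each fit on a bootstrap that under-samples
  every class to the minority-class count, so all classes are equally
  represented in every tree. The per-tree resampled indices are retained
  for audit.
* **token_lm** — a compact token-level neural classifier written in numpy:
  a regex SMILES tokenizer (bracket atoms, two-letter elements, aromatic
  atoms, bonds, ring digits), learned token embeddings, optional learned
  positional embeddings, a width-3 convolutional tanh layer, masked mean
  pooling, and a linear head. Training uses categorical cross-entropy,
  AdamW-style decoupled weight decay (default 0.01), batch size 16, an
  internal 10% evaluation split, and selection of the checkpoint with the
  lowest evaluation loss.

Tree backends featurize the canonical molecular graph and are therefore
invariant to the SMILES form; the token model reads the string itself and
is not — the property that training-time augmentation and the consensus
confidence metric exploit.

Design notes on the token model:

* Explicit numpy backprop was chosen so the model exposes exact analytic
  gradients with respect to its input embeddings, which integrated
  gradients requires; gradients are verified against finite differences in
  the test suite.
* The smooth tanh nonlinearity keeps the attribution path integral
  well-behaved under Riemann discretization; piecewise-linear activations
  put kinks on the integration path and make convergence diagnostics
  noisy.
* The width-3 convolution matters for interpretability: with a purely
  per-token model, bigram evidence such as the carbonyl `=O` accrues to
  the non-atom `=` token; the convolution lets the atoms carrying a
  functional group collect its attribution.
* Positional embeddings are **off by default**. For small-molecule strings
  they add little accuracy but let the model key on string positions,
  which both dilutes atom attributions and is unnecessary for the default
  workflow. They can be enabled (`use_positional=True`) when a
  form-sensitive model is wanted, e.g. to study augmentation robustness.
* The default learning rate of 1e-5 in `TrainConfig` is a fine-tuning
  rate appropriate to a large pre-trained checkpoint; the small
  from-scratch model used in tests trains with 1e-2. Epoch defaults follow
  the fine-tuning recipe: 20 unaugmented, 2 with 10-fold augmentation.

**Augmentation.** `train_augmented` expands every training molecule to k
synonymous SMILES (randomized graph traversals that canonicalize back to
the source) with the label copied. The expansion factor is uniform across
classes by construction: augmenting classes unevenly is a known failure
mode that collapses predictions onto the majority class, so it is not
supported.

## Consensus confidence

`consensus_predict` draws k (default 10) synonymous SMILES, predicts each,
and accepts the modal label only when its multiplicity reaches the
threshold (default: strict unanimity, threshold = k); otherwise the model
abstains. A tie for the modal label abstains even at threshold — the
conservative reading. Note one edge this creates: "accepted iff agreement
≥ threshold" holds except on exact modal ties. All k variants are sampled
independently; the canonical string is not forced into the ensemble.
Support is the fraction of molecules receiving a non-abstained prediction.
Voting is on argmax labels, not averaged probabilities, matching the
ensemble-agreement definition; probability averaging is easy to add as a
policy but is not the default.

## Integrated gradients

For a scorer F, input x and baseline x′, the attribution of feature i is
(x_i − x′_i) · ∫₀¹ ∂F/∂x_i (x′ + α(x − x′)) dα, discretized with the
midpoint Riemann rule (default 64 steps). The implementation is generic
over (value, gradient) callables and is validated against closed forms:
linear scorers give w_i·x_i exactly at any step count, and the quadratic
analytic integral is matched to machine precision. The completeness gap
|Σ attributions − (F(x) − F(x′))| is exposed as a numerical diagnostic; on
trained token models it decays ~4× per doubling of steps (the O(1/n²)
midpoint-rule rate) once past the coarsest grids, where signed-error
cancellation can make a 2-point estimate accidentally small.

For molecules, the attribution input is the token-embedding sequence with
a zero baseline, while positional embeddings (when enabled) are held fixed
along the path — attribution mass then reflects what a token *is*, not
where it sits. The target is the class **logit** (not the softmax
probability; a flag is not currently exposed, and the logit choice makes
attributions independent of the other classes' scores). A token's
attribution is the sum over its embedding dimensions; token scores map
onto atoms through the tokenizer's left-to-right atom numbering, which
matches RDKit's parse order for the same string. Mass on non-atom tokens
(bonds, digits, parentheses) is reported as `residual_nonatom`, so the
decomposition atom scores + residual = total attribution is exact. Bracket
atoms attribute wholly to their single heavy atom.

Tree backends have no gradient path; requesting atom attribution raises an
explicit unsupported-backend error. A permutation-importance fallback over
fingerprint bits is provided but is global and feature-level — clearly not
equivalent to per-atom integrated gradients.

## Evaluation

Per-class precision, recall and F1 come from the 5×5 confusion matrix;
0/0 ratios score 0 and are flagged, which matters for rare classes such as
umami. The macro average is the unweighted mean over the five classes
(emphasizing minorities); the weighted average weights by class instance
counts. One-vs-rest AUROC uses the Mann–Whitney rank statistic with
midranks for ties; classes lacking both a positive and a negative are
skipped and flagged rather than fatal.

Under consensus confidence, accuracy and per-class metrics are computed on
the accepted subset only and support is reported alongside — the
separate-support convention. AUROC is always computed from the
canonical-form probability vectors of all molecules, since abstention is a
label-level, not score-level, notion.

Binary reduction collapses all non-positive classes to one negative class
per taste; any correct 5-class prediction stays correct after collapsing,
so binary accuracy dominates multi-class accuracy — fuzz-tested, not
assumed. The multi-label analysis takes every class with probability
strictly above 0.2 (1/C for five classes) as predicted, and categorizes
each multi-taste molecule as exact (predicted set equals the true set),
too-many (strict superset), or collapsed (single predicted label, counted
correct when it belongs to the true set); anything else is tallied as
"other".

## Synthetic data

Real taste datasets associate structure with taste noisily; testing needs
the opposite — an exactly known structure→label mapping. The generator
assembles molecules from a scaffold-plus-decoration grammar whose
functional groups follow food-chemistry heuristics: carboxylic acids →
sour (acidic protons in the sour-tasting pKa range), amides → umami (the
signature of savory peptides), vicinal polyols → sweet (sugar-like
hydroxyl patterns), aromatic/fused-ring systems → bitter (polyphenol-like
scaffolds), plain alkanes → undefined. Labels are assigned by re-applying
the ordered SMARTS rule set (first match wins; acid outranks aromatic so
benzoic acid is sour), so at zero noise the mapping is a deterministic
function of the graph. Optional label noise flips each label to a random
other class; `flip_labels` applies the same corruption to a training split
only, modeling the common situation of noisy training annotations with
clean evaluation targets.

The default class mix (0.60, 0.20, 0.10, 0.05, 0.05 in label order) is
sweet-dominated with umami rare, the imbalance typical of aggregated taste
databases. What the generator does **not** emulate: the chemical-space
breadth of real tastant collections, realistic molecular weights beyond
the small-molecule range, stereochemistry, and correlated (non-uniform)
label noise. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted rules, not field performance on
real data.

The curation-fixture generator plants file defects in exact counts —
unparsable strings, neutral-fragment solvent pairs, single-fragment
charged species, ≥2000 Da alkane chains, and non-canonical duplicate
rewrites detectable only after canonicalization — each caught by exactly
one cascade stage, so curation reports can be audited end to end.

## Study sizes and numerical choices

The standard study conditions used by the tests and the acceptance script:
2000 zero-noise molecules with a 15% grouped held-out split for rule
recovery (gradient boosting and the token model), 30 held-out acids for
planted-rule attribution, 15% training-label noise with a 6-epoch
positional token model for the consensus study, 500 molecules × 10
variants for augmentation soundness, and 64 integration steps for
attribution. Probability vectors must sum to 1 within 1e-9; metric
identities are checked against counting oracles at 1e-12; seeds are
threaded through every random source so all results are exactly
reproducible.

## Known limitations

* The token model is a compact from-scratch network, not a pre-trained
  chemical language model; its accuracy on real heterogeneous data would
  be far below what transfer learning achieves. The training loop,
  however, accepts the same protocol (cross-entropy, weight decay,
  best-checkpoint selection) at any scale.
* The charge filter excludes all zwitterions; datasets where zwitterionic
  tastants matter (amino acids as drawn) need upstream neutralization.
* Consensus confidence is a voting heuristic, not a calibrated probability
  (no conformal guarantees).
* Attribution is reported per atom; multi-atom functional-group semantics
  are left to the reader or to the SMARTS matching used in the tests.
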