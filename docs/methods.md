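# Methods

## Model

`ddiscreen` treats DDI-type prediction as multi-label classification over
ordered drug pairs.  The core assumption is pharmacological similarity:
drugs with similar substructure content tend to share interaction behavior,
so a drug is represented not by its raw fingerprint but by its *structural
similarity profile* (SSP) — the vector of Tanimoto similarities to every
drug in a fixed reference set.  This makes the feature space dense,
bounded, and anchored to the training corpus: a query is described by
"which known drugs it resembles and how much".

Stages:

1. **Fingerprinting** (`chem_io`).  Binary Morgan/ECFP-style circular
   fingerprints, radius 2, 2048 bits.  SMILES are canonicalized with RDKit
   before hashing, so any atom ordering of the same molecule yields
   identical bits.  Salts and stereochemistry are kept as given — there is
   deliberately no standardization pipeline, so what you load is what is
   fingerprinted.
2. **SSP + reduction** (`similarity`).  Tanimoto T(a,b) = |a∧b|/|a∨b|; the
   similarity of two all-zero fingerprints is defined as 0 rather than NaN.
   Profiles are reduced by PCA.  Component signs are fixed (largest-
   magnitude coordinate positive) so fitted reducers are bit-stable across
   runs; serialization uses flat `.npy` arrays plus a JSON manifest for the
   same reason.
3. **Classifier** (`nn`, `ddi_model`).  Pair feature = concatenated reduced
   profiles of the two drugs (length 2k).  A feed-forward network with
   rectified hidden layers and 113 independent sigmoid outputs is trained
   with per-type weighted binary cross-entropy (positive weight =
   negatives/positives, capped at 100), Adam, mini-batches, and early
   stopping on a seeded 10% validation split.  Multi-label outputs were
   chosen over a softmax because observed pairs carry up to three
   co-occurring types, which a single-class model cannot express.
4. **Post-processing** (`ddi_model.process_predictions`).  Both pair orders
   are scored.  Directional types (the serum-concentration and metabolism
   families, ids 3, 6, 20, 33, 89 in the bundled catalogue) keep their
   order: each order passing the threshold yields its own record and
   sentence.  Non-directional (mutual-activity) types take the maximum over
   the two orders and are emitted once.  Calls are records with score ≥ the
   stored threshold, sorted by descending score with deterministic
   tie-breaks.
5. **Screening and summaries** (`screen`).  A DDI is counted
   as a distinct (panel drug, query, type) triple.  This is the only
   convention under which the three summary views — per-drug type counts,
   per-type drug counts, and the total DDI count — satisfy the
   double-counting identity Σ_d counts(d,q) = Σ_t counts(t,q), which the
   test suite asserts.  Reference-list overlap uses exact case-insensitive
   name matching after whitespace normalization; unmatched names are
   reported rather than fuzzily matched, trading recall for zero silent
   false matches.
6. **Alternatives**.  A candidate replaces a flagged drug iff it has zero
   predicted DDIs against every query and shares ≥1 normalized
   mechanism-of-action string.  Multi-valued MoA cells split on `|` and
   `;`.  No ontology mapping is attempted — synonymous mechanism phrasings
   will not match, a documented limitation.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| fingerprint radius | 2 | ECFP4-equivalent neighborhood, the de-facto standard for similarity work |
| n_bits | 2048 | low collision rate for drug-sized molecules |
| reduction k | 100 | see below |
| hidden layers | 256 × 256 | desk-scale capacity; config-driven, not a tuned optimum |
| threshold | 0.5 | stored in the model bundle so calls are reproducible |
| pos_weight cap | 100 | bounds the gradient contribution of ultra-rare types |
| val fraction / patience | 0.1 / 15 epochs | early-stopping guard; split seed recorded |

**Choice of k.**  With a reference of a few hundred drugs, reducing
profiles to 50 components measurably truncates the signal needed for
*compound* interaction rules (those conditioned on motifs in both drugs):
in the recovery benchmark the compound-rule F1 sits ≈0.04 below the
label-noise ceiling at k = 50 and ≈0.02 at k = 100, consistently across
seeds, while single-motif rules are at ceiling for both.  The default is
therefore k = 100; it is clamped to min(n−1, m) for small references and
fully configurable.

## Synthetic data: what it emulates and what it does not

`synthetic` stands in for a licensed gold-standard DDI corpus.  Molecules
are assembled from a small grammar — alkyl chains, methyl branches,
cyclohexyl and phenyl scaffolds, ether linkers — decorated independently
with three planted motifs (tertiary amine, carboxylic acid, chlorine).
Labels are planted by substructure rules (SMARTS match in one or both
drugs of a pair), then flipped independently at a configurable noise rate.
The motifs span multi-atom environments distinguishable at radius ≤ 2, so
the rules are learnable from SSP features *by construction*; the point of
the benchmark is that the pipeline recovers them, not that the task is
hard.

Presets are fixed study conditions, not dials: `tiny` (40 drugs, 200
pairs, 2 noise-free rules) for fast tests; `default` (200 drugs, 2000
pairs, 3 rules, 5% label noise) for the recovery benchmark; `screen` (2
queries, 50-drug panel, 120-drug training universe, noise-free
partner-conditioned rules) for end-to-end screening with exact brute-force
expected counts.  With 5% label flips the Bayes-optimal macro-F1 on the
default preset is itself ≈0.92–0.95 depending on the noise realization;
the acceptance bound of 0.90 asks the model to be near that ceiling.

What passing these benchmarks does **not** show: real DDI labels are not
generated by local substructure rules; real drugs are larger, more
diverse, and their interaction biology (transporters, PD interactions)
is only partially visible in 2-D structure.  Synthetic recovery validates
the machinery — featurization, optimization, thresholding, counting — not
clinical predictive accuracy.

Two generator caveats.  Deduplication against canonical SMILES slightly
enriches ring-bearing molecules (plain alkanes from different grammar
paths collapse to the same structure), so per-motif carrier rates are
binomial for the amine/carboxyl/chloro motifs but run a few percent high
for phenyl.  And the screen preset's training pairs are drawn from the
same drug universe that is later screened (though the specific
query×panel pairs need not occur in training), mirroring screening
against a model whose corpus contains the marketed drugs.

## Numerical and degenerate-input choices

- PCA via SVD of the centered matrix; explained variances equal the
  covariance eigenvalues (asserted to 1e-6 against a dense eigensolver).
  Zero-variance input returns a valid reducer with zero variances and a
  warning rather than failing.
- Gold-standard labels are treated as order-invariant for *learning*
  (each pair is presented in both orders with the same label set);
  directionality is applied at post-processing, where the order that
  passes threshold determines the sentence.  The alternative — dropping
  directional labels from the swapped copy — would inject systematic
  false negatives whenever both orders truly interact.
- Explicit negatives (pairs with no interaction) travel separately from
  labelled pairs and contribute all-zero label rows; class balance is
  therefore controllable rather than implied.
- Determinism: every stochastic step (generation, pair sampling, splits,
  initialization, shuffling) derives from explicit integer seeds; repeated
  runs produce byte-identical weight files and screen tables, which the
  suite asserts.
- Training refuses unresolvable drug ids and unknown type ids; single-type
  gold standards train with a warning; prediction refuses a reference set
  whose content digest differs from the model's.

## Known limitations

- The bundled catalogue anchors 14 established keywords; the other 99
  entries are marked provisional with placeholder templates and default to
  non-directional.  Dropping in a complete catalogue CSV replaces them
  without code changes.
- No tautomer/charge standardization, no 3-D information, no GPU path.
- The classifier is a compact numpy network intended for desk-scale
  corpora (10³–10⁴ pairs); it is not a route to training on 10⁶-pair
  corpora.
- Alternatives ranking is unscored: candidates are filtered, not ordered
  by predicted safety margin.
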