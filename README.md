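# ddiscreen

Structure-based prediction of drug–drug interaction (DDI) types, and
screening of query drugs against prescription-drug panels.

Co-administered drugs can change each other's pharmacology — a CYP3A
inhibitor slows a partner drug's metabolism, two QT-prolonging drugs
compound an arrhythmia risk.  `ddiscreen` predicts, from chemical structure
alone, which of 113 catalogued DDI types an ordered drug pair is likely to
exhibit, renders each call as a human-readable sentence, and supports the
downstream screening workflow: flagging every panel drug that interacts
with a set of query compounds (e.g. a protease inhibitor co-packaged with a
CYP3A inhibitor), summarizing the calls, comparing them with externally
published interaction lists, and proposing alternative drugs that share a
mechanism of action but carry no predicted interaction.

It is aimed at computational chemists and drug-safety researchers who want
a fully inspectable, seedable desk-scale pipeline of this design — not a
clinical decision tool.

## Method

For a drug *d* with Morgan (ECFP-style) fingerprint **f**(d) (radius 2,
2048 bits), the raw feature is its **structural similarity profile** (SSP)
against a fixed, ordered reference set R = (r₁ … r_m):

    SSP(d)ᵢ = T(f(d), f(rᵢ)),   T(a, b) = |a ∧ b| / |a ∨ b|   (Tanimoto)

Profiles are mean-centered and projected onto the top-k principal
components (default k = 100).  An ordered pair (A, B) is featurized as the
concatenation reduce(SSP(A)) ⊕ reduce(SSP(B)) and passed to a feed-forward
network (two rectified hidden layers of 256 units) with 113 independent
sigmoid outputs — a multi-label classifier, since one pair can exhibit
several DDI types at once.  Training minimizes per-type weighted binary
cross-entropy on gold-standard pairs (each pair also presented in swapped
order), with early stopping on a seeded validation split.  Scores from both
pair orders are post-processed into calls: thresholded at 0.5, with
directional types (serum-concentration and metabolism changes) keeping
their order and each order rendering its own sentence, and non-directional
types (mutual-activity changes) taking the maximum over orders and emitted
once.

Licensed DDI corpora cannot be redistributed, so the package ships a
synthetic-data module that generates valid small molecules from a SMILES
grammar and plants interaction labels via substructure rules (e.g.
"tertiary amine × phenyl carrier → type 89") that are detectable by
radius-2 fingerprints — making recovery of the planted rules a measurable
end-to-end correctness check with exact brute-force expected answers.

## Worked example

`examples/` contains one narrative script per capability.
`python examples/02_train_and_predict.py` trains on a 40-drug planted-rule
dataset and scores a pair:

```
dataset: 40 drugs, 175 labelled pairs, 25 explicit negatives, rules for types [3, 89]
trained: features 2k=78, hidden (256, 256), 113 output types

pair: synthomycin-001 (CCCC1CCCCC1OCN(C)CC(=O)O)  x  synthomycin-010 (CC(Cl)CC1CCCCC1c1ccccc1)
  type   3  score 0.983  synthomycin-010 may cause the increased serum concentration of synthomycin-001.
  type  89  score 0.972  synthomycin-010 may cause the decreased metabolism of synthomycin-001.
  type   3  score 0.970  synthomycin-001 may cause the increased serum concentration of synthomycin-010.
  type  89  score 0.930  synthomycin-001 may cause the decreased metabolism of synthomycin-010.
```

The first drug carries both planted motifs (a tertiary amine and a
carboxylic acid), so both planted rules fire; scores are per-type
probabilities and every call is at or above the 0.5 threshold.  Because
types 3 and 89 are directional, each pair order yields its own sentence.

`python examples/03_screen_panel.py` screens two query drugs against a
50-drug panel and prints the summary counts (35 of 50 panel drugs flagged,
61 distinct predicted DDIs, all counts matching the generator's brute-force
rule evaluation); `examples/04_alternatives.py` then proposes
interaction-free, same-mechanism alternatives for the flagged drugs.

The same workflow is scriptable from a shell:

```bash
ddiscreen synth  --preset screen --seed 1 --out fx/
ddiscreen train  --drugs fx/drugs.csv --gold fx/gold_standard.csv \
                 --negatives fx/negatives.csv --seed 11 --out model/
ddiscreen screen --model model/ --queries fx/queries.csv --panel fx/panel.csv \
                 --out screen.tsv
ddiscreen report --screen screen.tsv --panel fx/panel.csv \
                 --ref-list fda_like fx/fda_like.txt --out report/
ddiscreen alternatives --screen screen.tsv --panel fx/panel.csv \
                 --moa fx/moa.csv --out alternatives.tsv
```

## Limitations

Predictions are structural analogies, not clinical evidence.  The bundled
113-type catalogue anchors 14 well-established keywords; the remaining
templates are provisional placeholders that a complete catalogue table can
replace.  See `docs/methods.md` for the model's assumptions and what the
synthetic benchmarks do and do not demonstrate.
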