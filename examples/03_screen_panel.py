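"""Screen two query drugs against a 50-drug panel and summarize.

Uses the screening fixture: a protease-inhibitor-like and a CYP-inhibitor-
like query, a synthetic prescription panel, and planted interaction rules.
After training, every (query, panel drug) pair is scored in both orders,
thresholded, and counted as distinct (drug, query, type) triples.  The
printed counts are checked against the generator's own brute-force rule
evaluation, and the overlap with a reference drug list is reported as the
percentage of that list predicted to interact.
"""

from ddiscreen import TrainConfig, train
from ddiscreen.screen import compare_reference_lists, screen_panel, summarize
from ddiscreen.synthetic import make_screen_fixture

fx = make_screen_fixture(seed=1)
model = train(fx.train_pairs, fx.train_drugs, config=TrainConfig(seed=11),
              negatives=fx.train_negatives)
result = screen_panel(model, fx.queries, fx.panel)
summary = summarize(result)

print(f"panel size: {summary.panel_size}")
for q in sorted(summary.interacting_by_query):
    print(f"  drugs predicted to interact with {q}: {len(summary.interacting_by_query[q])}")
print(f"  union of interacting drugs: {len(summary.interacting_union)}")
print(f"  total predicted DDIs (distinct drug/query/type triples): {summary.total_ddis}")
print(f"  max DDI types for any (drug, query) pair: {summary.max_types_per_pair}")
print(f"  matches brute-force rule evaluation: "
      f"{summary.per_drug_type_counts == fx.expected['per_drug_type_counts']}")

name_map = {d.name: d.drug_id for d in fx.panel}
rep = compare_reference_lists(summary, fx.ref_lists["fda_like"], name_map)
print(f"\nreference list: {rep.n_predicted_interacting}/{rep.n_ref} "
      f"({rep.fraction}%) predicted to interact with at least one query")
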