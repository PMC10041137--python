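"""Propose alternative drugs for interaction-flagged panel members.

For every panel drug flagged in the screen, finds panel drugs that
(1) have no predicted DDI with either query and (2) share a mechanism of
action.  Flagged drugs without a MoA annotation are reported separately.
"""

from ddiscreen import TrainConfig, train
from ddiscreen.alternatives import MoAAnnotation, find_alternatives
from ddiscreen.screen import screen_panel, summarize
from ddiscreen.synthetic import make_screen_fixture

fx = make_screen_fixture(seed=1)
model = train(fx.train_pairs, fx.train_drugs, config=TrainConfig(seed=11),
              negatives=fx.train_negatives)
summary = summarize(screen_panel(model, fx.queries, fx.panel))
moa = [MoAAnnotation(name, m) for name, m in fx.moa_table]

report = find_alternatives(summary, fx.panel, moa)
with_alts = [s for s in report.suggestions if s.n_alternatives]
print(f"flagged drugs: {len(summary.interacting_union)}; "
      f"{len(with_alts)} have at least one safe same-MoA alternative; "
      f"{len(report.unannotated)} lack a MoA annotation")
for s in with_alts[:5]:
    print(f"  {s.flagged_drug} ({s.moa}): {', '.join(s.alternatives)}")

union_names = {d.name for d in fx.panel if d.drug_id in summary.interacting_union}
assert not any(set(s.alternatives) & union_names for s in report.suggestions)
print("soundness holds: no suggested alternative is itself flagged")
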