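"""Seed a clean dataset with synthetic PHI and derive the answer key.

Shows a header before and after injection, and the answer-key rows that a
de-identifier will later be scored against — including a mixed value where a
synthetic name is embedded in clinically useful text that must survive.
"""

from deidbench import answer_key as ak
from deidbench import injector as inj
from deidbench import phantom_factory as pf
from deidbench.tags import parse_tag

row = pf.ManifestRow("CR", 1, 1, 1, 2, (("CHEST", 1),), (("FUJIFILM", 1),))
clean, _ = pf.build_dataset(pf.CompositionManifest(rows=(row,)), seed=4, matrix=128)

plan, records = inj.build_default_plan(clean, seed=4)
evaluation, provenance = inj.run_plan(clean, plan)
key = ak.derive_answer_key(provenance, dataset=evaluation)

name = parse_tag("(0010,0010)")
desc = parse_tag("(0008,1030)")
print("before:", clean.instances[0].get_value(name), "|", clean.instances[0].get_value(desc))
print("after: ", evaluation.instances[0].get_value(name), "|",
      evaluation.instances[0].get_value(desc))

print(f"\n{len(plan)} directives -> {len(key)} answer-key entries; sample rows:")
for entry in key:
    if entry.tag in (name, desc):
        print(f"  {entry.scope:8s} {entry.tag} {entry.action:13s} {list(entry.action_text)}")
# text_removed rows list the synthetic PHI that must vanish; the
# text_retained row is the clinical phrase that must survive verbatim.
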