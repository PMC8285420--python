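"""Score de-identification attempts against the answer key.

Runs the reference (oracle) de-identifier — which must score 100% with zero
leaks — and an identity copy, which must fail every removal/shift/remap/
masking check while passing every retention check.  Any third-party
de-identifier can be scored the same way once its output and crosswalks are
loaded.
"""

from deidbench import answer_key as ak
from deidbench import evaluator as ev
from deidbench import injector as inj
from deidbench import phantom_factory as pf

rows = (
    pf.ManifestRow("CT", 1, 1, 1, 4, (("CHEST", 1),), (("GE MEDICAL SYSTEMS", 1),)),
    pf.ManifestRow("DX", 1, 1, 1, 2, (("CHEST", 1),), (("PHILIPS", 1),)),
)
clean, _ = pf.build_dataset(pf.CompositionManifest(rows=rows), seed=8, matrix=128)
plan, records = inj.build_default_plan(clean, seed=8)
evaluation, provenance = inj.run_plan(clean, plan)
key = ak.derive_answer_key(provenance, dataset=evaluation)

oracle, xwalk = ev.build_oracle_deid(evaluation, key, seed=8)
report = ev.evaluate(oracle, key, xwalk)
print("oracle:   overall_pass =", report.overall_pass, "| leaks =", len(report.leaks))

identity_xwalk = ak.Crosswalk(
    patient_map={r.patient_id: r.patient_id for r in records.values()},
    uid_map={u: u for u in xwalk.uid_map},
)
report = ev.evaluate(evaluation, key, identity_xwalk)
print("identity: overall_pass =", report.overall_pass)
for action, counts in sorted(report.per_action_counts.items()):
    print(f"  {action:13s} pass={counts['pass']:3d} fail={counts['fail']:3d}")
# The identity copy fails exactly the four PHI action classes; retention
# checks pass because nothing was (over-)deleted.
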