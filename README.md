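# deidbench

A benchmark toolkit for **medical image de-identification**. It manufactures
DICOM datasets seeded with synthetic protected health information (PHI) — in
standard header attributes, vendor private attributes, and burned into the
pixel data — emits a machine-readable **answer key** and patient-ID/UID
**crosswalks**, and scores any de-identification algorithm's output against
that key.

## Who it is for

Open imaging archives must remove PHI (names, dates, identifiers, burned-in
annotations) before publishing DICOM data, while *retaining* the research-
critical attributes a downstream scientist needs. Evaluating an automated
de-identifier therefore needs ground truth: a dataset where the exact
location and content of every planted identifier is known. Real clinical
data cannot provide that. This toolkit builds such ground truth
synthetically, end to end:

```
manifest ──► phantom_factory ──► clean dataset (no PHI)
                                      │
      phi_forge (seeded identities) ──┤
                                      ▼
                 injector ──► evaluation dataset + provenance
                                      │
             answer_key ──► key (CSV) + crosswalks
                                      │
   your de-identifier (or the built-in oracle)
                                      ▼
                 evaluator ──► per-check report + leakage scan
```

## The scoring model

Every answer-key entry is a check `(scope, tag, action, action text)` at
Patient / Study / Series / Instance scope. The seven actions:

| action | a de-identified dataset passes iff |
|---|---|
| `tag_retained` | the tag is still present |
| `text_notnull` | the value is non-empty |
| `text_retained` | each listed phrase survives **verbatim** (case-sensitive) |
| `text_removed` | no listed phrase remains (case-insensitive; absence passes) |
| `date_shifted` | the date moved by one consistent **nonzero** per-patient offset (or a configured offset) |
| `uid_changed` | the UID is valid, differs from the original, and matches the crosswalk |
| `pixels_hidden` | the burn-in rectangle is perfectly uniform |

A global, case-insensitive leakage scan over every text element (plus the
key's burn-in rectangles) catches PHI that a buggy de-identifier copied
somewhere the key does not point to. Injection uses six operations —
`set_tag`, `delete_tag`, `shift_date`, `substitute`, `string_replace`,
`annotate_img` — and mixed payloads such as
`"Billy Rogers XR CHEST AP PORTABLE"` deliberately interleave PHI with
clinical text that must survive, because deleting attributes indiscriminately
destroys research value.

The bundled composition manifest expands to the benchmark's reference
collection: **1,693 images, 21 patients, 22 studies, 26 series** across CT
(268), MR (150), PT (1,203), DX (10), CR (4) and MG (58).

## Worked example

```python
from deidbench import phantom_factory as pf, injector as inj
from deidbench import answer_key as ak, evaluator as ev

row = pf.ManifestRow("CR", 1, 1, 1, 2, (("CHEST", 1),), (("FUJIFILM", 1),))
clean, _ = pf.build_dataset(pf.CompositionManifest(rows=(row,)), seed=4, matrix=128)
plan, records = inj.build_default_plan(clean, seed=4)
evaluation, provenance = inj.run_plan(clean, plan)
key = ak.derive_answer_key(provenance, dataset=evaluation)
oracle, xwalk = ev.build_oracle_deid(evaluation, key, seed=4)
print(ev.evaluate(oracle, key, xwalk).overall_pass)
```

Running `python examples/02_inject_synthetic_phi.py` prints:

```
before: PHANTOM^001 | XR CHEST AP PORTABLE
after:  WARD^STEVEN | Steven Ward XR CHEST AP PORTABLE

28 directives -> 75 answer-key entries; sample rows:
  Patient  (0010,0010) text_removed  ['WARD^STEVEN']
  Study    (0008,1030) text_removed  ['Steven Ward']
  Study    (0008,1030) text_retained ['XR CHEST AP PORTABLE']
  Series   (0010,0010) tag_retained  []
```

The clean phantom carries neutral placeholders; after injection the patient
has a synthetic identity, and the Study Description is a mixed value: the
key demands that `Steven Ward` vanish while `XR CHEST AP PORTABLE` survives.
`examples/03_score_deidentification.py` then shows the two calibration
points of the scorer — the reference de-identifier passes every check with
zero leaks, while an unmodified copy fails exactly the
`text_removed` / `date_shifted` / `uid_changed` / `pixels_hidden` checks and
passes every retention check.

## Command line

```bash
deidbench generate --out clean/ --seed 1                  # full 1,693-image build
deidbench inject   --input clean/ --out eval/ --key key.csv --seed 1
deidbench oracle-deid --input eval/ --key key.csv --out deid/ \
    --patient-xwalk p.csv --uid-xwalk u.csv --seed 1
deidbench evaluate --input deid/ --key key.csv \
    --patient-xwalk p.csv --uid-xwalk u.csv --report report.json
```

`evaluate` exits 0 on an overall pass, 1 on failure, 2 on usage errors, so it
can gate CI of a third-party de-identifier. To score your own tool, point
`evaluate` at its output directory plus the crosswalks it produced.

## Layout

- `src/deidbench/` — library (`tags`, `dicom_core`, `phi_forge`,
  `phantom_factory`, `injector`, `answer_key`, `evaluator`, `cli`)
- `src/deidbench/data/` — modality attribute-type profiles, private-attribute
  dictionary, payload template catalogue, benchmark manifest
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameters, design choices, limitations
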