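# Methods

## Overview

deidbench evaluates DICOM de-identification the way a curation team would:
plant known identifiers everywhere identifiers are known to hide, write down
exactly what was planted and where, then check a candidate output against
that record. Three properties drive every design choice below:

1. **Self-containment.** No clinical data, no downloads. The image content
   is synthetic; only the *header* behavior needs to be realistic, because
   headers (and burned-in text) are what de-identifiers operate on.
2. **Determinism.** Every artifact is a pure function of a single integer
   seed, so a benchmark run is exactly reproducible and diffable.
3. **Closed-loop validation.** The toolkit carries its own reference
   de-identifier that performs exactly what the answer key demands. Its
   output must score 100% with zero leaks, and an unmodified copy must fail
   every PHI check — the scorer is calibrated against both endpoints before
   it is trusted on third-party output.

## DICOM data model

Files are Part-10, Explicit VR Little Endian, uncompressed, single-frame,
ASCII-only. Fixing one transfer syntax maximizes interoperability of the
benchmark and keeps candidate scoring unambiguous; compressed input is
rejected with an explicit error rather than decoded. Serialization is
delegated to pydicom with a pinned implementation UID and deterministic file
meta, so equal instances yield identical bytes and elements are emitted in
ascending tag order. Elements with VRs outside the supported text/date/UID
set are carried as opaque bytes and round-trip unchanged.

Private attributes are addressed as `(group, "CREATOR", byte)`. Resolution
scans the creator reservations `(gggg,0010)…(gggg,00ff)` for the matching
label and returns the element at `(block << 8) | byte`; an unreserved
creator resolves to "absent", never an error. Writing auto-reserves the next
free block. A small private dictionary (CSV) records, for each catalogued
private attribute, the curation process-operation description — kept,
hashed, offset, deleted, or emptied — as metadata for plan authors.

## Attribute-type profiles

`data/modality_profiles.csv` assigns each attribute a DICOM requirement
level (Type 1 required-with-value, 1C/2C conditional, 2 required-may-be-
empty, 3 optional) per modality, with `All` rows overridden by
modality-specific rows. The table contains the modality-discriminating rows
(Image Type and KVP for CT, Presentation Intent Type for DX, Positioner
Type and Organ Exposed for MG, Bits Allocated/Stored for MR, image
position/orientation for PT, Photometric Interpretation for CR) plus the
attributes any readable file needs: UIDs, Rows/Columns, pixel-encoding
attributes, Patient ID, and a handful of Type 3 attributes the injector
needs pre-populated (Station Name, Study Description, Derivation
Description). Conditional (1C/2C) attributes are listed for lookup but are
never generated and never injected — conditionality cannot be decided
without clinical context, so they are left out of both the phantom and the
PHI plan. Overlay Data is likewise excluded: overlays are optional in
practice, and a mandatory overlay row would force every phantom to carry
one.

The profile doubles as a validator: a compliant instance has every Type 1
attribute populated and every Type 2 attribute present. Generated datasets
must validate before and after injection (the injector refuses to delete
Type 1 attributes for the same reason).

## Composition manifest and hierarchy expansion

A manifest row gives per-modality patient/study/series/image counts plus
body-part and manufacturer study counts. Expansion is deterministic
largest-remainder allocation — studies round-robin over patients, series
over studies, images over series, earlier slots taking the remainder — so a
manifest always expands to the same hierarchy. Body parts and manufacturers
attach to studies in manifest order; the literal label `[BLANK]` yields an
empty Body Part Examined, and `VICTRE` (a synthetic-image collection, not a
vendor) is carried verbatim as a manufacturer string.

The bundled manifest reproduces the reference collection: 1,693 images, 22
studies, 26 series. Its per-modality patient counts sum to 22 while the
collection has 21 distinct patients, so exactly one patient must appear
under two modalities; the manifest's `shared_patients` column models this by
letting a row reuse patients from an earlier row. The fixture shares one
patient between the CR and DX rows (both image CHEST) — the published
composition does not say which patient is shared, so this is a modeling
choice, recorded here and configurable in the manifest.

Phantom pixels are a diagonal gradient (1000 + 20000·r/(R−1) +
20000·c/(C−1)) plus seeded uniform noise of amplitude 500, stored as 16-bit
grayscale. Values stay far below 65535 so burn-in glyphs (written at the
maximum value) are always distinguishable. The default matrix is 128×128 —
large enough to host multi-line burn-ins at the 5×7 font's scale 1, small
enough that the full 1,693-instance build plus scoring completes in minutes
on one CPU; the matrix is a parameter everywhere.

## Synthetic identities

Each patient identity (name, 10-digit ID, birth date, sex, address, phone,
accession numbers, two physicians, institution, study dates, plus
device/department identifiers used by private-attribute payloads) is a pure
function of `(seed, patient_index)`. Names come from a seed-shuffled
family×given product with four non-overlapping draws per patient (patient,
referring, performing, technologist), which keeps all person-name strings
pairwise distinct for cohorts up to 600. Numeric identifiers embed the
patient index (e.g. ID = 6 random digits + 4 index digits), making
cross-patient collisions structurally impossible rather than merely
improbable; accession numbers follow the date-prefixed shape
`YYYYMMDD` + letter + 6 digits.

Dates are chosen for both plausibility and scan-safety: study dates are
strided 37 days per patient (within-patient studies one day apart), so no
two patients share a date string; birth dates precede the studies by 18–90
years. Institution-derived short identifiers (issuer of Patient ID, station
names, application-entity titles) are initials-plus-digits forms that cannot
occur as substrings of any institution name — this matters because the
leakage scan is a substring scan.

Payload templates combine PHI field references with retained clinical
phrases ("mixed values"), reflecting that wholesale deletion of attributes
like Study Description destroys information a curator would keep; the
rendered value contains every PHI span and every retained span as
non-overlapping substrings, so removal can be verified by string surgery.
The default template catalogue (`data/payload_templates.json`) covers the
standard attributes and vendor private attributes where curation audit
practice has found PHI, with manufacturer-aware routing (GE, Siemens,
Fujifilm, Toshiba, Lorad/Hologic-era, PACS vendors) so private payloads land
on plausible equipment.

## Injection

Six operations: `set_tag` creates-or-overwrites; `substitute` only
overwrites existing non-empty values and records skips (the distinction
matters for attributes that may legitimately be absent); `delete_tag` is
idempotent and refuses Type 1 targets; `shift_date` offsets DA values;
`string_replace` substitutes text within a value and counts replacements;
`annotate_img` burns text into pixels. Directives carry a scope
(Collection/Patient/Study/Series/Instance) and a selector, resolved against
a snapshot of the dataset taken before the plan runs — a plan that rewrites
Patient ID can still address that patient by its original identifier.

Burn-ins use a built-in 5×7 bitmap font, integrally scaled, glyph pixels set
to the maximum pixel value and nothing else touched. Glyph-only burning
(not filled rectangles) lets the evaluator distinguish "text present" from
"region masked". Coordinates are (row, col), 0-based, rectangles half-open.
The default plan burns one annotation (name, birth date, and a series
ordinal for distinctness) into the first instance of every series, wrapped
to fit the matrix.

The default plan also shifts each study's placeholder date onto the
identity's synthetic study date via `shift_date`, so the evaluation dataset
carries real-looking dates whose required de-identification behavior
(interval-preserving offset) is recorded as `date_shifted` entries.

## Answer key

Provenance maps mechanically to key entries: each PHI span to one
`text_removed` entry, each retained span to one `text_retained` entry, date
shifts to `date_shifted` (action text = the date as it stands in the
evaluation dataset), burn-ins to `pixels_hidden` (action text = rect
coordinates `r0,c0,r1,c1` plus the burned text — the evaluator needs the
coordinates). From the dataset itself come `uid_changed` entries for every
study/series/instance UID and, per series, `tag_retained` (Types 1 and 2)
and `text_notnull` (Type 1) entries for the research-critical attributes.
`delete_tag` provenance yields no entry — nothing checkable remains.
Patient-scope selectors are translated to the evaluation dataset's Patient
IDs, since those are the identifiers a de-identifier actually sees; a
ScopeSelector column makes each key row resolvable in isolation. Keys are
CSV with JSON-encoded action-text lists; crosswalks are two CSVs
(patient old/new, UID old/new) plus an optional per-patient day-offset CSV,
with injectivity enforced on read and write.

## Evaluation

Checks are per entry with per-instance evidence. Matching is
case-insensitive for `text_removed` and the leakage scan (a leaked name in
any casing is PHI) and case-sensitive for `text_retained` (retained clinical
text must survive verbatim). `pixels_hidden` requires zero standard
deviation inside the rect — partial masking fails. `date_shifted` has two
modes: `fixed` checks a configured per-patient offset; the default `infer`
mode requires all of a patient's dated entries to exhibit one common
**nonzero** offset, which makes the scorer usable against third-party tools
that chose their own offset while still enforcing interval preservation.
Unresolvable selectors (missing crosswalk rows) are reported as a third
status distinct from failure, separating de-identification errors from
bookkeeping errors. `overall_pass` requires zero failures, zero
unresolvables among resolvable content, and zero leaks.

The leakage scan searches every text-VR element of every instance for every
key span, with two matching refinements. First, needles that begin or end in
digits/dots are bounded by a digit/dot-free context, so UID `…3.1` does not
"match" inside UID `…3.11`. Second, bare 8-digit dates are excluded from
the *global* corpus by default: a correctly shifted date of one patient can
coincidentally equal another patient's original date, which is no
disclosure; dates remain fully verified by the per-scope `date_shifted` and
`text_removed` checks, and callers can opt dates back in
(`corpus_from_key(..., include_dates=True)`), as the provenance-completeness
test does on the unshifted evaluation dataset where no such coincidence can
occur. Pixel leakage is limited to the key's burn-in rectangles — there is
deliberately no OCR.

The reference de-identifier removes spans by string surgery (preserving
retained text), draws one nonzero offset per patient uniformly from ±[30,
364] days, masks rects to zero, and freshly remaps patient IDs and UIDs
(remapped UIDs use a structurally distinct root segment so no original UID
can be a substring of a new one). Four single-fault variants — leave
burn-ins, skip private-tag removals, copy dates unshifted, reuse original
UIDs — are provided for fault-localization testing: each must fail exactly
its own action class.

## What the synthetic data does and does not show

The generator emulates the *location and shape* of PHI in clinical DICOM:
modality-correct mandatory attributes, vendor private blocks, mixed
PHI/clinical text, date structure, burned-in annotations. It does not
emulate anatomy, free-text report prose, non-ASCII character sets,
multi-frame or compressed objects, structured reports, or OCR-hard pixel
text. A de-identifier that passes this benchmark has demonstrated correct
mechanics — finding and editing the right attributes, preserving the right
text, shifting dates consistently, remapping identifiers, masking known
regions — not robustness to free-text or visual variability of real
clinical data.

## Problem sizes and numerical choices

The test suite runs on a miniature all-modality collection (20 images)
covering every manufacturer-specific private-attribute family and a shared
CR/DX patient; the acceptance script runs the full 1,693-image composition
at 128×128. Both are deterministic in the seed. Tolerances are exact
throughout — counts are integers, string checks are string checks; the only
floating-point comparison (rect uniformity) uses an exact zero on integer
data. Degenerate inputs are rejected early: empty manifests expand to empty
plans; matrices under 32 pixels, out-of-bounds rects, text that cannot fit
its rect, invalid calendar dates, and non-injective crosswalks all raise
before any artifact is written.
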