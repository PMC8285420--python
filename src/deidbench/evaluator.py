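"""Scoring a candidate de-identified dataset against an answer key.

Each answer-key entry is resolved to the candidate's instances through the
patient-ID and UID crosswalks, checked per its action, and aggregated into an
:class:`EvaluationReport`.  Failures are results, not errors; entries whose
selector cannot be resolved through the crosswalks are reported separately as
``unresolvable`` so bookkeeping mistakes are not conflated with
de-identification mistakes.

Matching policy: leakage and ``text_removed`` are case-insensitive (a leaked
name in any casing is still PHI); ``text_retained`` is case-sensitive
(retained clinical text must survive verbatim).  Pixel checks are limited to
the answer key's burn-in rectangles — a region counts as hidden only when it
is perfectly uniform; there is no OCR.

The module also ships a reference ("oracle") de-identifier that performs
exactly what the key demands.  It exists to close the loop — its output must
score 100% with zero leaks — and to produce single-fault variants for
localization testing.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

import numpy as np

from .answer_key import AnswerKeyEntry, Crosswalk
from .dataset import DicomDataset
from .dicom_core import InstanceObject
from .phi_forge import PhiRecord, derive_seed, shift_date
from .tags import parse_tag

__all__ = [
    "CheckResult",
    "EvaluationReport",
    "resolve_scope",
    "check_entry",
    "scan_leakage",
    "corpus_from_key",
    "corpus_from_records",
    "build_oracle_deid",
    "summarize",
    "evaluate",
    "ORACLE_FAULTS",
]

_UI_RE = re.compile(r"^[0-9.]{1,64}$")
_PATIENT_ID_TAG = parse_tag("(0010,0020)")

ORACLE_FAULTS = ("keep_burnin", "keep_private", "keep_dates", "keep_uids")


@dataclass
class CheckResult:
    entry: AnswerKeyEntry
    status: str  # pass | fail | unresolvable
    evidence: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.status in ("fail", "unresolvable") and not self.evidence:
            raise ValueError(f"{self.status} result requires evidence")


@dataclass
class EvaluationReport:
    per_action_counts: dict[str, dict[str, int]]
    leaks: list[dict]
    overall_pass: bool
    results: list[CheckResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scope resolution


def resolve_scope(
    entry: AnswerKeyEntry, dataset: DicomDataset, xwalk: Crosswalk
) -> tuple[list[InstanceObject], str | None]:
    """Map an entry's original-dataset selector to candidate instances.

    Returns ``(instances, None)`` or ``([], reason)`` when the selector is
    missing from the crosswalk or matches nothing.
    """
    if entry.scope == "Patient":
        new_id = xwalk.patient_map.get(entry.selector)
        if new_id is None:
            return [], f"patient {entry.selector!r} not in patient crosswalk"
        found = [i for i in dataset if i.patient_id == new_id]
    elif entry.scope in ("Study", "Series", "Instance"):
        new_uid = xwalk.uid_map.get(entry.selector)
        if new_uid is None:
            return [], f"{entry.scope.lower()} UID {entry.selector!r} not in UID crosswalk"
        level = {"Study": 0, "Series": 1, "Instance": 2}[entry.scope]
        found = [i for i in dataset if i.uids[level] == new_uid]
    else:
        return [], f"unsupported scope {entry.scope!r}"
    if not found:
        return [], f"selector {entry.selector!r} maps to no instance"
    return found, None


def _text_value(inst: InstanceObject, entry: AnswerKeyEntry) -> str | bytes | None:
    el = inst.get_element(entry.tag)
    return None if el is None else el.value


# ---------------------------------------------------------------------------
# Per-entry checks


def check_entry(
    entry: AnswerKeyEntry,
    instances: list[InstanceObject],
    options: dict | None = None,
) -> CheckResult:
    """Check one answer-key entry against its resolved instances.

    ``options`` for ``date_shifted``: ``{"mode": "infer",
    "consensus": {patient_id: days}}`` or ``{"mode": "fixed",
    "days": {patient_id: days}}`` with candidate-dataset patient IDs as keys.
    """
    options = options or {}
    evidence: list[dict] = []
    action = entry.action

    if action == "tag_retained":
        for inst in instances:
            if inst.get_element(entry.tag) is None:
                evidence.append({"instance": inst.instance_uid, "problem": "tag absent"})
    elif action == "text_notnull":
        for inst in instances:
            val = _text_value(inst, entry)
            if val in (None, "", b""):
                evidence.append({"instance": inst.instance_uid, "problem": "null value"})
    elif action == "text_retained":
        for inst in instances:
            val = _text_value(inst, entry)
            text = val if isinstance(val, str) else ""
            for span in entry.action_text:
                if span not in text:
                    evidence.append(
                        {"instance": inst.instance_uid, "missing": span, "value": text}
                    )
    elif action == "text_removed":
        for inst in instances:
            val = _text_value(inst, entry)
            if not isinstance(val, str) or not val:
                continue  # absent or empty satisfies removal
            low = val.lower()
            for span in entry.action_text:
                if span.lower() in low:
                    evidence.append(
                        {"instance": inst.instance_uid, "residual": span, "value": val}
                    )
    elif action == "date_shifted":
        original = entry.action_text[0]
        offsets = set()
        for inst in instances:
            val = _text_value(inst, entry)
            if not isinstance(val, str) or not re.match(r"^\d{8}$", val):
                evidence.append({"instance": inst.instance_uid, "value": str(val)})
                continue
            import datetime as _dt

            d0 = _dt.date(int(original[:4]), int(original[4:6]), int(original[6:8]))
            d1 = _dt.date(int(val[:4]), int(val[4:6]), int(val[6:8]))
            offsets.add((d1 - d0).days)
        if not evidence:
            if len(offsets) != 1:
                evidence.append({"problem": f"inconsistent offsets {sorted(offsets)}"})
            else:
                offset = offsets.pop()
                pid = instances[0].patient_id
                if options.get("mode", "infer") == "fixed":
                    want = options.get("days", {}).get(pid)
                    if want is None or offset != want:
                        evidence.append(
                            {"problem": f"offset {offset} != configured {want}"}
                        )
                else:
                    want = options.get("consensus", {}).get(pid)
                    if offset == 0:
                        evidence.append({"problem": "date not shifted (offset 0)"})
                    elif want is not None and offset != want:
                        evidence.append(
                            {"problem": f"offset {offset} != patient consensus {want}"}
                        )
    elif action == "uid_changed":
        original = entry.action_text[0]
        mapped = options.get("uid_map", {}).get(original)
        for inst in instances:
            val = _text_value(inst, entry)
            if not isinstance(val, str) or not _UI_RE.match(val):
                evidence.append({"instance": inst.instance_uid, "problem": f"invalid UID {val!r}"})
            elif val == original:
                evidence.append({"instance": inst.instance_uid, "problem": "UID unchanged"})
            elif mapped is not None and val != mapped:
                evidence.append(
                    {"instance": inst.instance_uid, "problem": f"UID {val} != crosswalk {mapped}"}
                )
    elif action == "pixels_hidden":
        r0, c0, r1, c1 = entry.rect()
        for inst in instances:
            px = inst.pixels
            if r1 > px.shape[0] or c1 > px.shape[1]:
                evidence.append({"instance": inst.instance_uid, "problem": "rect out of bounds"})
                continue
            region = px[r0:r1, c0:c1]
            sd = float(np.std(region.astype(np.float64)))
            if sd != 0.0:
                evidence.append(
                    {"instance": inst.instance_uid, "residual_std": sd, "problem": "region not uniform"}
                )
    else:  # pragma: no cover - AnswerKeyEntry already validates
        raise ValueError(f"unknown action {action!r}")

    return CheckResult(entry=entry, status="fail" if evidence else "pass", evidence=evidence)


# ---------------------------------------------------------------------------
# Leakage scan


def corpus_from_key(entries: list[AnswerKeyEntry], include_dates: bool = False) -> list[str]:
    """All PHI strings the key says must be gone (text, UIDs and, optionally,
    bare dates).

    Bare 8-digit dates are excluded from the global scan by default: they are
    verified by the targeted per-scope ``date_shifted`` / ``text_removed``
    checks, and are too low-entropy for a global substring scan — a correctly
    shifted date of one patient can coincide with another patient's original.
    """
    spans: set[str] = set()
    for e in entries:
        if e.action in ("text_removed", "date_shifted", "uid_changed"):
            spans.update(e.action_text)
    if not include_dates:
        spans = {s for s in spans if not re.match(r"^\d{8}$", s)}
    return sorted(spans)


def corpus_from_records(records: dict[str, PhiRecord] | list[PhiRecord]) -> list[str]:
    """Every identity string of a PHI corpus, for baseline scans."""
    if isinstance(records, dict):
        records = list(records.values())
    spans: set[str] = set()
    for r in records:
        spans.update(
            [
                r.patient_name,
                r.display_name,
                r.patient_id,
                r.birth_date,
                r.address,
                r.phone,
                r.referring_physician,
                r.performing_physician,
                r.institution,
                r.comments_seed,
                *r.accession_numbers,
                *r.study_dates,
                *r.extra.values(),
            ]
        )
    return sorted(spans)


def scan_leakage(
    dataset: DicomDataset,
    phi_corpus: list[str],
    pixel_checks: list[tuple[str, tuple[int, int, int, int], str]] = (),
) -> list[dict]:
    """Case-insensitive substring scan of every text element of every
    instance, plus uniformity checks of the given burn-in rects.

    ``pixel_checks`` items are ``(instance_uid-in-this-dataset, rect, text)``.
    Returns one leak record per (instance, location, matched text).
    """
    # digit/dot boundary guards stop a UID or date from "matching" inside a
    # longer identifier (e.g. instance UID ...3.1 as a prefix of ...3.11)
    def pattern(low: str) -> re.Pattern:
        pre = r"(?<![0-9.])" if low[0] in "0123456789." else ""
        post = r"(?![0-9.])" if low[-1] in "0123456789." else ""
        return re.compile(pre + re.escape(low) + post)

    needles = [
        (s, s.lower(), pattern(s.lower())) for s in sorted(set(phi_corpus)) if s
    ]
    leaks: list[dict] = []
    for inst in dataset:
        elements = list(inst.iter_text_elements())
        blob = "\n".join(v for _, v in elements).lower()
        for span, low, pat in needles:
            if low not in blob or not pat.search(blob):
                continue
            for location, value in elements:
                if pat.search(value.lower()):
                    leaks.append(
                        {
                            "instance": inst.instance_uid,
                            "location": location,
                            "text": span,
                        }
                    )
    by_uid = {i.instance_uid: i for i in dataset}
    for uid, rect, text in pixel_checks:
        inst = by_uid.get(uid)
        if inst is None:
            continue
        r0, c0, r1, c1 = rect
        region = inst.pixels[r0:r1, c0:c1]
        if region.size and float(np.std(region.astype(np.float64))) != 0.0:
            leaks.append({"instance": uid, "location": "pixels", "text": text})
    return leaks


# ---------------------------------------------------------------------------
# Aggregation


def summarize(results: list[CheckResult], leaks: list[dict]) -> EvaluationReport:
    counts: dict[str, dict[str, int]] = {}
    for r in results:
        bucket = counts.setdefault(
            r.entry.action, {"pass": 0, "fail": 0, "unresolvable": 0}
        )
        bucket[r.status] += 1
    overall = (
        all(r.status == "pass" for r in results) and not leaks
    )
    return EvaluationReport(
        per_action_counts=counts, leaks=leaks, overall_pass=overall, results=results
    )


def evaluate(
    dataset: DicomDataset,
    key: list[AnswerKeyEntry],
    xwalk: Crosswalk,
    shift_mode: str = "infer",
) -> EvaluationReport:
    """Full scoring pass: resolve, check every entry, scan for leakage."""
    if shift_mode not in ("infer", "fixed"):
        raise ValueError(f"shift_mode must be 'infer' or 'fixed', got {shift_mode!r}")
    resolved: list[tuple[AnswerKeyEntry, list[InstanceObject], str | None]] = []
    for entry in key:
        instances, reason = resolve_scope(entry, dataset, xwalk)
        resolved.append((entry, instances, reason))

    options: dict = {"mode": shift_mode, "uid_map": xwalk.uid_map}
    if shift_mode == "fixed":
        inverse_pid = {v: k for k, v in xwalk.patient_map.items()}
        options["days"] = {
            new: (xwalk.date_shift_days or {}).get(orig)
            for new, orig in inverse_pid.items()
        }
    else:
        # consensus offset per candidate patient, majority over date entries
        import collections
        import datetime as _dt

        votes: dict[str, collections.Counter] = {}
        for entry, instances, reason in resolved:
            if entry.action != "date_shifted" or reason or not instances:
                continue
            original = entry.action_text[0]
            val = _text_value(instances[0], entry)
            if isinstance(val, str) and re.match(r"^\d{8}$", val):
                d0 = _dt.date(int(original[:4]), int(original[4:6]), int(original[6:8]))
                d1 = _dt.date(int(val[:4]), int(val[4:6]), int(val[6:8]))
                votes.setdefault(instances[0].patient_id, collections.Counter())[
                    (d1 - d0).days
                ] += 1
        options["consensus"] = {
            pid: counter.most_common(1)[0][0] for pid, counter in votes.items()
        }

    results: list[CheckResult] = []
    for entry, instances, reason in resolved:
        if reason is not None:
            results.append(
                CheckResult(entry=entry, status="unresolvable", evidence=[{"problem": reason}])
            )
        else:
            results.append(check_entry(entry, instances, options))

    pixel_checks = []
    for entry in key:
        if entry.action == "pixels_hidden":
            mapped = xwalk.uid_map.get(entry.selector)
            if mapped:
                pixel_checks.append((mapped, entry.rect(), entry.action_text[1]))
    leaks = scan_leakage(dataset, corpus_from_key(key), pixel_checks)
    return summarize(results, leaks)


# ---------------------------------------------------------------------------
# Oracle de-identifier


def build_oracle_deid(
    dataset: DicomDataset,
    key: list[AnswerKeyEntry],
    seed: int,
    faults: frozenset[str] | set[str] = frozenset(),
) -> tuple[DicomDataset, Crosswalk]:
    """Reference de-identifier: does exactly what the key demands.

    Removes every ``text_removed`` span (string surgery, retained text kept),
    shifts each patient's dates by one nonzero drawn offset, masks burn-in
    rects to zero, and freshly remaps patient IDs and UIDs.  ``faults`` are
    deliberate single omissions for fault-localization tests:
    ``keep_burnin``, ``keep_private``, ``keep_dates``, ``keep_uids``.
    """
    unknown = set(faults) - set(ORACLE_FAULTS)
    if unknown:
        raise ValueError(f"unknown faults {sorted(unknown)}")
    out = dataset.copy()
    # snapshot scope index: edits (e.g. clearing Patient ID) must not
    # disturb resolution of later entries
    from .injector import build_scope_index

    index = build_scope_index(out)
    pid_of = {i.instance_uid: i.patient_id for i in out}

    def scoped(entry: AnswerKeyEntry) -> list[InstanceObject]:
        found = index.get((entry.scope, entry.selector), [])
        if not found:
            raise KeyError(f"key entry references absent {entry.scope} {entry.selector}")
        return found

    rng = random.Random(derive_seed(seed, "oracle"))
    offsets: dict[str, int] = {}
    for pid in sorted({i.patient_id for i in out}):
        magnitude = rng.randrange(30, 365)
        offsets[pid] = magnitude if rng.random() < 0.5 else -magnitude
    if "keep_dates" in faults:
        offsets = {pid: 0 for pid in offsets}

    for entry in key:
        if entry.action == "text_removed":
            if "keep_private" in faults and entry.tag is not None and entry.tag.is_private:
                continue
            for inst in scoped(entry):
                el = inst.get_element(entry.tag)
                if el is None or not isinstance(el.value, str):
                    continue
                value = el.value
                for span in entry.action_text:
                    value = value.replace(span, "")
                value = re.sub(r"  +", " ", value).strip()
                inst.set_value(entry.tag, value, vr=el.vr)
        elif entry.action == "date_shifted":
            for inst in scoped(entry):
                el = inst.get_element(entry.tag)
                if el is None or not isinstance(el.value, str) or not el.value:
                    continue
                days = offsets[pid_of[inst.instance_uid]]
                if days:
                    inst.set_value(entry.tag, shift_date(el.value, days), vr="DA")
        elif entry.action == "pixels_hidden":
            if "keep_burnin" in faults:
                continue
            r0, c0, r1, c1 = entry.rect()
            for inst in scoped(entry):
                px = inst.pixels.copy()
                px[r0:r1, c0:c1] = 0
                inst.set_pixels(px)

    # fresh identifier spaces
    old_pids = sorted(set(pid_of.values()))
    patient_map = {pid: f"DEID{k + 1:04d}" for k, pid in enumerate(old_pids)}
    # second fixed segment "9" differs from the phantom factory's "0", so no
    # original UID can be a substring of a remapped one (leak-scan safety)
    uid_root = f"1.2.826.0.1.3680043.10.1342.{derive_seed(seed, 'uids') % 10**9}.9"
    uid_map: dict[str, str] = {}
    counter = 0
    for inst in dataset:
        study, series, iuid = inst.uids
        for level, old in (("1", study), ("2", series), ("3", iuid)):
            if old not in uid_map:
                counter += 1
                uid_map[old] = f"{uid_root}.{level}.{counter}"
    if "keep_uids" in faults:
        uid_map = {uid: uid for uid in uid_map}

    for inst in out:
        study, series, iuid = inst.uids
        inst.ds.PatientID = patient_map[pid_of[iuid]]
        inst.ds.StudyInstanceUID = uid_map[study]
        inst.ds.SeriesInstanceUID = uid_map[series]
        inst.ds.SOPInstanceUID = uid_map[iuid]

    xwalk = Crosswalk(
        patient_map=patient_map,
        uid_map=uid_map,
        date_shift_days=dict(offsets),  # keyed by original patient id
    )
    return out, xwalk
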