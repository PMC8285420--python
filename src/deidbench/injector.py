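"""Re-identification operations: seeding a clean dataset with synthetic PHI.

Six operations cover everything the benchmark injects: ``set_tag`` (create or
overwrite), ``delete_tag``, ``shift_date``, ``substitute`` (overwrite only if
a non-empty value exists), ``string_replace`` (in-value text substitution) and
``annotate_img`` (burn text into the pixel matrix).  Each application is
logged as an :class:`AppliedOperation` carrying the affected instances and
the PHI / retained text spans — the provenance from which the answer key is
derived.

Scopes are Collection / Patient / Study / Series / Instance; selectors are
resolved against a snapshot of the dataset taken before the first directive
runs, so a plan that rewrites Patient ID can still address that patient by
the original identifier in later directives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

from .dataset import DicomDataset
from .dicom_core import InstanceObject, attribute_type, VrError
from .font import render_text
from .phi_forge import PhiRecord, PayloadTemplate, make_phi_record, render_payload, shift_date
from .tags import TagPath, parse_tag, format_tag

__all__ = [
    "OPERATION_KINDS",
    "SCOPES",
    "InjectionDirective",
    "AppliedOperation",
    "InjectionError",
    "apply_set_tag",
    "apply_delete_tag",
    "apply_shift_date",
    "apply_substitute",
    "apply_string_replace",
    "apply_annotate_img",
    "run_plan",
    "build_default_plan",
    "write_plan",
    "read_plan",
    "write_provenance",
    "read_provenance",
]

OPERATION_KINDS = (
    "set_tag",
    "delete_tag",
    "shift_date",
    "substitute",
    "string_replace",
    "annotate_img",
)
SCOPES = ("Collection", "Patient", "Study", "Series", "Instance")

BURN_VALUE = 0xFFFF  # glyph pixels take the maximum representable value


class InjectionError(ValueError):
    """Directive cannot be applied (bad params, protected tag, bad rect)."""


@dataclass(frozen=True)
class InjectionDirective:
    """One declarative edit: scope + selector + operation + parameters."""

    scope: str
    selector: str
    op: str
    tag: TagPath | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scope not in SCOPES:
            raise InjectionError(f"unknown scope {self.scope!r}")
        if self.op not in OPERATION_KINDS:
            raise InjectionError(f"unknown operation {self.op!r}")
        if self.op == "annotate_img":
            rect = self.params.get("rect")
            if not rect or len(rect) != 4:
                raise InjectionError("annotate_img requires a rect [r0,c0,r1,c1]")
            r0, c0, r1, c1 = rect
            if not (0 <= r0 < r1 and 0 <= c0 < c1):
                raise InjectionError(f"degenerate rect {rect}")
        elif self.tag is None:
            raise InjectionError(f"{self.op} requires a tag")

    def to_json(self) -> str:
        d = {
            "scope": self.scope,
            "selector": self.selector,
            "op": self.op,
            "tag": format_tag(self.tag) if self.tag else None,
            "params": self.params,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, line: str) -> "InjectionDirective":
        d = json.loads(line)
        return cls(
            scope=d["scope"],
            selector=d["selector"],
            op=d["op"],
            tag=parse_tag(d["tag"]) if d.get("tag") else None,
            params=d.get("params", {}),
        )


@dataclass
class AppliedOperation:
    """Provenance record of one directive application."""

    directive: InjectionDirective
    affected_instances: list[str]
    before_value: str | None = None
    after_value: str | None = None
    phi_spans: list[str] = field(default_factory=list)
    retained_spans: list[str] = field(default_factory=list)
    n_replacements: int = 0
    skipped_instances: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scope resolution


def build_scope_index(dataset: DicomDataset) -> dict[tuple[str, str], list[InstanceObject]]:
    index: dict[tuple[str, str], list[InstanceObject]] = {}
    for inst in dataset:
        study, series, iuid = inst.uids
        for key in (
            ("Collection", "*"),
            ("Patient", inst.patient_id),
            ("Study", study),
            ("Series", series),
            ("Instance", iuid),
        ):
            index.setdefault(key, []).append(inst)
    return index


def _scoped(dataset, directive, index):
    if index is None:
        index = build_scope_index(dataset)
    instances = index.get((directive.scope, directive.selector), [])
    if not instances:
        raise InjectionError(
            f"{directive.scope} selector {directive.selector!r} resolves to nothing"
        )
    return instances


def _as_text(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bytes):
        return value.decode("ascii", "replace")
    return str(value)


# ---------------------------------------------------------------------------
# Operations


def apply_set_tag(dataset, directive, index=None) -> AppliedOperation:
    """Create-or-overwrite; the whole scope receives one identical value."""
    instances = _scoped(dataset, directive, index)
    value = directive.params.get("value", "")
    vr = directive.params.get("vr")
    before = _as_text(instances[0].get_value(directive.tag))
    for inst in instances:
        try:
            inst.set_value(directive.tag, value, vr=vr)
        except VrError as exc:
            raise InjectionError(str(exc)) from exc
    return AppliedOperation(
        directive=directive,
        affected_instances=[i.instance_uid for i in instances],
        before_value=before,
        after_value=value,
        phi_spans=list(directive.params.get("phi_spans", [])),
        retained_spans=list(directive.params.get("retained_spans", [])),
    )


def apply_delete_tag(dataset, directive, index=None) -> AppliedOperation:
    """Remove the tag everywhere in scope; absent tags are a recorded no-op.
    Type 1 attributes of the instance's profile are protected."""
    instances = _scoped(dataset, directive, index)
    for inst in instances:
        if attribute_type(inst.sop_class, directive.tag) == "T1":
            raise InjectionError(
                f"refusing to delete Type 1 attribute {directive.tag} "
                f"of a {inst.sop_class} instance"
            )
    affected = []
    before = None
    for inst in instances:
        el = inst.get_element(directive.tag)
        if el is not None and inst.delete(directive.tag):
            if before is None:
                before = _as_text(el.value)
            affected.append(inst.instance_uid)
    return AppliedOperation(
        directive=directive,
        affected_instances=affected,
        before_value=before,
        after_value=None,
    )


def apply_shift_date(dataset, directive, index=None) -> AppliedOperation:
    """Shift a DA value by ``params["days"]``; scope-wide consistent."""
    instances = _scoped(dataset, directive, index)
    days = int(directive.params["days"])
    before = after = None
    for inst in instances:
        el = inst.get_element(directive.tag)
        if el is None or el.vr != "DA":
            raise InjectionError(f"{directive.tag} is not a populated DA attribute")
        try:
            shifted = shift_date(_as_text(el.value), days)
        except ValueError as exc:
            raise InjectionError(str(exc)) from exc
        if before is None:
            before, after = _as_text(el.value), shifted
        inst.set_value(directive.tag, shifted, vr="DA")
    return AppliedOperation(
        directive=directive,
        affected_instances=[i.instance_uid for i in instances],
        before_value=before,
        after_value=after,
    )


def apply_substitute(dataset, directive, index=None) -> AppliedOperation:
    """Overwrite only where the tag already holds a non-empty value;
    instances lacking it are skipped and recorded."""
    instances = _scoped(dataset, directive, index)
    value = directive.params.get("value", "")
    affected, skipped = [], []
    before = None
    for inst in instances:
        el = inst.get_element(directive.tag)
        if el is None or el.value in ("", b"", None):
            skipped.append(inst.instance_uid)
            continue
        if before is None:
            before = _as_text(el.value)
        inst.set_value(directive.tag, value, vr=directive.params.get("vr") or el.vr)
        affected.append(inst.instance_uid)
    return AppliedOperation(
        directive=directive,
        affected_instances=affected,
        before_value=before,
        after_value=value if affected else None,
        phi_spans=list(directive.params.get("phi_spans", [])) if affected else [],
        retained_spans=list(directive.params.get("retained_spans", [])) if affected else [],
        skipped_instances=skipped,
    )


def apply_string_replace(dataset, directive, index=None) -> AppliedOperation:
    """Replace every occurrence of ``old`` with ``new`` in the tag's value."""
    instances = _scoped(dataset, directive, index)
    old, new = directive.params["old"], directive.params["new"]
    total = 0
    before = after = None
    affected = []
    for inst in instances:
        el = inst.get_element(directive.tag)
        if el is None or not isinstance(el.value, str):
            continue
        count = el.value.count(old)
        total += count
        if count and old != new:
            if before is None:
                before = el.value
            replaced = el.value.replace(old, new)
            inst.set_value(directive.tag, replaced, vr=el.vr)
            after = replaced
            affected.append(inst.instance_uid)
        elif count:
            affected.append(inst.instance_uid)
    return AppliedOperation(
        directive=directive,
        affected_instances=affected,
        before_value=before,
        after_value=after,
        phi_spans=list(directive.params.get("phi_spans", [])) if affected else [],
        retained_spans=list(directive.params.get("retained_spans", [])) if affected else [],
        n_replacements=total,
    )


def apply_annotate_img(dataset, directive, index=None) -> AppliedOperation:
    """Burn text into the pixel matrix: glyph pixels within the rect are set
    to the maximum pixel value; everything else is untouched."""
    instances = _scoped(dataset, directive, index)
    text = directive.params.get("text", "")
    r0, c0, r1, c1 = directive.params["rect"]
    scale = int(directive.params.get("scale", 1))
    for inst in instances:
        px = inst.pixels.copy()
        rows, cols = px.shape
        if r1 > rows or c1 > cols:
            raise InjectionError(f"rect {(r0, c0, r1, c1)} exceeds {rows}x{cols} matrix")
        if text:
            mask = render_text(text, scale=scale)
            if mask.shape[0] > r1 - r0 or mask.shape[1] > c1 - c0:
                raise InjectionError(
                    f"text needs {mask.shape} pixels, rect offers "
                    f"{(r1 - r0, c1 - c0)}"
                )
            region = px[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
            region[mask] = BURN_VALUE
        inst.set_pixels(px)
    return AppliedOperation(
        directive=directive,
        affected_instances=[i.instance_uid for i in instances],
        phi_spans=[text] if text else [],
    )


_DISPATCH = {
    "set_tag": apply_set_tag,
    "delete_tag": apply_delete_tag,
    "shift_date": apply_shift_date,
    "substitute": apply_substitute,
    "string_replace": apply_string_replace,
    "annotate_img": apply_annotate_img,
}


def run_plan(
    dataset: DicomDataset,
    plan: list[InjectionDirective],
    phi: dict[str, PhiRecord] | None = None,
    seed: int = 0,
) -> tuple[DicomDataset, list[AppliedOperation]]:
    """Apply a plan in order to a copy of *dataset*.

    Selectors resolve against the dataset as it stood before the plan ran.
    The first failing directive aborts with its position in the plan.
    Deterministic: the directives carry concrete values, so equal inputs give
    byte-equal outputs.
    """
    out = dataset.copy()
    index = build_scope_index(out)
    provenance: list[AppliedOperation] = []
    for pos, directive in enumerate(plan):
        try:
            provenance.append(_DISPATCH[directive.op](out, directive, index))
        except InjectionError as exc:
            raise InjectionError(f"directive {pos} ({directive.op}): {exc}") from exc
    return out, provenance


# ---------------------------------------------------------------------------
# Plan / provenance files (JSON-lines)


def write_plan(plan: list[InjectionDirective], path: str | Path) -> None:
    Path(path).write_text("".join(d.to_json() + "\n" for d in plan))


def read_plan(path: str | Path) -> list[InjectionDirective]:
    return [
        InjectionDirective.from_json(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_provenance(provenance: list[AppliedOperation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for op in provenance:
            d = asdict(op)
            d["directive"] = json.loads(op.directive.to_json())
            fh.write(json.dumps(d) + "\n")


def read_provenance(path: str | Path) -> list[AppliedOperation]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        directive = InjectionDirective.from_json(json.dumps(d.pop("directive")))
        out.append(AppliedOperation(directive=directive, **d))
    return out


# ---------------------------------------------------------------------------
# Default plan


def _catalogue() -> list[dict]:
    path = resources.files("deidbench").joinpath("data").joinpath("payload_templates.json")
    return json.loads(Path(str(path)).read_text())


def _applies(entry: dict, modality: str, manufacturer: str) -> bool:
    if entry.get("modalities") and modality not in entry["modalities"]:
        return False
    if entry.get("manufacturers") and manufacturer not in entry["manufacturers"]:
        return False
    return True


def _wrap_burn_text(words: list[str], rows: int, cols: int, margin: int = 4) -> str:
    """Greedy word wrap to fit the pixel matrix; errors if a word cannot fit."""
    max_chars = (cols - 2 * margin + 1) // 6
    max_lines = (rows - 2 * margin + 2) // 9
    if max_chars < 1 or max_lines < 1:
        raise InjectionError(f"matrix {rows}x{cols} too small for burn-in text")
    lines, cur = [], ""
    for word in words:
        if len(word) > max_chars:
            raise InjectionError(f"word {word!r} too wide for {cols}-pixel matrix")
        cand = f"{cur} {word}".strip()
        if len(cand) <= max_chars:
            cur = cand
        else:
            lines.append(cur)
            cur = word
    if cur:
        lines.append(cur)
    if len(lines) > max_lines:
        raise InjectionError("burn-in text too tall for matrix")
    return "\n".join(lines)


def build_default_plan(
    dataset: DicomDataset, seed: int, burn_in: bool = True
) -> tuple[list[InjectionDirective], dict[str, PhiRecord]]:
    """Build the default injection plan for a clean dataset.

    One synthetic identity per patient; every applicable catalogue attribute
    receives a payload; study dates are shifted onto the identity's synthetic
    dates; one burn-in annotation per series (first instance).  Returns the
    plan and the patient-keyed identity corpus (keys are the clean dataset's
    patient IDs).
    """
    catalogue = _catalogue()
    plan: list[InjectionDirective] = []
    records: dict[str, PhiRecord] = {}

    # strip the factory's own de-identification markers first
    for tag in ("(0012,0062)", "(0012,0063)"):
        plan.append(
            InjectionDirective(
                scope="Collection", selector="*", op="delete_tag", tag=parse_tag(tag)
            )
        )

    patients = dataset.patients()
    series_ordinal = 0
    for p_idx, (patient_id, instances) in enumerate(sorted(patients.items())):
        studies: dict[str, list[InstanceObject]] = {}
        for inst in instances:
            studies.setdefault(inst.uids[0], []).append(inst)
        study_uids = sorted(studies)
        record = make_phi_record(seed, p_idx, n_studies=len(study_uids))
        records[patient_id] = record

        def emit(entry: dict, scope: str, selector: str, study_idx: int | None = None):
            phi_refs = [
                ref.replace(":J", f":{study_idx}") for ref in entry.get("phi", [])
            ]
            retained = list(entry.get("retained", []))
            tag = parse_tag(entry["tag"])
            op = entry.get("op", "set_tag")
            if op == "string_replace":
                inserted = " ".join(record.field_value(r) for r in phi_refs)
                params = {
                    "old": entry["old"],
                    "new": entry["old"] + " " + inserted,
                    "phi_spans": [record.field_value(r) for r in phi_refs],
                }
            else:
                template = PayloadTemplate(
                    target=entry["tag"],
                    phi_parts=tuple(phi_refs),
                    retained_parts=tuple(retained),
                    assembly=entry.get("assembly", "phi_first"),
                )
                value, phi_spans, retained_spans = render_payload(template, record)
                params = {
                    "value": value,
                    "phi_spans": phi_spans,
                    "retained_spans": retained_spans,
                }
                if entry.get("vr"):
                    params["vr"] = entry["vr"]
            plan.append(
                InjectionDirective(scope=scope, selector=selector, op=op, tag=tag, params=params)
            )

        for entry in (e for e in catalogue if e["scope"] == "Patient"):
            modality = instances[0].sop_class
            if _applies(entry, modality, ""):
                emit(entry, "Patient", patient_id)

        for j, study_uid in enumerate(study_uids):
            study_instances = studies[study_uid]
            modality = study_instances[0].sop_class
            manufacturer = _as_text(study_instances[0].get_value(parse_tag("(0008,0070)")))
            desc = _as_text(study_instances[0].get_value(parse_tag("(0008,1030)")))
            for entry in (e for e in catalogue if e["scope"] == "Study"):
                if not _applies(entry, modality, manufacturer):
                    continue
                e = dict(entry)
                e["retained"] = [desc if r == "$DESC" else r for r in e.get("retained", [])]
                emit(e, "Study", study_uid, study_idx=j)
            # move the clean placeholder study date onto the identity's date
            import datetime as _dt

            clean = _as_text(study_instances[0].get_value(parse_tag("(0008,0020)")))
            target = record.study_dates[j]
            days = (
                _dt.date(int(target[:4]), int(target[4:6]), int(target[6:8]))
                - _dt.date(int(clean[:4]), int(clean[4:6]), int(clean[6:8]))
            ).days
            plan.append(
                InjectionDirective(
                    scope="Study",
                    selector=study_uid,
                    op="shift_date",
                    tag=parse_tag("(0008,0020)"),
                    params={"days": days},
                )
            )

            series: dict[str, list[InstanceObject]] = {}
            for inst in study_instances:
                series.setdefault(inst.uids[1], []).append(inst)
            for series_uid in sorted(series):
                series_ordinal += 1
                s_insts = series[series_uid]
                for entry in (e for e in catalogue if e["scope"] == "Series"):
                    if _applies(entry, modality, manufacturer):
                        emit(entry, "Series", series_uid, study_idx=j)
                if burn_in:
                    first = min(s_insts, key=lambda i: i.instance_uid)
                    rows, cols = first.pixels.shape
                    words = record.display_name.split() + [
                        record.birth_date,
                        f"#{series_ordinal}",
                    ]
                    text = _wrap_burn_text(words, rows, cols)
                    mask = render_text(text)
                    rect = [4, 4, 4 + mask.shape[0], 4 + mask.shape[1]]
                    plan.append(
                        InjectionDirective(
                            scope="Instance",
                            selector=first.instance_uid,
                            op="annotate_img",
                            params={"text": text, "rect": rect},
                        )
                    )
    return plan, records
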