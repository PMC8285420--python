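"""Answer keys and crosswalks.

The answer key is the machine-readable ground truth for scoring a
de-identified dataset: per attribute and scope it states what must have
happened — text removed or retained, value non-null, tag present, date
shifted, UID remapped, pixel region hidden.  It is derived mechanically from
the injector's provenance plus the dataset's UID inventory and the
research-critical attribute profiles, and serialized as CSV with
JSON-encoded action-text lists.

Crosswalks map original patient IDs and study/series/instance UIDs to their
de-identified replacements; both maps must be injective.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .dataset import DicomDataset
from .dicom_core import profile_for, tag_name
from .injector import AppliedOperation
from .tags import TagPath, parse_tag, format_tag

__all__ = [
    "ACTION_KINDS",
    "AnswerKeyEntry",
    "Crosswalk",
    "KeyFormatError",
    "derive_answer_key",
    "write_key",
    "read_key",
    "write_crosswalk",
    "read_crosswalk",
]

ACTION_KINDS = (
    "tag_retained",
    "text_notnull",
    "text_retained",
    "text_removed",
    "date_shifted",
    "uid_changed",
    "pixels_hidden",
)

_STUDY_UID_TAG = parse_tag("(0020,000d)")
_SERIES_UID_TAG = parse_tag("(0020,000e)")
_INSTANCE_UID_TAG = parse_tag("(0008,0018)")
_PATIENT_ID_TAG = parse_tag("(0010,0020)")


class KeyFormatError(ValueError):
    """Unparseable answer-key or crosswalk file."""


@dataclass(frozen=True)
class AnswerKeyEntry:
    scope: str                      # Patient | Study | Series | Instance
    selector: str                   # original-dataset identifier
    tag: TagPath | None             # absent for pixels_hidden
    tag_name: str
    action: str
    action_text: tuple[str, ...] = ()

    def __post_init__(self):
        if self.action not in ACTION_KINDS:
            raise KeyFormatError(f"unknown action {self.action!r}")
        if self.action in ("text_removed", "text_retained") and not self.action_text:
            raise KeyFormatError(f"{self.action} entry needs action text")
        if self.action == "pixels_hidden":
            self.rect()  # validates

    def rect(self) -> tuple[int, int, int, int] | None:
        if self.action != "pixels_hidden":
            return None
        try:
            r0, c0, r1, c1 = (int(x) for x in self.action_text[0].split(","))
        except (IndexError, ValueError) as exc:
            raise KeyFormatError(
                f"pixels_hidden entry needs 'r0,c0,r1,c1' action text, "
                f"got {self.action_text!r}"
            ) from exc
        if not (0 <= r0 < r1 and 0 <= c0 < c1):
            raise KeyFormatError(f"degenerate rect {self.action_text[0]!r}")
        return r0, c0, r1, c1


def derive_answer_key(
    provenance: list[AppliedOperation],
    dataset: DicomDataset | None = None,
    include_retention: bool = True,
) -> list[AnswerKeyEntry]:
    """Turn injection provenance into answer-key entries.

    PHI spans become ``text_removed``, retained spans ``text_retained``,
    date shifts ``date_shifted`` (action text: the date as it stands in the
    evaluation dataset), burn-ins ``pixels_hidden``.  When *dataset* (the
    evaluation dataset) is given, ``uid_changed`` entries are added for every
    study/series/instance UID, and ``tag_retained`` / ``text_notnull``
    entries for the research-critical attributes of each series' modality.

    Patient-scope selectors are translated to the evaluation dataset's
    Patient IDs (the identifiers a de-identifier actually sees).
    """
    # clean patient id -> injected id, from the Patient ID set_tag directives
    pid_map: dict[str, str] = {}
    for op in provenance:
        d = op.directive
        if d.op == "set_tag" and d.tag == _PATIENT_ID_TAG and d.scope == "Patient":
            pid_map[d.selector] = d.params.get("value", d.selector)

    entries: list[AnswerKeyEntry] = []

    def selector_of(op: AppliedOperation) -> str:
        d = op.directive
        if d.scope == "Patient":
            return pid_map.get(d.selector, d.selector)
        return d.selector

    for op in provenance:
        d = op.directive
        if d.op == "delete_tag":
            continue  # nothing checkable remains
        if d.op not in ("set_tag", "substitute", "string_replace", "shift_date", "annotate_img"):
            raise KeyFormatError(f"no derivable action for operation {d.op!r}")
        if not op.affected_instances:
            continue
        sel = selector_of(op)
        if d.op == "shift_date":
            entries.append(
                AnswerKeyEntry(
                    scope=d.scope,
                    selector=sel,
                    tag=d.tag,
                    tag_name=tag_name(d.tag),
                    action="date_shifted",
                    action_text=(op.after_value,),
                )
            )
            continue
        if d.op == "annotate_img":
            rect = d.params["rect"]
            entries.append(
                AnswerKeyEntry(
                    scope=d.scope,
                    selector=sel,
                    tag=None,
                    tag_name="Pixel Data",
                    action="pixels_hidden",
                    action_text=(",".join(str(x) for x in rect), d.params.get("text", "")),
                )
            )
            continue
        for span in op.phi_spans:
            entries.append(
                AnswerKeyEntry(
                    scope=d.scope,
                    selector=sel,
                    tag=d.tag,
                    tag_name=tag_name(d.tag),
                    action="text_removed",
                    action_text=(span,),
                )
            )
        for span in op.retained_spans:
            entries.append(
                AnswerKeyEntry(
                    scope=d.scope,
                    selector=sel,
                    tag=d.tag,
                    tag_name=tag_name(d.tag),
                    action="text_retained",
                    action_text=(span,),
                )
            )

    if dataset is not None:
        for study_uid in sorted(dataset.studies()):
            entries.append(
                AnswerKeyEntry(
                    scope="Study",
                    selector=study_uid,
                    tag=_STUDY_UID_TAG,
                    tag_name=tag_name(_STUDY_UID_TAG),
                    action="uid_changed",
                    action_text=(study_uid,),
                )
            )
        for series_uid in sorted(dataset.series()):
            entries.append(
                AnswerKeyEntry(
                    scope="Series",
                    selector=series_uid,
                    tag=_SERIES_UID_TAG,
                    tag_name=tag_name(_SERIES_UID_TAG),
                    action="uid_changed",
                    action_text=(series_uid,),
                )
            )
        for inst in dataset:
            entries.append(
                AnswerKeyEntry(
                    scope="Instance",
                    selector=inst.instance_uid,
                    tag=_INSTANCE_UID_TAG,
                    tag_name=tag_name(_INSTANCE_UID_TAG),
                    action="uid_changed",
                    action_text=(inst.instance_uid,),
                )
            )
        if include_retention:
            for series_uid, insts in sorted(dataset.series().items()):
                prof = profile_for(insts[0].sop_class)
                for entry in prof.entries:
                    if entry.type_code not in ("T1", "T2"):
                        continue
                    entries.append(
                        AnswerKeyEntry(
                            scope="Series",
                            selector=series_uid,
                            tag=entry.tag,
                            tag_name=entry.name,
                            action="tag_retained",
                        )
                    )
                    if entry.type_code == "T1":
                        entries.append(
                            AnswerKeyEntry(
                                scope="Series",
                                selector=series_uid,
                                tag=entry.tag,
                                tag_name=entry.name,
                                action="text_notnull",
                            )
                        )
    return entries


# ---------------------------------------------------------------------------
# Key file I/O

_COLUMNS = ["Scope", "ScopeSelector", "Tag", "TagName", "Action", "ActionText"]


def write_key(entries: list[AnswerKeyEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.scope,
                    e.selector,
                    format_tag(e.tag) if e.tag else "",
                    e.tag_name,
                    e.action,
                    json.dumps(list(e.action_text)),
                ]
            )


def read_key(path: str | Path) -> list[AnswerKeyEntry]:
    entries: list[AnswerKeyEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            if row["Action"] not in ACTION_KINDS:
                raise KeyFormatError(
                    f"{path}, line {lineno}: unknown action {row['Action']!r}"
                )
            entries.append(
                AnswerKeyEntry(
                    scope=row["Scope"],
                    selector=row["ScopeSelector"],
                    tag=parse_tag(row["Tag"]) if row["Tag"] else None,
                    tag_name=row["TagName"],
                    action=row["Action"],
                    action_text=tuple(json.loads(row["ActionText"])),
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Crosswalks


@dataclass
class Crosswalk:
    """Original→de-identified mappings for patient IDs and UIDs, plus the
    optional per-patient date-shift offsets (days; ``None`` means infer)."""

    patient_map: dict[str, str] = field(default_factory=dict)
    uid_map: dict[str, str] = field(default_factory=dict)
    date_shift_days: dict[str, int] | None = None

    def validate(self) -> None:
        for name, mapping in (("patient", self.patient_map), ("uid", self.uid_map)):
            targets = list(mapping.values())
            if len(set(targets)) != len(targets):
                raise KeyFormatError(f"{name} crosswalk is not injective")


def write_crosswalk(
    xwalk: Crosswalk,
    patient_path: str | Path,
    uid_path: str | Path,
    shift_path: str | Path | None = None,
) -> None:
    xwalk.validate()
    with open(patient_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["old", "new"])
        for old, new in sorted(xwalk.patient_map.items()):
            writer.writerow([old, new])
    with open(uid_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["old", "new"])
        for old, new in sorted(xwalk.uid_map.items()):
            writer.writerow([old, new])
    if shift_path is not None and xwalk.date_shift_days is not None:
        with open(shift_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient", "days"])
            for pid, days in sorted(xwalk.date_shift_days.items()):
                writer.writerow([pid, days])


def _read_map(path: str | Path, key: str, value: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            if row[key] in out:
                raise KeyFormatError(f"{path}, line {lineno}: duplicate source {row[key]!r}")
            out[row[key]] = row[value]
    return out


def read_crosswalk(
    patient_path: str | Path,
    uid_path: str | Path,
    shift_path: str | Path | None = None,
) -> Crosswalk:
    xwalk = Crosswalk(
        patient_map=_read_map(patient_path, "old", "new"),
        uid_map=_read_map(uid_path, "old", "new"),
    )
    if shift_path is not None:
        xwalk.date_shift_days = {
            k: int(v) for k, v in _read_map(shift_path, "patient", "days").items()
        }
    xwalk.validate()
    return xwalk
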