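"""Clean synthetic DICOM dataset generation.

A composition manifest gives per-modality patient/study/series/image counts
plus body-part and manufacturer study counts.  :func:`expand_manifest` turns
it into a fully enumerated hierarchy (deterministic largest-remainder
allocation), and :func:`build_dataset` materializes modality-correct
instances with phantom pixel data and neutral, PHI-free placeholder
demographics.  Pixel realism is a non-goal; header realism — every Type 1
attribute populated, every Type 2 present — is the point, since the dataset
exists to carry injected PHI for de-identification scoring.

A manifest row may mark some of its patients as shared with an earlier row
(``shared_patients`` column, e.g. ``DX:1``): the same patient then has
studies under both modalities, which is how a cohort can have fewer distinct
patients than the per-modality patient counts suggest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .dataset import DicomDataset
from .dicom_core import (
    InstanceObject,
    MODALITIES,
    SOP_CLASS_UIDS,
    profile_for,
    validate_instance,
)
from .phi_forge import derive_seed
from pydicom.dataset import Dataset

__all__ = [
    "ManifestRow",
    "CompositionManifest",
    "HierarchyPlan",
    "expand_manifest",
    "build_instance",
    "build_dataset",
    "render_phantom_pixels",
    "default_manifest_path",
    "ManifestError",
]

_UID_ROOT = "1.2.826.0.1.3680043.10.1342"
_CLEAN_DATE = "20200101"
_MIN_MATRIX = 32


class ManifestError(ValueError):
    """Composition manifest violates its invariants."""


# ---------------------------------------------------------------------------
# Manifest


@dataclass(frozen=True)
class ManifestRow:
    modality: str
    n_patients: int
    n_studies: int
    n_series: int
    n_images: int
    body_parts: tuple[tuple[str, int], ...]
    manufacturers: tuple[tuple[str, int], ...]
    shared_patients: tuple[tuple[str, int], ...] = ()  # (earlier modality, count)


@dataclass(frozen=True)
class CompositionManifest:
    rows: tuple[ManifestRow, ...]

    def validate(self) -> None:
        seen = set()
        for row in self.rows:
            if row.modality not in MODALITIES:
                raise ManifestError(f"unknown modality {row.modality!r}")
            if row.modality in seen:
                raise ManifestError(f"duplicate modality row {row.modality}")
            seen.add(row.modality)
            for n in (row.n_patients, row.n_studies, row.n_series, row.n_images):
                if n <= 0:
                    raise ManifestError(f"{row.modality}: counts must be positive")
            if not row.n_patients <= row.n_studies <= row.n_series:
                raise ManifestError(
                    f"{row.modality}: need patients <= studies <= series"
                )
            if row.n_images < row.n_series:
                raise ManifestError(f"{row.modality}: every series needs an image")
            if sum(c for _, c in row.body_parts) != row.n_studies:
                raise ManifestError(f"{row.modality}: body-part counts != studies")
            if sum(c for _, c in row.manufacturers) != row.n_studies:
                raise ManifestError(f"{row.modality}: manufacturer counts != studies")
            for other, cnt in row.shared_patients:
                if other not in seen or other == row.modality:
                    raise ManifestError(
                        f"{row.modality}: shared_patients must name an earlier row"
                    )
                if cnt >= row.n_patients:
                    raise ManifestError(
                        f"{row.modality}: cannot share all patients"
                    )


def _parse_pairs(text: str) -> tuple[tuple[str, int], ...]:
    if not text.strip():
        return ()
    out = []
    for item in text.split("|"):
        label, _, count = item.rpartition(":")
        out.append((label.strip(), int(count)))
    return tuple(out)


def default_manifest_path() -> Path:
    """Fixture manifest transcribing the published benchmark composition."""
    return Path(str(resources.files("deidbench").joinpath("data").joinpath("benchmark_manifest.csv")))


def load_manifest(path: str | Path | None = None) -> CompositionManifest:
    path = Path(path) if path else default_manifest_path()
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                ManifestRow(
                    modality=row["modality"].strip(),
                    n_patients=int(row["patients"]),
                    n_studies=int(row["studies"]),
                    n_series=int(row["series"]),
                    n_images=int(row["images"]),
                    body_parts=_parse_pairs(row["body_parts"]),
                    manufacturers=_parse_pairs(row["manufacturers"]),
                    shared_patients=_parse_pairs(row.get("shared_patients") or ""),
                )
            )
    manifest = CompositionManifest(rows=tuple(rows))
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# Hierarchy expansion


@dataclass
class InstanceSlot:
    instance_uid: str
    instance_number: int


@dataclass
class SeriesPlan:
    series_uid: str
    series_number: int
    modality: str
    instances: list[InstanceSlot] = field(default_factory=list)


@dataclass
class StudyPlan:
    study_uid: str
    study_id: str
    modality: str
    body_part: str
    manufacturer: str
    series: list[SeriesPlan] = field(default_factory=list)


@dataclass
class PatientPlan:
    patient_id: str
    studies: list[StudyPlan] = field(default_factory=list)


@dataclass
class HierarchyPlan:
    patients: list[PatientPlan] = field(default_factory=list)

    def iter_leaves(self):
        """Yield (patient, study, series, instance) tuples."""
        for p in self.patients:
            for st in p.studies:
                for se in st.series:
                    for inst in se.instances:
                        yield p, st, se, inst

    def counts(self) -> dict[str, int]:
        leaves = list(self.iter_leaves())
        return {
            "patients": len({p.patient_id for p, *_ in leaves}),
            "studies": len({st.study_uid for _, st, *_ in leaves}),
            "series": len({se.series_uid for _, _, se, _ in leaves}),
            "images": len(leaves),
        }

    def modality_counts(self) -> dict[str, dict[str, int]]:
        per: dict[str, dict[str, set | int]] = {}
        for p, st, se, inst in self.iter_leaves():
            d = per.setdefault(
                st.modality, {"patients": set(), "studies": set(), "series": set(), "images": 0}
            )
            d["patients"].add(p.patient_id)
            d["studies"].add(st.study_uid)
            d["series"].add(se.series_uid)
            d["images"] += 1
        return {
            m: {
                "patients": len(d["patients"]),
                "studies": len(d["studies"]),
                "series": len(d["series"]),
                "images": d["images"],
            }
            for m, d in sorted(per.items())
        }


def _distribute(total: int, slots: int) -> list[int]:
    """Largest-remainder split of *total* over *slots*; earlier slots take
    the remainder, every slot gets at least the floor share."""
    base, rem = divmod(total, slots)
    return [base + 1 if i < rem else base for i in range(slots)]


def _expand_labels(pairs: tuple[tuple[str, int], ...]) -> list[str]:
    out: list[str] = []
    for label, count in pairs:
        out.extend([label] * count)
    return out


def expand_manifest(manifest: CompositionManifest, seed: int) -> HierarchyPlan:
    """Expand a manifest into a concrete hierarchy, deterministically.

    Studies are distributed round-robin over patients, series over studies,
    images over series, always by largest remainder with earlier slots taking
    the extra unit.  Body parts and manufacturers attach to studies in
    manifest order.  UIDs are derived from the seed and are globally unique
    across the plan.
    """
    manifest.validate()
    root = f"{_UID_ROOT}.{seed % 10**9}.0"
    plan = HierarchyPlan()
    by_modality: dict[str, list[PatientPlan]] = {}
    n_patient = n_study = n_series_total = n_instance = 0

    for row in manifest.rows:
        patients: list[PatientPlan] = []
        for other, cnt in row.shared_patients:
            patients.extend(by_modality[other][:cnt])
        while len(patients) < row.n_patients:
            n_patient += 1
            p = PatientPlan(patient_id=f"PH{n_patient:06d}")
            plan.patients.append(p)
            patients.append(p)
        by_modality[row.modality] = patients

        studies_per_patient = _distribute(row.n_studies, row.n_patients)
        studies: list[StudyPlan] = []
        body_parts = _expand_labels(row.body_parts)
        manufacturers = _expand_labels(row.manufacturers)
        for patient, n_st in zip(patients, studies_per_patient):
            for _ in range(n_st):
                n_study += 1
                k = len(studies)
                body = body_parts[k]
                st = StudyPlan(
                    study_uid=f"{root}.1.{n_study}",
                    study_id=f"S{n_study:04d}",
                    modality=row.modality,
                    body_part="" if body == "[BLANK]" else body,
                    manufacturer=manufacturers[k],
                )
                patient.studies.append(st)
                studies.append(st)

        series_per_study = _distribute(row.n_series, row.n_studies)
        series: list[SeriesPlan] = []
        for st, n_se in zip(studies, series_per_study):
            for j in range(n_se):
                n_series_total += 1
                se = SeriesPlan(
                    series_uid=f"{root}.2.{n_series_total}",
                    series_number=j + 1,
                    modality=row.modality,
                )
                st.series.append(se)
                series.append(se)

        images_per_series = _distribute(row.n_images, row.n_series)
        for se, n_im in zip(series, images_per_series):
            for j in range(n_im):
                n_instance += 1
                se.instances.append(
                    InstanceSlot(
                        instance_uid=f"{root}.3.{n_instance}",
                        instance_number=j + 1,
                    )
                )
    return plan


# ---------------------------------------------------------------------------
# Phantom pixels


def render_phantom_pixels(
    rows: int, cols: int, seed: int, noise_amp: int = 500
) -> np.ndarray:
    """16-bit grayscale phantom: diagonal gradient plus seeded uniform noise.

    Values stay strictly below 65535 so the burn-in annotator, which writes
    glyphs at the maximum representable value, is always distinguishable
    from anatomy.  With ``noise_amp=0`` the array is the pure gradient
    ``1000 + 20000*(r/(rows-1)) + 20000*(c/(cols-1))`` (mean ``21000``).
    """
    if rows < _MIN_MATRIX or cols < _MIN_MATRIX:
        raise ValueError(f"matrix must be at least {_MIN_MATRIX}x{_MIN_MATRIX}")
    r = np.linspace(0.0, 1.0, rows)[:, None]
    c = np.linspace(0.0, 1.0, cols)[None, :]
    img = 1000.0 + 20000.0 * r + 20000.0 * c
    if noise_amp:
        rng = np.random.default_rng(seed)
        img = img + rng.integers(0, noise_amp + 1, size=(rows, cols))
    return img.round().astype(np.uint16)


# ---------------------------------------------------------------------------
# Instance construction


def build_instance(
    patient: PatientPlan,
    study: StudyPlan,
    series: SeriesPlan,
    slot: InstanceSlot,
    seed: int,
    matrix: int = 128,
) -> InstanceObject:
    """Materialize one plan leaf as a profile-compliant instance.

    Demographics are neutral placeholders (``PHANTOM^NNN``); no PHI exists in
    a freshly built dataset, which is what makes the later leakage scan of
    the clean baseline meaningful.
    """
    if study.modality not in SOP_CLASS_UIDS:
        raise ValueError(f"unsupported modality {study.modality!r}")
    ds = Dataset()
    inst = InstanceObject(ds)
    pixels = render_phantom_pixels(
        matrix, matrix, derive_seed(seed, "px", slot.instance_uid)
    )
    prof = profile_for(study.modality)
    phantom_no = int(patient.patient_id[2:]) % 1000
    for entry in prof.entries:
        rule = entry.rule
        if rule == "none":
            continue
        if rule == "pixels":
            inst.set_pixels(pixels)
            continue
        if rule.startswith("fixed:"):
            value = rule.split(":", 1)[1]
        elif rule == "empty":
            value = ""
        elif rule == "sop_class":
            value = SOP_CLASS_UIDS[study.modality]
        elif rule == "uid_instance":
            value = slot.instance_uid
        elif rule == "uid_study":
            value = study.study_uid
        elif rule == "uid_series":
            value = series.series_uid
        elif rule == "modality":
            value = study.modality
        elif rule == "study_date":
            value = _CLEAN_DATE
        elif rule == "manufacturer":
            value = study.manufacturer
        elif rule == "body_part":
            value = study.body_part
        elif rule == "patient_name":
            value = f"PHANTOM^{phantom_no:03d}"
        elif rule == "patient_id":
            value = patient.patient_id
        elif rule == "study_id":
            value = study.study_id
        elif rule == "series_number":
            value = str(series.series_number)
        elif rule == "instance_number":
            value = str(slot.instance_number)
        elif rule == "rows":
            value = str(pixels.shape[0])
        elif rule == "cols":
            value = str(pixels.shape[1])
        elif rule == "desc_by_modality":
            value = _DESCRIPTIONS[study.modality]
        else:
            raise ValueError(f"unknown generation rule {rule!r}")
        if rule in ("rows", "cols"):
            continue  # set by set_pixels
        inst.set_value(entry.tag, value)
    return inst


_DESCRIPTIONS = {
    "CT": "CT ABDOMEN PELVIS W CONTRAST",
    "MR": "MR ABDOMEN WO CONTRAST",
    "PT": "PET WHOLEBODY",
    "DX": "XR CHEST AP PORTABLE",
    "CR": "XR CHEST AP PORTABLE",
    "MG": "MAMMOGRAM SCREENING BILATERAL",
    "SC": "SECONDARY CAPTURE",
}


def build_dataset(
    manifest: CompositionManifest, seed: int, matrix: int = 128, validate: bool = False
) -> tuple[DicomDataset, HierarchyPlan]:
    """Expand and materialize a whole manifest."""
    plan = expand_manifest(manifest, seed)
    dataset = DicomDataset()
    for p, st, se, slot in plan.iter_leaves():
        inst = build_instance(p, st, se, slot, seed, matrix=matrix)
        if validate:
            problems = validate_instance(inst)
            if problems:
                raise AssertionError(f"{slot.instance_uid}: {problems}")
        dataset.add(inst)
    return dataset, plan
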