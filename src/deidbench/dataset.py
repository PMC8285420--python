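"""In-memory DICOM dataset: a collection of instances with hierarchy indexes
and the on-disk layout ``<modality>/<patient>/<study>/<series>/<instance>.dcm``."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from .dicom_core import InstanceObject, read_instance, write_instance

__all__ = ["DicomDataset"]


class DicomDataset:
    def __init__(self, instances: Iterable[InstanceObject] = ()):
        self.instances: list[InstanceObject] = list(instances)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[InstanceObject]:
        return iter(self.instances)

    def add(self, inst: InstanceObject) -> None:
        self.instances.append(inst)

    # -- indexes -----------------------------------------------------------
    def by_instance_uid(self) -> dict[str, InstanceObject]:
        return {inst.instance_uid: inst for inst in self.instances}

    def patients(self) -> dict[str, list[InstanceObject]]:
        out: dict[str, list[InstanceObject]] = {}
        for inst in self.instances:
            out.setdefault(inst.patient_id, []).append(inst)
        return out

    def studies(self) -> dict[str, list[InstanceObject]]:
        out: dict[str, list[InstanceObject]] = {}
        for inst in self.instances:
            out.setdefault(inst.uids[0], []).append(inst)
        return out

    def series(self) -> dict[str, list[InstanceObject]]:
        out: dict[str, list[InstanceObject]] = {}
        for inst in self.instances:
            out.setdefault(inst.uids[1], []).append(inst)
        return out

    def counts(self) -> dict[str, int]:
        return {
            "patients": len(self.patients()),
            "studies": len(self.studies()),
            "series": len(self.series()),
            "images": len(self.instances),
        }

    def modality_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, DicomDataset] = {}
        for inst in self.instances:
            out.setdefault(inst.sop_class, DicomDataset()).add(inst)
        return {mod: sub.counts() for mod, sub in sorted(out.items())}

    # -- copy / io ---------------------------------------------------------
    def copy(self) -> "DicomDataset":
        """Deep copy via serialization round-trip."""
        return DicomDataset(read_instance(write_instance(i)) for i in self.instances)

    def save(self, root: str | Path) -> list[Path]:
        root = Path(root)
        written: list[Path] = []
        series_ordinals: dict[str, int] = {}
        for inst in self.instances:
            study_uid, series_uid, instance_uid = inst.uids
            sub = (
                root
                / inst.sop_class
                / inst.patient_id
                / study_uid.rsplit(".", 1)[-1]
                / series_uid.rsplit(".", 1)[-1]
            )
            sub.mkdir(parents=True, exist_ok=True)
            n = series_ordinals.get(series_uid, 0) + 1
            series_ordinals[series_uid] = n
            path = sub / f"{instance_uid.rsplit('.', 1)[-1]}.dcm"
            path.write_bytes(write_instance(inst))
            written.append(path)
        return written

    @classmethod
    def load(cls, root: str | Path) -> "DicomDataset":
        paths = sorted(Path(root).rglob("*.dcm"))
        return cls(read_instance(p) for p in paths)
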