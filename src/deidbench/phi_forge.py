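"""Deterministic synthetic-PHI generation.

Every output is a pure function of ``(seed, patient_index)``: the forge draws
from fixed name/street/institution pools through a seeded shuffle, and embeds
the patient index into numeric identifiers so that IDs, accession numbers,
phones and dates are collision-free across a cohort without any global state.

Values are shaped like real clinical identifiers — person names in DICOM PN
form (``ROGERS^BILLY``) and display form (``Billy Rogers``), 10-digit patient
IDs, accession numbers of the form ``YYYYMMDD`` + letter + 6 digits — so that
de-identifiers are exercised against realistic text, while remaining ASCII,
US-locale and obviously synthetic on inspection.
"""

from __future__ import annotations

import datetime as _dt
import functools
import hashlib
import random
import re
from dataclasses import dataclass, field

__all__ = [
    "PhiRecord",
    "PayloadTemplate",
    "make_phi_record",
    "shift_date",
    "render_payload",
    "derive_seed",
]

_FAMILY = [
    "ROGERS", "ROBERTSON", "PHILLIPS", "BAILEY", "SMITH", "JOHNSON", "WALKER",
    "HARRIS", "MARTIN", "THOMPSON", "GARCIA", "MARTINEZ", "CLARK", "LEWIS",
    "LEE", "HALL", "ALLEN", "YOUNG", "KING", "WRIGHT", "SCOTT", "GREEN",
    "ADAMS", "NELSON", "HILL", "CAMPBELL", "MITCHELL", "CARTER", "TURNER",
    "PARKER", "COLLINS", "EDWARDS", "STEWART", "MORRIS", "MURPHY", "COOK",
    "ROGERSON", "BELL", "COOPER", "RICHARDSON", "COX", "HOWARD", "WARD",
    "BROOKS", "GRAY", "JAMES", "WATSON", "SANDERS",
]
_GIVEN = [
    "BILLY", "JESSE", "JOHN", "THERESA", "MARY", "ROBERT", "PATRICIA",
    "MICHAEL", "LINDA", "DAVID", "BARBARA", "WILLIAM", "ELIZABETH", "RICHARD",
    "SUSAN", "JOSEPH", "JESSICA", "THOMAS", "KAREN", "CHARLES", "NANCY",
    "DANIEL", "MARGARET", "MATTHEW", "LISA", "ANTHONY", "BETTY", "MARK",
    "DOROTHY", "PAUL", "SANDRA", "STEVEN", "ASHLEY", "ANDREW", "KIMBERLY",
    "GEORGE",
]
_STREETS = [
    "Maple Street", "Oak Avenue", "Cedar Lane", "Elm Drive", "Pine Court",
    "Willow Way", "Birch Road", "Sycamore Boulevard", "Juniper Terrace",
    "Magnolia Place", "Dogwood Circle", "Hickory Trail",
]
_CITIES = [
    ("Little Rock", "AR", "72201"), ("Springfield", "IL", "62701"),
    ("Fayette", "MO", "65248"), ("Georgetown", "TX", "78626"),
    ("Clayton", "NC", "27520"), ("Madison", "WI", "53703"),
    ("Franklin", "TN", "37064"), ("Greenville", "SC", "29601"),
]
_INST_FIRST = [
    "Treetop", "Riverside", "Lakeview", "Summit", "Pinecrest", "Oakdale",
    "Hillcrest", "Meadowbrook", "Clearwater", "Stonebridge", "Fairview",
    "Brookhaven", "Silverlake", "Northgate", "Eastbrook", "Westfield",
]
_INST_SECOND = [
    "Medical Center", "Memorial Hospital", "Regional Clinic",
    "Community Hospital", "Imaging Institute", "Health Pavilion",
]


def derive_seed(seed: int, *parts: object) -> int:
    """Stable sub-seed (< 2**31) from a master seed and context labels."""
    h = hashlib.sha256(repr((seed,) + parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def shift_date(date: str, days: int) -> str:
    """Offset a DA value (``YYYYMMDD``) by a signed number of days.

    Inverse of itself under negation: ``shift_date(shift_date(d, k), -k) == d``.
    """
    if not re.match(r"^\d{8}$", date or ""):
        raise ValueError(f"not a DA value: {date!r}")
    d = _dt.date(int(date[:4]), int(date[4:6]), int(date[6:8]))
    return (d + _dt.timedelta(days=days)).strftime("%Y%m%d")


@dataclass(frozen=True)
class PhiRecord:
    """One patient's complete synthetic identity — the ground truth that a
    de-identifier must scrub and a leakage scan searches for."""

    patient_index: int
    patient_name: str          # PN form, e.g. "ROGERS^BILLY"
    patient_id: str            # 10 digits, cohort-unique
    birth_date: str            # DA
    sex: str                   # CS: M/F/O
    address: str
    phone: str
    accession_numbers: tuple[str, ...]
    referring_physician: str   # PN form
    performing_physician: str  # PN form
    institution: str
    study_dates: tuple[str, ...]
    comments_seed: str
    extra: dict[str, str] = field(default_factory=dict)

    @property
    def display_name(self) -> str:
        """"Billy Rogers" form of the PN "ROGERS^BILLY"."""
        return _display(self.patient_name)

    def field_value(self, ref: str) -> str:
        """Resolve a template field reference against this record."""
        if ":" in ref:
            name, idx_s = ref.split(":", 1)
            idx = int(idx_s)
            if name == "accession":
                return self.accession_numbers[idx]
            if name == "study_date":
                return self.study_dates[idx]
            if name == "scheduled_date":
                return shift_date(self.study_dates[idx], -1)
            if name == "struct_date":
                return shift_date(self.study_dates[idx], -2)
            raise KeyError(f"unresolvable field reference {ref!r}")
        simple = {
            "patient_name": self.patient_name,
            "display_name": self.display_name,
            "patient_id": self.patient_id,
            "birth_date": self.birth_date,
            "sex": self.sex,
            "address": self.address,
            "phone": self.phone,
            "referring_physician": self.referring_physician,
            "referring_display": _display(self.referring_physician),
            "performing_physician": self.performing_physician,
            "performing_display": _display(self.performing_physician),
            "institution": self.institution,
            "comments_seed": self.comments_seed,
        }
        if ref in simple:
            return simple[ref]
        if ref in self.extra:
            return self.extra[ref]
        raise KeyError(f"unresolvable field reference {ref!r}")


@functools.lru_cache(maxsize=8)
def _shuffled_names(seed: int) -> tuple[tuple[str, str], ...]:
    combos = [(f, g) for f in _FAMILY for g in _GIVEN]
    random.Random(derive_seed(seed, "names")).shuffle(combos)
    return tuple(combos)


@functools.lru_cache(maxsize=8)
def _shuffled_institutions(seed: int) -> tuple[str, ...]:
    insts = [f"{a} {b}" for a in _INST_FIRST for b in _INST_SECOND]
    random.Random(derive_seed(seed, "institutions")).shuffle(insts)
    return tuple(insts)


def _display(pn: str) -> str:
    """PN "FAMILY^GIVEN" -> display "Given Family"."""
    parts = pn.split("^")
    ordered = parts[1:] + parts[:1]
    return " ".join(p.title() for p in ordered if p)


def make_phi_record(seed: int, patient_index: int, n_studies: int = 1) -> PhiRecord:
    """Build one patient identity; identical for identical ``(seed, index)``.

    Names are drawn from a seed-shuffled family×given product so that the
    patient, the two physicians and the technologist of one patient — and of
    every other patient in a cohort of up to 600 — are pairwise distinct.
    """
    if patient_index < 0:
        raise ValueError("patient_index must be >= 0")
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    combos = _shuffled_names(seed)
    rng = random.Random(derive_seed(seed, "record", patient_index))

    def pn(k: int) -> str:
        f, g = combos[(4 * patient_index + k) % len(combos)]
        return f"{f}^{g}"

    patient_name = pn(0)
    referring = pn(1)
    performing = pn(2)
    operator = pn(3)

    patient_id = f"{rng.randrange(10**5, 10**6):06d}{patient_index % 10000:04d}"

    # study dates: strided by patient so no two patients share a date string
    base = _dt.date(2011, 1, 4) + _dt.timedelta(
        days=37 * (patient_index % 70) + rng.randrange(0, 30)
    )
    study_dates = tuple(
        (base + _dt.timedelta(days=j)).strftime("%Y%m%d") for j in range(n_studies)
    )
    # birth 18-90 years before the studies, index-strided for uniqueness
    birth = _dt.date(1923, 1, 1) + _dt.timedelta(
        days=255 * (patient_index % 100) + rng.randrange(0, 150)
    )
    birth_date = birth.strftime("%Y%m%d")

    a2 = rng.randrange(0, 100)
    accessions = tuple(
        f"{study_dates[j]}{rng.choice('ABCDEFGHJKLMNPRSTUVWXYZ')}"
        f"{(a2 + j) % 100:02d}{patient_index % 10000:04d}"
        for j in range(n_studies)
    )

    city, state, zipc = _CITIES[rng.randrange(len(_CITIES))]
    address = f"{100 + patient_index} {rng.choice(_STREETS)}, {city}, {state} {zipc}"
    phone = f"({rng.randrange(200, 990)}) 555-{(1000 + patient_index) % 10000:04d}"

    insts = _shuffled_institutions(seed)
    institution = insts[patient_index % len(insts)]
    prior_facility = insts[(patient_index + len(insts) // 2) % len(insts)]
    # initials + digits: never a substring of any institution name
    initials = "".join(w[0] for w in institution.split()).upper()
    issuer = f"{initials}{100 + patient_index % 900}"

    comments_seed = f"Claim {rng.randrange(100, 1000)}{patient_index % 10000:04d} filed by spouse"

    def uniq(prefix: str) -> str:
        # index suffix keeps device/department identifiers cohort-unique
        return f"{prefix}{rng.randrange(100, 1000)}{patient_index % 10000:04d}"

    extra = {
        "operator_display": _display(operator),
        "issuer": issuer,
        "prior_facility": prior_facility,
        "device_serial": uniq("SN"),
        "workstation": f"{issuer}-WS{patient_index % 100:02d}",
        "department": f"{issuer} IMAGING UNIT {patient_index % 100}",
        "imaging_options": uniq("OPT"),
        "batch_desc": uniq("BATCH "),
        "service_id": uniq("SVC"),
        "coil_id": uniq("COIL"),
        "start_secs": str(rng.randrange(30000, 80000) * 10 + patient_index % 10),
        "phoenix": uniq("PHX"),
        "kanji_dept": uniq("RAD DEPT "),
        "source_ae": f"AE{issuer[:6]}{patient_index % 100:02d}",
        "mao_buffer": uniq("MAO"),
        "detector_id": uniq("DET"),
        "proc_code": uniq("PRC"),
        "struct_desc": uniq("RTSS "),
    }
    return PhiRecord(
        patient_index=patient_index,
        patient_name=patient_name,
        patient_id=patient_id,
        birth_date=birth_date,
        sex=rng.choice(["M", "F"]),
        address=address,
        phone=phone,
        accession_numbers=accessions,
        referring_physician=referring,
        performing_physician=performing,
        institution=institution,
        study_dates=study_dates,
        comments_seed=comments_seed,
        extra=extra,
    )


@dataclass(frozen=True)
class PayloadTemplate:
    """Recipe for one attribute value: PHI field references mixed with
    clinically useful text that must survive de-identification."""

    target: str                       # tag notation, informational
    phi_parts: tuple[str, ...] = ()   # field references
    retained_parts: tuple[str, ...] = ()
    assembly: str = "phi_first"       # phi_first | retained_first

    def __post_init__(self):
        if not self.phi_parts and not self.retained_parts:
            raise ValueError("template needs at least one phi or retained part")
        if self.assembly not in ("phi_first", "retained_first"):
            raise ValueError(f"unknown assembly rule {self.assembly!r}")


def render_payload(
    template: PayloadTemplate, record: PhiRecord
) -> tuple[str, list[str], list[str]]:
    """Render a template to ``(value, phi_spans, retained_spans)``.

    Every span is a verbatim substring of the value; PHI and retained spans
    never overlap (parts are joined with single spaces).
    """
    phi_spans = [record.field_value(ref) for ref in template.phi_parts]
    retained_spans = list(template.retained_parts)
    if template.assembly == "phi_first":
        parts = phi_spans + retained_spans
    else:
        parts = retained_spans + phi_spans
    return " ".join(parts), phi_spans, retained_spans
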