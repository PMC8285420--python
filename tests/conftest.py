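"""Shared fixtures: a small all-modality benchmark pipeline built once.

The mini manifest exercises every modality, every manufacturer-specific
private attribute family, and a shared CR/DX-style patient, at a size that
keeps the whole suite fast.  All stages (clean build, injection, answer key,
oracle) are session-scoped and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from deidbench import answer_key as ak
from deidbench import evaluator as ev
from deidbench import injector as inj
from deidbench import phantom_factory as pf

SEED = 11


@pytest.fixture(scope="session")
def mini_manifest() -> pf.CompositionManifest:
    rows = (
        pf.ManifestRow("CT", 2, 2, 2, 6, (("CHEST", 2),),
                       (("GE MEDICAL SYSTEMS", 1), ("TOSHIBA", 1))),
        pf.ManifestRow("MR", 1, 1, 2, 4, (("KIDNEY", 1),), (("SIEMENS", 1),)),
        pf.ManifestRow("CR", 2, 2, 2, 2, (("CHEST", 2),), (("FUJIFILM", 2),),
                       (("CT", 1),)),
        pf.ManifestRow("MG", 1, 1, 1, 2, (("BREAST", 1),), (("LORAD", 1),)),
        pf.ManifestRow("PT", 1, 1, 1, 2, (("[BLANK]", 1),), (("PHILIPS", 1),)),
        pf.ManifestRow("DX", 1, 1, 1, 2, (("CHEST", 1),),
                       (("GE MEDICAL SYSTEMS", 1),)),
    )
    return pf.CompositionManifest(rows=rows)


@dataclass
class Pipeline:
    manifest: pf.CompositionManifest
    clean: object
    plan: list
    records: dict
    evaluation: object
    provenance: list
    key: list
    oracle: object
    xwalk: object


@pytest.fixture(scope="session")
def pipeline(mini_manifest) -> Pipeline:
    clean, _ = pf.build_dataset(mini_manifest, SEED, matrix=128)
    plan, records = inj.build_default_plan(clean, SEED)
    evaluation, provenance = inj.run_plan(clean, plan)
    key = ak.derive_answer_key(provenance, dataset=evaluation)
    oracle, xwalk = ev.build_oracle_deid(evaluation, key, seed=3)
    return Pipeline(
        manifest=mini_manifest,
        clean=clean,
        plan=plan,
        records=records,
        evaluation=evaluation,
        provenance=provenance,
        key=key,
        oracle=oracle,
        xwalk=xwalk,
    )


@pytest.fixture()
def identity_xwalk(pipeline) -> ak.Crosswalk:
    """Crosswalk of a 'de-identifier' that changed nothing."""
    return ak.Crosswalk(
        patient_map={r.patient_id: r.patient_id for r in pipeline.records.values()},
        uid_map={u: u for u in pipeline.xwalk.uid_map},
    )
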