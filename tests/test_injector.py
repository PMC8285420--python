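"""Injection operations: scope semantics, locality, provenance, burn-in."""

import numpy as np
import pytest

from deidbench import phantom_factory as pf
from deidbench.dicom_core import validate_instance, write_instance
from deidbench.font import GLYPH_H, LINE_LEADING, render_text
from deidbench.injector import (
    InjectionDirective,
    InjectionError,
    apply_annotate_img,
    apply_delete_tag,
    apply_set_tag,
    apply_shift_date,
    apply_string_replace,
    apply_substitute,
    run_plan,
)
from deidbench.tags import parse_tag


@pytest.fixture()
def small():
    """One CT patient, one study, two series, four instances."""
    row = pf.ManifestRow(
        "CT", 1, 1, 2, 4, (("CHEST", 1),), (("GE MEDICAL SYSTEMS", 1),)
    )
    ds, _ = pf.build_dataset(pf.CompositionManifest(rows=(row,)), 7, matrix=64)
    return ds


def _patient(ds):
    return next(iter(ds.patients()))


class TestSetTag:
    def test_patient_scope_consistency(self, small):
        d = InjectionDirective(
            scope="Patient", selector=_patient(small), op="set_tag",
            tag=parse_tag("(0010,0010)"),
            params={"value": "ROGERS^BILLY", "phi_spans": ["ROGERS^BILLY"]},
        )
        op = apply_set_tag(small, d)
        assert len(op.affected_instances) == 4
        values = {i.get_value(parse_tag("(0010,0010)")) for i in small}
        assert values == {"ROGERS^BILLY"}

    def test_private_tag_auto_reserves_creator_block(self, small):
        tag = parse_tag('(0009,"GEMS_PETD_01",37)')
        d = InjectionDirective(
            scope="Collection", selector="*", op="set_tag", tag=tag,
            params={"value": "batch 17", "phi_spans": ["batch 17"]},
        )
        apply_set_tag(small, d)
        for inst in small:
            assert inst.get_value(tag) == "batch 17"
            # the reservation element itself carries the creator label
            assert inst.get_value(parse_tag("(0009,0010)")) == "GEMS_PETD_01"

    def test_set_empty_leaves_zero_length_element(self, small):
        tag = parse_tag("(0010,21b0)")
        d = InjectionDirective(
            scope="Collection", selector="*", op="set_tag", tag=tag, params={"value": ""}
        )
        apply_set_tag(small, d)
        el = small.instances[0].get_element(tag)
        assert el is not None and el.value == ""

    def test_vr_violation_rejected(self, small):
        d = InjectionDirective(
            scope="Collection", selector="*", op="set_tag",
            tag=parse_tag("(0010,0030)"), params={"value": "not-a-date"},
        )
        with pytest.raises(InjectionError):
            apply_set_tag(small, d)


class TestDeleteTag:
    def test_delete_then_absent_then_idempotent(self, small):
        tag = parse_tag("(0012,0062)")
        d = InjectionDirective(scope="Collection", selector="*", op="delete_tag", tag=tag)
        op1 = apply_delete_tag(small, d)
        assert len(op1.affected_instances) == 4
        assert all(i.get_element(tag) is None for i in small)
        op2 = apply_delete_tag(small, d)
        assert op2.affected_instances == []

    def test_type1_attribute_protected(self, small):
        d = InjectionDirective(
            scope="Collection", selector="*", op="delete_tag",
            tag=parse_tag("(0008,0016)"),
        )
        with pytest.raises(InjectionError):
            apply_delete_tag(small, d)


class TestShiftDate:
    def test_plus_thirty_days(self, small):
        tag = parse_tag("(0008,0020)")
        before = small.instances[0].get_value(tag)
        d = InjectionDirective(
            scope="Collection", selector="*", op="shift_date", tag=tag,
            params={"days": 30},
        )
        op = apply_shift_date(small, d)
        assert op.before_value == before == "20200101"
        assert op.after_value == "20200131"

    def test_zero_days_unchanged_but_logged(self, small):
        tag = parse_tag("(0008,0020)")
        d = InjectionDirective(
            scope="Collection", selector="*", op="shift_date", tag=tag, params={"days": 0}
        )
        op = apply_shift_date(small, d)
        assert op.before_value == op.after_value
        assert len(op.affected_instances) == 4

    def test_study_scope_gets_identical_value_everywhere(self, small):
        study_uid = next(iter(small.studies()))
        tag = parse_tag("(0008,0020)")
        d = InjectionDirective(
            scope="Study", selector=study_uid, op="shift_date", tag=tag,
            params={"days": -7},
        )
        apply_shift_date(small, d)
        assert {i.get_value(tag) for i in small} == {"20191225"}

    def test_non_da_tag_rejected(self, small):
        d = InjectionDirective(
            scope="Collection", selector="*", op="shift_date",
            tag=parse_tag("(0010,0010)"), params={"days": 1},
        )
        with pytest.raises(InjectionError):
            apply_shift_date(small, d)


class TestSubstitute:
    def test_replaces_existing_value(self, small):
        tag = parse_tag("(0008,1010)")
        d = InjectionDirective(
            scope="Collection", selector="*", op="substitute", tag=tag,
            params={"value": "WS-PHI-01", "phi_spans": ["WS-PHI-01"]},
        )
        op = apply_substitute(small, d)
        assert len(op.affected_instances) == 4
        assert op.before_value == "STATION01"

    def test_absent_tag_everywhere_is_recorded_skip(self, small):
        tag = parse_tag("(0040,1400)")
        d = InjectionDirective(
            scope="Collection", selector="*", op="substitute", tag=tag,
            params={"value": "x"},
        )
        op = apply_substitute(small, d)
        assert op.affected_instances == []
        assert len(op.skipped_instances) == 4
        assert op.phi_spans == []


class TestStringReplace:
    def test_replacement_count_matches_substring_oracle(self, small):
        tag = parse_tag("(0008,1030)")
        value = small.instances[0].get_value(tag)
        expected = sum(i.get_value(tag).count("CONTRAST") for i in small)
        d = InjectionDirective(
            scope="Collection", selector="*", op="string_replace", tag=tag,
            params={"old": "CONTRAST", "new": "Billy Rogers CONTRAST",
                    "phi_spans": ["Billy Rogers"]},
        )
        op = apply_string_replace(small, d)
        assert op.n_replacements == expected > 0
        assert "Billy Rogers CONTRAST" in small.instances[0].get_value(tag)
        assert value.replace("CONTRAST", "Billy Rogers CONTRAST") == small.instances[0].get_value(tag)

    def test_absent_old_leaves_value_unchanged(self, small):
        tag = parse_tag("(0008,1030)")
        before = small.instances[0].get_value(tag)
        d = InjectionDirective(
            scope="Collection", selector="*", op="string_replace", tag=tag,
            params={"old": "ZZZ", "new": "YYY"},
        )
        op = apply_string_replace(small, d)
        assert op.n_replacements == 0
        assert small.instances[0].get_value(tag) == before

    def test_old_equals_new_counts_without_changing(self, small):
        tag = parse_tag("(0008,1030)")
        before = small.instances[0].get_value(tag)
        d = InjectionDirective(
            scope="Collection", selector="*", op="string_replace", tag=tag,
            params={"old": "CONTRAST", "new": "CONTRAST"},
        )
        op = apply_string_replace(small, d)
        assert op.n_replacements > 0
        assert small.instances[0].get_value(tag) == before


class TestAnnotateImg:
    def test_glyphs_at_max_value_only_inside_rect(self, small):
        inst = small.instances[0]
        before = inst.pixels.copy()
        rect = [8, 8, 30, 60]
        d = InjectionDirective(
            scope="Instance", selector=inst.instance_uid, op="annotate_img",
            params={"text": "ID 42", "rect": rect},
        )
        apply_annotate_img(small, d)
        after = inst.pixels
        r0, c0, r1, c1 = rect
        assert (after[r0:r1, c0:c1] == 0xFFFF).sum() > 0
        outside = np.ones_like(after, dtype=bool)
        outside[r0:r1, c0:c1] = False
        assert np.array_equal(after[outside], before[outside])
        # non-glyph pixels inside the rect untouched
        changed = after != before
        assert np.array_equal(after[changed], np.full(changed.sum(), 0xFFFF))

    def test_empty_text_changes_nothing_but_is_logged(self, small):
        inst = small.instances[0]
        before = inst.pixels.copy()
        d = InjectionDirective(
            scope="Instance", selector=inst.instance_uid, op="annotate_img",
            params={"text": "", "rect": [0, 0, 10, 10]},
        )
        op = apply_annotate_img(small, d)
        assert np.array_equal(inst.pixels, before)
        assert op.affected_instances == [inst.instance_uid]

    def test_multiline_lines_stack_with_fixed_leading(self):
        one = render_text("AB")
        two = render_text("AB\nCD")
        assert one.shape[0] == GLYPH_H
        assert two.shape[0] == 2 * GLYPH_H + LINE_LEADING
        assert np.array_equal(two[:GLYPH_H, : one.shape[1]], one)

    def test_rect_out_of_bounds_rejected(self, small):
        inst = small.instances[0]
        d = InjectionDirective(
            scope="Instance", selector=inst.instance_uid, op="annotate_img",
            params={"text": "A", "rect": [0, 0, 10, 999]},
        )
        with pytest.raises(InjectionError):
            apply_annotate_img(small, d)

    def test_text_too_large_for_rect_rejected(self, small):
        inst = small.instances[0]
        d = InjectionDirective(
            scope="Instance", selector=inst.instance_uid, op="annotate_img",
            params={"text": "WAY TOO LONG FOR THIS RECT", "rect": [0, 0, 8, 20]},
        )
        with pytest.raises(InjectionError):
            apply_annotate_img(small, d)


class TestRunPlan:
    def test_empty_plan_is_byte_identity(self, small):
        out, prov = run_plan(small, [])
        assert prov == []
        for a, b in zip(small, out):
            assert write_instance(a) == write_instance(b)

    def test_deterministic_for_fixed_plan(self, pipeline):
        again, _ = run_plan(pipeline.clean, pipeline.plan)
        for a, b in zip(pipeline.evaluation, again):
            assert write_instance(a) == write_instance(b)

    def test_failing_directive_reports_position(self, small):
        plan = [
            InjectionDirective(
                scope="Collection", selector="*", op="set_tag",
                tag=parse_tag("(0010,0010)"), params={"value": "X^Y"},
            ),
            InjectionDirective(
                scope="Patient", selector="NOSUCH", op="set_tag",
                tag=parse_tag("(0010,0010)"), params={"value": "X^Y"},
            ),
        ]
        with pytest.raises(InjectionError, match="directive 1"):
            run_plan(small, plan)

    def test_locality_of_header_operation(self, small):
        """A set_tag touches its target tag and nothing else."""
        tag = parse_tag("(0010,4000)")
        plan = [
            InjectionDirective(
                scope="Collection", selector="*", op="set_tag", tag=tag,
                params={"value": "note"},
            )
        ]
        out, _ = run_plan(small, plan)
        for a, b in zip(small, out):
            da = {el.tag: el.value for el in a.ds}
            db = {el.tag: el.value for el in b.ds}
            diff = {t for t in set(da) | set(db) if da.get(t) != db.get(t)}
            assert diff == {0x00104000}

    def test_t1_attributes_survive_default_plan(self, pipeline):
        for inst in pipeline.evaluation:
            assert validate_instance(inst) == []

    def test_disjoint_directives_commute(self, small):
        a = InjectionDirective(
            scope="Collection", selector="*", op="set_tag",
            tag=parse_tag("(0010,4000)"), params={"value": "one"},
        )
        b = InjectionDirective(
            scope="Collection", selector="*", op="set_tag",
            tag=parse_tag("(0008,0080)"), params={"value": "two"},
        )
        out1, _ = run_plan(small, [a, b])
        out2, _ = run_plan(small, [b, a])
        for x, y in zip(out1, out2):
            assert write_instance(x) == write_instance(y)


class TestDefaultPlan:
    def test_every_patient_gets_core_identifiers(self, pipeline):
        name_tag = parse_tag("(0010,0010)")
        id_tag = parse_tag("(0010,0020)")
        birth_tag = parse_tag("(0010,0030)")
        for clean_pid, record in pipeline.records.items():
            insts = [
                i for i in pipeline.evaluation if i.patient_id == record.patient_id
            ]
            assert insts, clean_pid
            for inst in insts:
                assert inst.get_value(name_tag) == record.patient_name
                assert inst.get_value(id_tag) == record.patient_id
                assert inst.get_value(birth_tag) == record.birth_date

    def test_all_six_operations_used(self, pipeline):
        ops = {d.op for d in pipeline.plan}
        assert ops == {
            "set_tag", "delete_tag", "shift_date", "substitute",
            "string_replace", "annotate_img",
        }

    def test_provenance_spans_exist_in_output(self, pipeline):
        for op in pipeline.provenance:
            if op.directive.op in ("set_tag", "substitute") and op.phi_spans:
                assert op.after_value is not None
                for span in op.phi_spans:
                    assert span in op.after_value
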