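"""Scoring: scope resolution, per-action checks, oracle/identity soundness."""

import copy

import pytest

from deidbench import answer_key as ak
from deidbench import evaluator as ev
from deidbench.answer_key import AnswerKeyEntry, Crosswalk
from deidbench.dicom_core import write_instance
from deidbench.tags import parse_tag


class TestResolveScope:
    def test_patient_selector_through_crosswalk(self, pipeline):
        record = next(iter(pipeline.records.values()))
        entry = AnswerKeyEntry(
            scope="Patient", selector=record.patient_id,
            tag=parse_tag("(0010,0010)"), tag_name="Patient's Name",
            action="text_removed", action_text=(record.patient_name,),
        )
        insts, reason = ev.resolve_scope(entry, pipeline.oracle, pipeline.xwalk)
        assert reason is None
        mapped = pipeline.xwalk.patient_map[record.patient_id]
        assert insts and all(i.patient_id == mapped for i in insts)

    def test_unknown_series_is_unresolvable(self, pipeline):
        entry = AnswerKeyEntry(
            scope="Series", selector="1.2.3.4", tag=parse_tag("(0020,000e)"),
            tag_name="Series Instance UID", action="uid_changed",
            action_text=("1.2.3.4",),
        )
        insts, reason = ev.resolve_scope(entry, pipeline.oracle, pipeline.xwalk)
        assert insts == [] and "not in UID crosswalk" in reason

    def test_instance_scope_resolves_to_single_instance(self, pipeline):
        entry = next(e for e in pipeline.key if e.scope == "Instance")
        insts, reason = ev.resolve_scope(entry, pipeline.oracle, pipeline.xwalk)
        assert reason is None and len(insts) == 1


class TestCheckEntry:
    def test_residual_text_fails_with_offending_value(self, pipeline):
        entry = next(
            e for e in pipeline.key
            if e.action == "text_removed" and e.tag == parse_tag("(0010,0010)")
        )
        insts = [i for i in pipeline.evaluation if i.patient_id == entry.selector]
        result = ev.check_entry(entry, insts)
        assert result.status == "fail"
        assert result.evidence[0]["residual"] == entry.action_text[0]

    def test_deleted_tag_satisfies_removal(self, pipeline):
        entry = next(
            e for e in pipeline.key
            if e.action == "text_removed" and e.tag == parse_tag("(0010,1040)")
        )
        insts = [i.copy() for i in pipeline.evaluation if i.patient_id == entry.selector]
        for i in insts:
            i.delete(entry.tag)
        assert ev.check_entry(entry, insts).status == "pass"

    def test_date_shift_fixed_mode(self, pipeline):
        entry = next(e for e in pipeline.key if e.action == "date_shifted")
        insts = [i.copy() for i in pipeline.evaluation if i.uids[0] == entry.selector]
        from deidbench.phi_forge import shift_date

        for i in insts:
            i.set_value(entry.tag, shift_date(entry.action_text[0], -14), vr="DA")
        pid = insts[0].patient_id
        ok = ev.check_entry(entry, insts, {"mode": "fixed", "days": {pid: -14}})
        bad = ev.check_entry(entry, insts, {"mode": "fixed", "days": {pid: -15}})
        assert ok.status == "pass" and bad.status == "fail"

    def test_case_variant_leak_still_fails_removal(self, pipeline):
        entry = next(
            e for e in pipeline.key
            if e.action == "text_removed" and e.tag == parse_tag("(0008,0080)")
        )
        insts = [i.copy() for i in pipeline.evaluation if i.uids[0] == entry.selector]
        for i in insts:
            i.set_value(entry.tag, entry.action_text[0].upper())
        assert ev.check_entry(entry, insts).status == "fail"


class TestSoundness:
    def test_oracle_scores_perfect(self, pipeline):
        report = ev.evaluate(pipeline.oracle, pipeline.key, pipeline.xwalk)
        assert report.overall_pass
        assert report.leaks == []
        assert all(r.status == "pass" for r in report.results)

    def test_identity_copy_failure_profile(self, pipeline, identity_xwalk):
        """A 'de-identifier' that changes nothing fails every removal/shift/
        remap/masking check and passes every retention check."""
        report = ev.evaluate(pipeline.evaluation, pipeline.key, identity_xwalk)
        assert not report.overall_pass
        c = report.per_action_counts
        for action in ("text_removed", "date_shifted", "uid_changed", "pixels_hidden"):
            assert c[action]["fail"] > 0 and c[action]["pass"] == 0, action
        for action in ("tag_retained", "text_retained", "text_notnull"):
            assert c[action]["pass"] > 0 and c[action]["fail"] == 0, action

    @pytest.mark.parametrize(
        "fault,expected_action",
        [
            ("keep_burnin", "pixels_hidden"),
            ("keep_dates", "date_shifted"),
            ("keep_uids", "uid_changed"),
        ],
    )
    def test_single_fault_localizes_to_one_action(self, pipeline, fault, expected_action):
        deid, xwalk = ev.build_oracle_deid(
            pipeline.evaluation, pipeline.key, seed=3, faults={fault}
        )
        report = ev.evaluate(deid, pipeline.key, xwalk)
        failing = {r.entry.action for r in report.results if r.status != "pass"}
        assert failing == {expected_action}

    def test_private_fault_localizes_to_private_tags(self, pipeline):
        deid, xwalk = ev.build_oracle_deid(
            pipeline.evaluation, pipeline.key, seed=3, faults={"keep_private"}
        )
        report = ev.evaluate(deid, pipeline.key, xwalk)
        bad = [r for r in report.results if r.status != "pass"]
        assert bad
        assert all(r.entry.action == "text_removed" for r in bad)
        assert all(r.entry.tag.is_private for r in bad)

    def test_monotonicity_removing_extra_optional_attribute(self, pipeline):
        """Deleting a non-keyed, non-mandatory attribute from a passing
        dataset cannot introduce a failure."""
        stripped = pipeline.oracle.copy()
        tag = parse_tag("(0018,0015)")  # Body Part Examined, Type 3, unkeyed
        for inst in stripped:
            inst.delete(tag)
        report = ev.evaluate(stripped, pipeline.key, pipeline.xwalk)
        assert report.overall_pass

    def test_relabeling_invariance(self, pipeline):
        """Renaming de-identified IDs/UIDs consistently in dataset and
        crosswalks leaves the outcome unchanged."""
        relabeled = pipeline.oracle.copy()
        pid_rename = {
            new: f"X{k:03d}" for k, new in enumerate(sorted(
                set(pipeline.xwalk.patient_map.values())
            ))
        }
        uid_rename = {
            new: f"7.7.{k}" for k, new in enumerate(sorted(
                set(pipeline.xwalk.uid_map.values())
            ))
        }
        for inst in relabeled:
            study, series, iuid = inst.uids
            inst.ds.PatientID = pid_rename[inst.patient_id]
            inst.ds.StudyInstanceUID = uid_rename[study]
            inst.ds.SeriesInstanceUID = uid_rename[series]
            inst.ds.SOPInstanceUID = uid_rename[iuid]
        xwalk = Crosswalk(
            patient_map={o: pid_rename[n] for o, n in pipeline.xwalk.patient_map.items()},
            uid_map={o: uid_rename[n] for o, n in pipeline.xwalk.uid_map.items()},
            date_shift_days=pipeline.xwalk.date_shift_days,
        )
        report = ev.evaluate(relabeled, pipeline.key, xwalk)
        assert report.overall_pass

    def test_evaluation_is_deterministic(self, pipeline, identity_xwalk):
        r1 = ev.evaluate(pipeline.evaluation, pipeline.key, identity_xwalk)
        r2 = ev.evaluate(pipeline.evaluation, pipeline.key, identity_xwalk)
        assert r1.per_action_counts == r2.per_action_counts
        assert r1.leaks == r2.leaks


class TestLeakScan:
    def test_clean_phantom_dataset_has_zero_hits(self, pipeline):
        corpus = ev.corpus_from_records(pipeline.records)
        assert ev.scan_leakage(pipeline.clean, corpus) == []

    def test_unmodified_evaluation_dataset_reports_every_span(self, pipeline):
        corpus = ev.corpus_from_key(pipeline.key, include_dates=True)
        leaks = ev.scan_leakage(pipeline.evaluation, corpus)
        found = {l["text"] for l in leaks}
        for entry in pipeline.key:
            if entry.action in ("text_removed", "date_shifted", "uid_changed"):
                assert any(t in found for t in entry.action_text), entry

    def test_phi_copied_into_unkeyed_tag_is_reported(self, pipeline):
        """A buggy de-identifier that copies a name into an un-keyed tag."""
        buggy = pipeline.oracle.copy()
        record = next(iter(pipeline.records.values()))
        buggy.instances[0].set_value(
            parse_tag("(0008,0081)"), record.display_name, vr="ST"
        )
        leaks = ev.scan_leakage(buggy, ev.corpus_from_key(pipeline.key))
        assert any(
            l["text"] == record.display_name and "(0008,0081)" in l["location"]
            for l in leaks
        )

    def test_pixel_rect_left_unmasked_is_reported(self, pipeline, identity_xwalk):
        checks = [
            (e.selector, e.rect(), e.action_text[1])
            for e in pipeline.key
            if e.action == "pixels_hidden"
        ]
        leaks = ev.scan_leakage(pipeline.evaluation, [], pixel_checks=checks)
        assert len(leaks) == len(checks) > 0


class TestSummarize:
    def test_counts_sum_to_key_length(self, pipeline):
        report = ev.evaluate(pipeline.oracle, pipeline.key, pipeline.xwalk)
        total = sum(
            sum(bucket.values()) for bucket in report.per_action_counts.values()
        )
        assert total == len(pipeline.key)

    def test_single_fail_clears_overall_pass(self, pipeline):
        report = ev.evaluate(pipeline.oracle, pipeline.key, pipeline.xwalk)
        results = list(report.results)
        bad = copy.deepcopy(results[0])
        bad.status = "fail"
        bad.evidence = [{"problem": "synthetic"}]
        tweaked = ev.summarize([bad] + results[1:], [])
        assert not tweaked.overall_pass

    def test_unresolvable_distinct_from_fail(self, pipeline):
        xwalk = Crosswalk(patient_map={}, uid_map=dict(pipeline.xwalk.uid_map),
                          date_shift_days=pipeline.xwalk.date_shift_days)
        report = ev.evaluate(pipeline.oracle, pipeline.key, xwalk)
        patient_entries = [
            r for r in report.results if r.entry.scope == "Patient"
        ]
        assert patient_entries
        assert all(r.status == "unresolvable" for r in patient_entries)
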