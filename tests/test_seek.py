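"""Ignore rules, upload gating, plan construction and mock execution."""

import pytest

from pisatree import (
    ConfigurationError,
    InMemorySeekEndpoint,
    SeekSyncError,
    build_upload_plan,
    execute_plan,
    files_to_upload,
    generate_strt_fixture,
    parse_seekignore,
)
from pisatree.levels import load_tree, metadata_filename, read_metadata_file, rel_to_project
from pisatree.levels import LevelKind, write_metadata_file
from pisatree.seek import INVESTIGATION_FILES_STUDY, IgnoreRules


@pytest.fixture
def strt(tmp_path):
    """A private STRT copy whose metadata the tests may edit."""
    tree = generate_strt_fixture(tmp_path / "t")
    return tree, tree.children[0]


def _set_gate(level_dir, kind, value):
    meta = level_dir / metadata_filename(kind)
    record = read_metadata_file(meta)
    record.set("Upload to FAIRDOMHub", value)
    write_metadata_file(record, meta)


class TestIgnoreRules:
    def test_comments_and_blanks_skipped(self, tmp_path):
        f = tmp_path / "seekignore.txt"
        f.write_text("# comment\n\noutput/raw\n*.log\n", encoding="utf-8")
        rules = parse_seekignore(f)
        assert rules.patterns == ["output/raw", "*.log"]

    def test_absent_file_excludes_nothing(self, tmp_path):
        assert parse_seekignore(tmp_path / "missing.txt").patterns == []

    def test_directory_pattern_prunes_subtree_anywhere(self):
        rules = IgnoreRules(patterns=["output/raw"])
        assert rules.matches("_p_X/_I_Y/_S_Z/_A_W-T/output/raw/file.dat")
        assert not rules.matches("_p_X/_I_Y/_S_Z/_A_W-T/output/result.txt")

    def test_exclusion_equals_brute_force_filter(self, strt):
        tree, inv = strt
        rules = IgnoreRules(patterns=["scripts", "*.sh"])
        everything = files_to_upload(inv)
        filtered = files_to_upload(inv, rules)
        brute = [p for p in everything if not rules.matches(p)]
        assert filtered == brute
        assert any("scripts" in p for p in everything)
        assert not any("scripts" in p for p in filtered)


class TestFilesToUpload:
    def test_default_lists_every_file(self, strt):
        tree, inv = strt
        base = tree.path.parent
        expected = sorted(
            rel_to_project(p, base) for p in inv.path.rglob("*") if p.is_file()
        )
        assert files_to_upload(inv) == expected

    def test_metadata_files_included(self, strt):
        _, inv = strt
        assert any(p.endswith("_INVESTIGATION_METADATA.TXT") for p in files_to_upload(inv))

    def test_gated_study_contributes_zero_files(self, strt):
        tree, inv = strt
        study_dir = inv.path / "_S_01_Preprocessing"
        _set_gate(study_dir, LevelKind.STUDY, "No")
        files = files_to_upload(load_tree(inv.path))
        assert not any("_S_01_Preprocessing" in p for p in files)
        assert any("_S_02_DeNovoAssembly" in p for p in files)

    def test_gate_inherited_by_sublevels(self, strt):
        tree, inv = strt
        _set_gate(inv.path, LevelKind.INVESTIGATION, "No")
        assert files_to_upload(load_tree(inv.path)) == []

    def test_gate_monotonicity(self, strt):
        tree, inv = strt
        before = set(files_to_upload(inv))
        _set_gate(inv.path / "_S_03_CultivarTranscriptomes", LevelKind.STUDY, "No")
        after = set(files_to_upload(load_tree(inv.path)))
        assert after <= before


class TestBuildPlan:
    def test_container_counting_convention(self, strt):
        # 4 studies + "Investigation files"; 4 assays + 1 inv-files + 4 per-study
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        kinds = [i.object_kind for i in plan.items]
        assert kinds.count("investigation") == 1
        assert kinds.count("study") == 4 + 1
        assert kinds.count("assay") == 4 + 1 + 4

    def test_investigation_metadata_attaches_to_investigation_files_assay(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        item = next(
            i for i in plan.data_files
            if i.local_path.endswith("_INVESTIGATION_METADATA.TXT")
        )
        assert item.attach_to == (inv.name, INVESTIGATION_FILES_STUDY, inv.name)

    def test_study_metadata_attaches_to_study_named_assay(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        item = next(
            i for i in plan.data_files
            if i.local_path.endswith("_S_01_Preprocessing/" + metadata_filename(LevelKind.STUDY))
        )
        assert item.attach_to == (inv.name, "01_Preprocessing", "01_Preprocessing")

    def test_every_data_file_attaches_at_assay_depth(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        assert plan.data_files
        for item in plan.data_files:
            assert len(item.attach_to) == 3  # investigation/study/assay chain

    def test_topological_order(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        seen = {()}
        for item in plan.items:
            assert item.attach_to in seen
            if item.object_kind != "data_file":
                seen.add(item.attach_to + (item.title,))

    def test_policy_and_license_from_metadata(self, strt):
        _, inv = strt
        meta = inv.path / metadata_filename(LevelKind.INVESTIGATION)
        record = read_metadata_file(meta)
        record.set("Sharing permission", "Public")
        record.set("License", "CC BY 4.0")
        write_metadata_file(record, meta)
        plan = build_upload_plan(load_tree(inv.path), project_id="7")
        inv_item = next(i for i in plan.items if i.object_kind == "investigation")
        assert inv_item.policy == "Public" and inv_item.license == "CC BY 4.0"

    def test_default_policy_is_private(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        assert all(i.policy == "Private" for i in plan.items)

    def test_missing_project_id_rejected(self, strt):
        _, inv = strt
        with pytest.raises(ConfigurationError):
            build_upload_plan(inv, project_id=None)

    def test_plan_files_equal_files_to_upload(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        assert sorted(i.local_path for i in plan.data_files) == files_to_upload(inv)


class TestExecute:
    def test_create_call_count(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        endpoint = InMemorySeekEndpoint()
        transcript = execute_plan(plan, endpoint)
        assert endpoint.create_calls == len(plan.items)
        assert len(transcript) == len(plan.items)

    def test_private_policy_recorded_on_remote(self, strt):
        _, inv = strt
        endpoint = InMemorySeekEndpoint()
        execute_plan(build_upload_plan(inv, project_id="7"), endpoint)
        assert all(o["attrs"]["policy"] == "Private" for o in endpoint.objects.values())

    def test_transcript_completeness(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        transcript = execute_plan(plan, InMemorySeekEndpoint())
        uploaded = {t.local_path for t in transcript if t.kind == "data_file"}
        assert uploaded == set(files_to_upload(inv))
        assert all(t.remote_id for t in transcript)

    def test_rerun_is_noop(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        endpoint = InMemorySeekEndpoint()
        execute_plan(plan, endpoint)
        created = endpoint.create_calls
        second = execute_plan(plan, endpoint)
        assert endpoint.create_calls == created
        assert all(t.action == "exists" for t in second)

    def test_failure_aborts_with_partial_transcript(self, strt):
        _, inv = strt
        plan = build_upload_plan(inv, project_id="7")
        endpoint = InMemorySeekEndpoint(fail_after=5)
        with pytest.raises(SeekSyncError) as excinfo:
            execute_plan(plan, endpoint)
        assert len(excinfo.value.transcript) == 5
        # resumable: a healthy endpoint rerun completes the remaining steps
        endpoint.fail_after = None
        transcript = execute_plan(plan, endpoint)
        assert len(transcript) == len(plan.items)
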