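"""Tree/metadata reports, completeness checking and the path-length rule."""

import os

import pytest

from pisatree import (
    CreationRequest,
    LevelKind,
    check_path_lengths,
    classify_dirname,
    generate_strt_fixture,
    init_tree_root,
    make_level,
    parse_metadata,
    show_metadata,
    show_tree,
    xcheck_metadata,
)
from pisatree.levels import metadata_filename, read_metadata_file, write_metadata_file


@pytest.fixture
def small_tree(tmp_path, repo):
    init_tree_root(tmp_path)
    project = make_level(
        CreationRequest(tmp_path, LevelKind.PROJECT, "Mini",
                        answers={"Principal investigator": "PI"}, date_stamp="20200101"),
        repo,
    )
    inv = make_level(
        CreationRequest(project.path, LevelKind.INVESTIGATION, "01_Inv",
                        answers={"Start date": "2020-01-01"}, date_stamp="20200101"),
        repo,
    )
    study = make_level(
        CreationRequest(inv.path, LevelKind.STUDY, "01_Study", date_stamp="20200101"), repo
    )
    assay = make_level(
        CreationRequest(study.path, LevelKind.ASSAY, "A1",
                        assay_class="dry", assay_type="NGS",
                        answers={"Workflow": "wf"}),
        repo,
    )
    return project, inv, study, assay


class TestShowTree:
    def test_counts_match_independent_walk(self, cpb_tree):
        report = show_tree(cpb_tree.path, levels_only=True, write_file=False)
        walked = {kind: 0 for kind in LevelKind}
        for dirpath, dirnames, _ in os.walk(cpb_tree.path):
            for d in dirnames:
                cls = classify_dirname(d)
                if cls:
                    walked[cls[0]] += 1
        walked[LevelKind.PROJECT] += 1  # the root line itself
        assert dict(report.counts) == walked

    def test_levels_only_hides_data_dirs(self, strt_tree):
        full = show_tree(strt_tree.path, write_file=False).rendered
        levels = show_tree(strt_tree.path, levels_only=True, write_file=False).rendered
        assert "scripts" in full and "scripts" not in levels
        assert levels.count("_S_") == 4

    def test_tree_file_written_and_deterministic(self, tmp_path):
        tree = generate_strt_fixture(tmp_path / "t")
        first = show_tree(tree.path).rendered
        assert (tree.path / "TREE.TXT").read_text(encoding="utf-8") == first
        assert show_tree(tree.path).rendered == first

    def test_empty_project_single_line(self, tmp_path, repo):
        init_tree_root(tmp_path)
        project = make_level(CreationRequest(tmp_path, LevelKind.PROJECT, "Empty"), repo)
        report = show_tree(project.path, levels_only=True, write_file=False)
        assert report.rendered == "_p_Empty\n"
        assert report.counts[LevelKind.PROJECT] == 1


class TestShowMetadata:
    def test_every_pair_appears_exactly_once(self, strt_tree):
        document = show_metadata(strt_tree.path, write_file=False)
        from pisatree.levels import load_tree

        expected = []
        for node in load_tree(strt_tree.path).walk():
            expected += [(p.key, p.value) for p in node.metadata.pairs]
        doc_pairs = [
            (p.key, p.value)
            for p in parse_metadata(document).pairs
        ]
        assert sorted(doc_pairs) == sorted(expected)

    def test_headings_include_relative_paths(self, strt_tree):
        document = show_metadata(strt_tree.path, write_file=False)
        assert "_p_StRT/_I_STRT" in document
        assert "_p_StRT/_I_STRT/_S_01_Preprocessing" in document

    def test_markdown_heading_depth_follows_level(self, strt_tree):
        document = show_metadata(strt_tree.path, format="markdown", write_file=False)
        assert "# _p_StRT\n" in document
        assert "## _p_StRT/_I_STRT\n" in document
        assert "### _p_StRT/_I_STRT/_S_01_Preprocessing\n" in document

    def test_pure_except_report_file(self, tmp_path):
        tree = generate_strt_fixture(tmp_path / "t")
        before = sorted(str(p) for p in tree.path.rglob("*"))
        show_metadata(tree.path, write_file=False)
        assert sorted(str(p) for p in tree.path.rglob("*")) == before


class TestXcheck:
    def test_clean_fixture_has_no_findings(self, small_tree, repo):
        project = small_tree[0]
        assert xcheck_metadata(project.path, repo) == []

    def test_unanswered_mandatory_prompt_is_reported(self, small_tree, repo):
        _, _, study, _ = small_tree
        make_level(
            CreationRequest(study.path, LevelKind.ASSAY, "A2",
                            assay_class="dry", assay_type="NGS"),
            repo,
        )  # "Workflow" mandatory, unanswered
        findings = xcheck_metadata(study.path, repo)
        assert [(f.key, f.problem) for f in findings] == [("Workflow", "missing_value")]

    def test_deleting_metadata_file_adds_exactly_one_finding(self, small_tree, repo):
        project, inv, _, _ = small_tree
        before = xcheck_metadata(project.path, repo)
        (inv.path / metadata_filename(LevelKind.INVESTIGATION)).unlink()
        after = xcheck_metadata(project.path, repo)
        new = set(after) - set(before)
        assert len(new) == 1 and next(iter(new)).problem == "missing_file"

    def test_monotone_blanking_one_value_adds_one_finding(self, small_tree, repo):
        project, inv, _, _ = small_tree
        before = xcheck_metadata(project.path, repo)
        meta_path = inv.path / metadata_filename(LevelKind.INVESTIGATION)
        record = read_metadata_file(meta_path)
        record.set("Start date", "")
        write_metadata_file(record, meta_path)
        after = xcheck_metadata(project.path, repo)
        assert set(before) <= set(after)
        assert len(after) == len(before) + 1

    def test_findings_sorted_by_path_then_key(self, small_tree, repo):
        project, inv, study, _ = small_tree
        for meta in (inv.path / metadata_filename(LevelKind.INVESTIGATION),
                     study.path / metadata_filename(LevelKind.STUDY)):
            record = read_metadata_file(meta)
            record.set("Title", "")
            write_metadata_file(record, meta)
        findings = xcheck_metadata(project.path, repo)
        assert findings == sorted(findings, key=lambda f: (f.path, f.key))


class TestPathLengths:
    def test_threshold_at_247(self, tmp_path):
        # a file whose simulated absolute path is exactly the limit passes
        name = "f" * 20
        (tmp_path / name).write_text("x", encoding="utf-8")
        prefix_pass = "C" * (247 - len(name) - 1)
        prefix_fail = "C" * (248 - len(name) - 1)
        assert check_path_lengths(tmp_path, mount_prefix=prefix_pass) == []
        findings = check_path_lengths(tmp_path, mount_prefix=prefix_fail)
        assert [f.problem for f in findings] == ["path_too_long"]

    def test_smallest_flagged_length_is_limit_plus_one(self, tmp_path):
        (tmp_path / "g").write_text("x", encoding="utf-8")
        lengths_flagged = []
        for prefix_len in range(240, 250):
            prefix = "C" * prefix_len
            total = prefix_len + 2  # "/g"
            if check_path_lengths(tmp_path, mount_prefix=prefix):
                lengths_flagged.append(total)
        assert min(lengths_flagged) == 248

    def test_empty_tree_no_findings(self, tmp_path):
        assert check_path_lengths(tmp_path) == []

    def test_custom_limit(self, tmp_path):
        (tmp_path / "abc.txt").write_text("x", encoding="utf-8")
        # effective path "Z/abc.txt" has 9 characters: <=9 passes, <9 flags
        assert check_path_lengths(tmp_path, limit=9, mount_prefix="Z") == []
        flagged = check_path_lengths(tmp_path, limit=8, mount_prefix="Z")
        assert [f.problem for f in flagged] == ["path_too_long"]
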