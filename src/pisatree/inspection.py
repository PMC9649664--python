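"""Tree and metadata reports plus completeness and path-length checks.

``show_tree`` renders the directory tree (optionally level directories
only) and records per-level counts; ``show_metadata`` aggregates every
level's metadata into one plain-text or markdown document; ``xcheck``
reports mandatory keys with missing values and absent metadata files;
``check_path_lengths`` flags paths that would exceed the classic Windows
247-character limit.  All reports are deterministic: sibling order is
case-insensitive lexicographic and findings are sorted by path then key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .levels import (
    LevelKind,
    LevelNode,
    classify_dirname,
    find_metadata_file,
    find_project_root,
    load_tree,
    metadata_filename,
    rel_to_project,
    resolve_chain,
)
from .templates import TemplateRepository, default_repository

__all__ = [
    "TreeReport",
    "CheckFinding",
    "WINDOWS_PATH_LIMIT",
    "show_tree",
    "show_metadata",
    "xcheck_metadata",
    "check_path_lengths",
]

#: Maximum usable path length on stock Windows installations.
WINDOWS_PATH_LIMIT = 247

TREE_FILENAME = "TREE.TXT"
METADATA_FILENAMES = {"plain": "METADATA.TXT", "markdown": "METADATA.md"}
CHECK_FILENAME = "CHECK.TXT"


@dataclass
class TreeReport:
    root: LevelNode
    rendered: str
    counts: dict[LevelKind, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CheckFinding:
    """One validation problem at a path (optionally at one metadata key)."""

    path: str
    key: str
    problem: str  # missing_value | missing_file | malformed_line | path_too_long

    def __str__(self) -> str:
        detail = f" [{self.key}]" if self.key else ""
        return f"{self.problem}: {self.path}{detail}"


def _sibling_sort_key(p: Path):
    return (p.name.lower(), p.name)


def _render_dirs(directory: Path, depth: int, levels_only: bool, lines: list[str]) -> None:
    for child in sorted(directory.iterdir(), key=_sibling_sort_key):
        if not child.is_dir():
            continue
        is_level = classify_dirname(child.name) is not None
        if levels_only and not is_level:
            continue
        lines.append("    " * depth + child.name)
        _render_dirs(child, depth + 1, levels_only, lines)


def show_tree(
    start: Union[str, Path], levels_only: bool = False, write_file: bool = True
) -> TreeReport:
    """Render the project tree from its root, depth-first.

    ``levels_only`` restricts the listing to prefixed level directories.
    A ``TREE.TXT`` report is written at ``start`` unless ``write_file`` is
    false; the tree itself is never modified otherwise.
    """
    start = Path(start)
    project = find_project_root(start)
    lines = [project.name]
    _render_dirs(project, 1, levels_only, lines)
    rendered = "\n".join(lines) + "\n"

    counts = {kind: 0 for kind in LevelKind}
    for line in lines:
        cls = classify_dirname(line.strip())
        if cls is not None:
            counts[cls[0]] += 1
    report = TreeReport(root=load_tree(project), rendered=rendered, counts=counts)
    if write_file:
        (start / TREE_FILENAME).write_text(rendered, encoding="utf-8")
    return report


def show_metadata(
    start: Union[str, Path], format: str = "plain", write_file: bool = True
) -> str:
    """Concatenate every level's metadata, in tree order, under path headings.

    Markdown headings are nested by level depth (project ``#`` ... assay
    ``####``); plain format underlines each relative path heading.
    """
    if format not in METADATA_FILENAMES:
        raise ValueError(f"format must be one of {sorted(METADATA_FILENAMES)}")
    start = Path(start)
    project = find_project_root(start)
    tree = load_tree(project)
    blocks: list[str] = []

    def emit(node: LevelNode, rel: str, depth: int) -> None:
        if format == "markdown":
            blocks.append("#" * (depth + 1) + f" {rel}")
        else:
            blocks.append(rel)
            blocks.append("-" * len(rel))
        for pair in node.metadata.pairs:
            blocks.append(f"{pair.key}:\t{pair.value}")
        blocks.append("")
        for child in node.children:
            emit(child, f"{rel}/{child.dirname}", depth + 1)

    emit(tree, tree.dirname, 0)
    document = "\n".join(blocks)
    if write_file:
        (start / METADATA_FILENAMES[format]).write_text(document, encoding="utf-8")
    return document


def _mandatory_keys(node: LevelNode, templates: TemplateRepository) -> list[str]:
    prompts = list(templates.level_prompts.get(node.kind, []))
    if node.kind is LevelKind.ASSAY and node.assay_type:
        spec = templates.find_type(node.assay_type)
        if spec is not None:
            prompts += spec.prompts
    return [p.key for p in prompts if p.mandatory]


def xcheck_metadata(
    start: Union[str, Path],
    templates: Optional[TemplateRepository] = None,
    write_file: bool = False,
) -> list[CheckFinding]:
    """Report mandatory keys with empty/absent values and missing metadata files.

    Findings are sorted by path then key; an empty list means the subtree
    meets the minimum reporting template.  Problems are findings, never
    exceptions.
    """
    templates = templates or default_repository()
    start = Path(start)
    project = find_project_root(start)
    scope = start if classify_dirname(start.name) is not None else resolve_chain(start)[-1].path
    tree = load_tree(scope)

    findings: list[CheckFinding] = []
    for node in tree.walk():
        rel = rel_to_project(node.path, project.parent)
        if find_metadata_file(node.path, node.kind) is None:
            findings.append(CheckFinding(rel, metadata_filename(node.kind), "missing_file"))
            continue
        for w in node.metadata.warnings:
            if "no tab separator" in w:
                findings.append(CheckFinding(rel, w, "malformed_line"))
        for key in _mandatory_keys(node, templates):
            value = node.metadata.get(key)
            if value is None or value.strip() == "":
                findings.append(CheckFinding(rel, key, "missing_value"))
    findings.sort(key=lambda f: (f.path, f.key))
    if write_file:
        text = "".join(str(f) + "\n" for f in findings) or "OK: no findings\n"
        (start / CHECK_FILENAME).write_text(text, encoding="utf-8")
    return findings


def check_path_lengths(
    root: Union[str, Path],
    limit: int = WINDOWS_PATH_LIMIT,
    mount_prefix: Optional[str] = None,
) -> list[CheckFinding]:
    """Flag every file or directory whose full path exceeds ``limit`` characters.

    Lengths are measured on the absolute path as it would appear under
    ``mount_prefix`` (the longest prefix under which the tree will ever be
    mounted); when no prefix is given the tree's actual absolute location
    is used.  Paths of exactly ``limit`` characters pass.
    """
    root = Path(root)
    base = mount_prefix if mount_prefix is not None else str(root.resolve())
    base = base.rstrip("/\\")
    findings: list[CheckFinding] = []
    for path in sorted(root.rglob("*"), key=lambda p: str(p)):
        rel = rel_to_project(path, root)
        effective = f"{base}/{rel}"
        if len(effective) > limit:
            findings.append(CheckFinding(rel, f"length {len(effective)}", "path_too_long"))
    findings.sort(key=lambda f: (f.path, f.key))
    return findings
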