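"""The four-level tree model and the tab-delimited key-value metadata dialect.

A pISA-style tree nests one **p**roject, its **I**nvestigations, their
**S**tudies and their **A**ssays as plain directories whose basenames carry a
level prefix (``_p_``, ``_I_``, ``_S_``, ``_A_``).  Every level directory
holds one metadata file of ordered ``key:<TAB>value`` lines.  This module is
the single authority for that dialect: parsing, serialisation, directory-name
classification and upward resolution of the level chain from any path.

Design notes
------------
* Metadata files are written as ``_<LEVEL>_METADATA.TXT`` (level uppercase)
  and located case-insensitively on read, since hand-maintained trees mix
  case freely.
* Parsing is lossless: malformed lines (no tab) and blank lines are kept
  verbatim in the entry stream so ``write(parse(f))`` reproduces the file
  byte-for-byte up to the configured line terminator.
* Duplicate keys are preserved and surfaced as warnings, never errors --
  the files are meant to be editable with any text editor.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .errors import MissingKeyError, NotInTreeError, ValidationError

__all__ = [
    "LevelKind",
    "KeyValuePair",
    "RawLine",
    "MetadataRecord",
    "LevelNode",
    "parse_metadata",
    "write_metadata",
    "read_metadata_file",
    "write_metadata_file",
    "metadata_filename",
    "find_metadata_file",
    "classify_dirname",
    "resolve_chain",
    "get_meta",
]

_BOM = "﻿"


class LevelKind(enum.IntEnum):
    """The four hierarchy levels, ordered project < investigation < study < assay."""

    PROJECT = 0
    INVESTIGATION = 1
    STUDY = 2
    ASSAY = 3

    @property
    def prefix(self) -> str:
        return _PREFIXES[self]

    @property
    def successor(self) -> Optional["LevelKind"]:
        return LevelKind(self + 1) if self < LevelKind.ASSAY else None

    @property
    def label(self) -> str:
        return self.name.lower()


_PREFIXES = {
    LevelKind.PROJECT: "_p_",
    LevelKind.INVESTIGATION: "_I_",
    LevelKind.STUDY: "_S_",
    LevelKind.ASSAY: "_A_",
}
_PREFIX_TO_KIND = {v: k for k, v in _PREFIXES.items()}


def metadata_filename(kind: LevelKind) -> str:
    """Canonical metadata basename for a level, e.g. ``_STUDY_METADATA.TXT``."""
    return f"_{kind.name}_METADATA.TXT"


@dataclass(frozen=True)
class KeyValuePair:
    """One ``key:<TAB>value`` line.

    ``key`` is non-empty and contains neither tab nor newline; ``value`` may
    be empty but must not contain newline or tab (a tab would break the
    dialect, so it is rejected on write).
    """

    key: str
    value: str

    def serialise(self) -> str:
        return f"{self.key}:\t{self.value}"


@dataclass(frozen=True)
class RawLine:
    """A verbatim non-pair line (malformed or blank) kept for lossless write-back."""

    text: str


Entry = Union[KeyValuePair, RawLine]


@dataclass
class MetadataRecord:
    """Ordered metadata of one level; preserves entry order and duplicates."""

    entries: list[Entry] = field(default_factory=list)
    level: Optional[LevelKind] = None
    source_path: Optional[Path] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def pairs(self) -> list[KeyValuePair]:
        return [e for e in self.entries if isinstance(e, KeyValuePair)]

    def keys(self) -> list[str]:
        return [p.key for p in self.pairs]

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        try:
            return get_meta(self, key)
        except MissingKeyError:
            return default

    def __getitem__(self, key: str) -> str:
        return get_meta(self, key)

    def __contains__(self, key: str) -> bool:
        return self.get(key) is not None

    def set(self, key: str, value: str) -> None:
        """Replace the first pair with ``key`` (or append a new pair)."""
        for i, e in enumerate(self.entries):
            if isinstance(e, KeyValuePair) and e.key.strip() == key.strip():
                self.entries[i] = KeyValuePair(e.key, value)
                return
        self.entries.append(KeyValuePair(key, value))

    def __iter__(self) -> Iterator[KeyValuePair]:
        return iter(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetadataRecord):
            return NotImplemented
        return self.entries == other.entries


def parse_metadata(
    text: Union[str, Iterable[str]], level: Optional[LevelKind] = None
) -> MetadataRecord:
    """Parse metadata text (or an iterable of lines) into a :class:`MetadataRecord`.

    Accepts LF and CRLF endings and strips a leading UTF-8 BOM.  One pair per
    non-blank line containing a tab; the trailing colon of the key token is a
    serialisation artefact and is stripped.  Lines without a tab are recorded
    verbatim with a warning; duplicate keys are kept and flagged.
    """
    if isinstance(text, str):
        lines = text.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    record = MetadataRecord(level=level)
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if lineno == 1 and line.startswith(_BOM):
            line = line[len(_BOM):]
        if line.strip() == "":
            record.entries.append(RawLine(line))
            continue
        if "\t" not in line:
            record.entries.append(RawLine(line))
            record.warnings.append(f"line {lineno}: no tab separator: {line!r}")
            continue
        key_token, value = line.split("\t", 1)
        key = key_token[:-1] if key_token.endswith(":") else key_token
        if key == "":
            record.entries.append(RawLine(line))
            record.warnings.append(f"line {lineno}: empty key")
            continue
        norm = key.strip()
        if norm in seen:
            record.warnings.append(f"line {lineno}: duplicate key {norm!r}")
        seen.add(norm)
        record.entries.append(KeyValuePair(key, value))
    return record


def write_metadata(record: MetadataRecord, newline: str = "\n") -> str:
    """Serialise a record to text; entry order preserved, pairs as ``key:<TAB>value``."""
    out: list[str] = []
    for e in record.entries:
        if isinstance(e, KeyValuePair):
            if "\t" in e.key or "\n" in e.key or not e.key.strip():
                raise ValidationError(f"invalid metadata key: {e.key!r}")
            if "\t" in e.value or "\n" in e.value:
                raise ValidationError(
                    f"value of {e.key!r} contains a tab or newline, "
                    "which would break the key-value dialect"
                )
            out.append(e.serialise())
        else:
            out.append(e.text)
    return "".join(line + newline for line in out)


def read_metadata_file(path: Union[str, Path], level: Optional[LevelKind] = None) -> MetadataRecord:
    path = Path(path)
    try:
        text = path.read_bytes().decode("utf-8")
    except UnicodeDecodeError as exc:
        # report the 1-based line of the offending byte
        bad_line = path.read_bytes()[: exc.start].count(b"\n") + 1
        raise ValidationError(f"{path}: undecodable UTF-8 at line {bad_line}") from exc
    record = parse_metadata(text, level=level)
    record.source_path = path
    return record


def write_metadata_file(record: MetadataRecord, path: Union[str, Path], newline: str = "\n") -> None:
    Path(path).write_bytes(write_metadata(record, newline=newline).encode("utf-8"))


def find_metadata_file(level_dir: Union[str, Path], kind: LevelKind) -> Optional[Path]:
    """Locate the level's metadata file, matching the canonical name case-insensitively."""
    level_dir = Path(level_dir)
    want = metadata_filename(kind).upper()
    if not level_dir.is_dir():
        return None
    for child in sorted(level_dir.iterdir(), key=lambda p: p.name):
        if child.is_file() and child.name.upper() == want:
            return child
    return None


def get_meta(record: MetadataRecord, key: str) -> str:
    """Value of the first pair whose key equals ``key`` after trimming whitespace.

    Raises :class:`MissingKeyError` (naming key and file) when absent.
    """
    want = key.strip()
    matches = [p for p in record.pairs if p.key.strip() == want]
    if not matches:
        src = str(record.source_path) if record.source_path else None
        raise MissingKeyError(key, src)
    if len(matches) > 1:
        record.warnings.append(f"duplicate key {want!r}: returning first occurrence")
    return matches[0].value


def classify_dirname(basename: str):
    """Classify a directory basename into ``(kind, name, assay_type)`` or ``None``.

    For assays the substring after the *last* hyphen is the assay type (assay
    names may themselves contain hyphens; type names must not).  An assay
    basename without a hyphen classifies with ``assay_type=None``.  Returns
    ``None`` for anything that is not a level directory.
    """
    for prefix, kind in _PREFIX_TO_KIND.items():
        if basename.startswith(prefix):
            rest = basename[len(prefix):]
            if rest == "":
                return None
            if kind is LevelKind.ASSAY:
                if "-" in rest:
                    name, _, assay_type = rest.rpartition("-")
                    if name == "":
                        return None
                    return (kind, name, assay_type or None)
                return (kind, rest, None)
            return (kind, rest, None)
    return None


@dataclass
class LevelNode:
    """One directory in the hierarchy with its metadata and children.

    ``dirname`` is the on-disk basename; ``rel_path`` is relative to the
    directory that contains the project root, with ``/`` separators, so that
    joining chain segments reproduces filesystem paths.
    """

    kind: LevelKind
    name: str
    dirname: str
    path: Path
    metadata: MetadataRecord = field(default_factory=MetadataRecord)
    assay_type: Optional[str] = None
    children: list["LevelNode"] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def rel_path(self) -> str:
        chain = resolve_chain(self.path)
        return "/".join(n.dirname for n in chain)

    def walk(self) -> Iterator["LevelNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


def _load_node(path: Path) -> LevelNode:
    cls = classify_dirname(path.name)
    if cls is None:
        raise NotInTreeError(f"{path} is not a level directory")
    kind, name, assay_type = cls
    node = LevelNode(kind=kind, name=name, dirname=path.name, path=path, assay_type=assay_type)
    if kind is LevelKind.ASSAY and assay_type is None:
        node.warnings.append(f"assay directory {path.name!r} has no -<AssayType> suffix")
    meta_path = find_metadata_file(path, kind)
    if meta_path is not None:
        node.metadata = read_metadata_file(meta_path, level=kind)
    else:
        node.metadata = MetadataRecord(level=kind)
        node.warnings.append(f"missing metadata file in {path.name}")
    return node


def load_tree(root: Union[str, Path]) -> LevelNode:
    """Load a level directory and all its nested level descendants.

    Sibling order is case-insensitive lexicographic (deterministic reports).
    Only directories whose kind is the successor of the parent's kind become
    children; other subdirectories are data directories.
    """
    root = Path(root)
    node = _load_node(root)
    succ = node.kind.successor
    if succ is None:
        return node
    for child in sorted(root.iterdir(), key=lambda p: (p.name.lower(), p.name)):
        if not child.is_dir():
            continue
        cls = classify_dirname(child.name)
        if cls is not None and cls[0] is succ:
            node.children.append(load_tree(child))
    return node


def find_project_root(start: Union[str, Path]) -> Path:
    """Nearest ancestor (or self) whose basename carries the ``_p_`` prefix."""
    p = Path(start).resolve()
    for candidate in [p, *p.parents]:
        cls = classify_dirname(candidate.name)
        if cls is not None and cls[0] is LevelKind.PROJECT:
            return candidate
    raise NotInTreeError(f"{start} has no '_p_' project ancestor")


def resolve_chain(start: Union[str, Path]) -> list[LevelNode]:
    """Ordered chain of level nodes from the project down to ``start``.

    ``start`` may be a level directory or any path nested inside one (for
    example an assay's ``scripts`` subdirectory); the chain ends at the
    deepest enclosing level.  Metadata is loaded for every node.  The chain
    depends only on the tree's internal layout, never on where the project
    root sits on disk.
    """
    start = Path(start).resolve()
    project = find_project_root(start)
    chain_dirs = [project]
    if start != project:
        rel = start.relative_to(project)
        current = project
        for part in rel.parts:
            candidate = current / part
            if candidate.is_dir() and classify_dirname(part) is not None:
                chain_dirs.append(candidate)
                current = candidate
            else:
                break
    return [_load_node(d) for d in chain_dirs]


def rel_to_project(path: Union[str, Path], project_root: Union[str, Path]) -> str:
    """Project-root-relative path with ``/`` separators (platform-independent)."""
    rel = os.path.relpath(str(path), str(project_root))
    return rel.replace(os.sep, "/")
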