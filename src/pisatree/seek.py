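"""SEEK/FAIRDOMHub-style bulk upload: ignore rules, gating, planning, execution.

The remote repository links files only at the assay level, so the plan
follows the placement convention of the original tooling: a synthetic study
named ``Investigation files`` holds an assay named after the investigation
(for investigation-level files), and each study gains a synthetic assay
named after the study (for study-level files).  Per-level upload gates come
from the ``Upload to FAIRDOMHub`` metadata key (default Yes, inherited by
sublevels), sharing policy from ``Sharing permission`` (default Private)
and license from ``License``.

Planning is pure (no network).  Execution talks to any object implementing
the small :class:`SeekEndpoint` protocol; the bundled
:class:`InMemorySeekEndpoint` implements it for offline use and testing,
including idempotent re-runs via title matching within the parent container.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Union

from .errors import ConfigurationError, SeekSyncError
from .levels import LevelKind, LevelNode, load_tree, rel_to_project, resolve_chain

__all__ = [
    "IgnoreRules",
    "UploadItem",
    "UploadPlan",
    "TranscriptEntry",
    "SeekEndpoint",
    "InMemorySeekEndpoint",
    "parse_seekignore",
    "files_to_upload",
    "build_upload_plan",
    "execute_plan",
    "INVESTIGATION_FILES_STUDY",
]

INVESTIGATION_FILES_STUDY = "Investigation files"
GATE_KEY = "Upload to FAIRDOMHub"
POLICY_KEY = "Sharing permission"
LICENSE_KEY = "License"


@dataclass
class IgnoreRules:
    """Ordered glob patterns (seekignore.txt), matched on project-relative paths.

    A pattern excludes a path when it matches the path itself, any of its
    ancestor directories, or either of those at any depth (so ``output/raw``
    prunes every assay's raw directory).  There is no negation.
    """

    patterns: list[str] = field(default_factory=list)

    def matches(self, rel_path: str) -> bool:
        candidates = []
        parts = rel_path.split("/")
        for i in range(1, len(parts) + 1):
            candidates.append("/".join(parts[:i]))
        for pattern in self.patterns:
            for cand in candidates:
                if fnmatch.fnmatch(cand, pattern) or fnmatch.fnmatch(cand, f"*/{pattern}"):
                    return True
        return False


def parse_seekignore(path: Union[str, Path, None]) -> IgnoreRules:
    """Load seekignore patterns; an absent file yields empty rules."""
    rules = IgnoreRules()
    if path is None:
        return rules
    path = Path(path)
    if not path.is_file():
        return rules
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rules.patterns.append(line.replace("\\", "/").rstrip("/"))
    return rules


def _gate_open(node: LevelNode) -> bool:
    value = node.metadata.get(GATE_KEY)
    return value is None or value.strip().lower() != "no"


def _level_dir_of(path: Path, level_dirs: dict[Path, LevelNode]) -> Optional[LevelNode]:
    for candidate in [path, *path.parents]:
        if candidate in level_dirs:
            return level_dirs[candidate]
    return None


def files_to_upload(
    inv: Union[LevelNode, str, Path], rules: Optional[IgnoreRules] = None
) -> list[str]:
    """Project-relative paths of every file to upload for one investigation.

    Excludes seekignore matches and the whole subtree of any level whose
    upload gate is "No" (gates inherit downward).  Metadata files and tables
    are ordinary files and are included.
    """
    node = inv if isinstance(inv, LevelNode) else load_tree(Path(inv))
    rules = rules or IgnoreRules()
    project_root = resolve_chain(node.path)[0].path
    base = project_root.parent

    closed: set[Path] = set()
    for level in node.walk():
        if not _gate_open(level):
            closed.add(level.path)

    out: list[str] = []
    for path in sorted(node.path.rglob("*"), key=lambda p: rel_to_project(p, base)):
        if not path.is_file():
            continue
        if any(c == path or c in path.parents for c in closed):
            continue
        rel = rel_to_project(path, base)
        if rules.matches(rel):
            continue
        out.append(rel)
    return out


@dataclass(frozen=True)
class UploadItem:
    """One remote object to create: a container or a file attachment."""

    object_kind: str  # investigation | study | assay | data_file
    title: str
    attach_to: tuple[str, ...]  # container chain above this object
    local_path: Optional[str] = None  # project-relative, data_file only
    policy: str = "Private"
    license: Optional[str] = None


@dataclass
class UploadPlan:
    project_id: str
    items: list[UploadItem] = field(default_factory=list)
    synthetic_containers: list[str] = field(default_factory=list)

    @property
    def containers(self) -> list[UploadItem]:
        return [i for i in self.items if i.object_kind != "data_file"]

    @property
    def data_files(self) -> list[UploadItem]:
        return [i for i in self.items if i.object_kind == "data_file"]


def _policy_of(node: LevelNode) -> tuple[str, Optional[str]]:
    policy = (node.metadata.get(POLICY_KEY) or "Private").strip() or "Private"
    license_ = node.metadata.get(LICENSE_KEY)
    if license_ is not None and not license_.strip():
        license_ = None
    return policy, license_


def build_upload_plan(
    inv: Union[LevelNode, str, Path],
    rules: Optional[IgnoreRules] = None,
    project_id: Optional[str] = None,
) -> UploadPlan:
    """Plan the remote object set for one investigation (pure, no network).

    Containers precede everything that attaches to them; every data file
    attaches to an assay-level object, using the synthetic ``Investigation
    files`` study / per-study assays for files that live above assay level.
    """
    if not project_id:
        raise ConfigurationError(
            "a remote project id is required (create the project page first)"
        )
    node = inv if isinstance(inv, LevelNode) else load_tree(Path(inv))
    if node.kind is not LevelKind.INVESTIGATION:
        raise ConfigurationError(f"{node.dirname} is not an investigation")
    rules = rules or IgnoreRules()
    project_root = resolve_chain(node.path)[0].path
    base = project_root.parent

    files = files_to_upload(node, rules)
    plan = UploadPlan(project_id=str(project_id))

    inv_policy, inv_license = _policy_of(node)
    plan.items.append(UploadItem("investigation", node.name, (), None, inv_policy, inv_license))

    open_studies = [s for s in node.children if _gate_open(s)]
    for study in open_studies:
        policy, license_ = _policy_of(study)
        plan.items.append(UploadItem("study", study.name, (node.name,), None, policy, license_))
    plan.items.append(
        UploadItem("study", INVESTIGATION_FILES_STUDY, (node.name,), None, inv_policy, inv_license)
    )
    plan.synthetic_containers.append(INVESTIGATION_FILES_STUDY)

    # assay containers: real assays, the investigation-files assay, one per study
    assay_chain: dict[Path, tuple[str, ...]] = {}
    for study in open_studies:
        for assay in study.children:
            if not _gate_open(assay):
                continue
            policy, license_ = _policy_of(assay)
            chain = (node.name, study.name, assay.name)
            plan.items.append(UploadItem("assay", assay.name, chain[:-1], None, policy, license_))
            assay_chain[assay.path] = chain
    plan.items.append(
        UploadItem("assay", node.name, (node.name, INVESTIGATION_FILES_STUDY), None,
                   inv_policy, inv_license)
    )
    plan.synthetic_containers.append(f"{INVESTIGATION_FILES_STUDY}/{node.name}")
    study_assay_chain: dict[Path, tuple[str, ...]] = {}
    for study in open_studies:
        policy, license_ = _policy_of(study)
        chain = (node.name, study.name, study.name)
        plan.items.append(UploadItem("assay", study.name, chain[:-1], None, policy, license_))
        plan.synthetic_containers.append(f"{study.name}/{study.name}")
        study_assay_chain[study.path] = chain

    level_dirs = {lvl.path: lvl for lvl in node.walk()}
    for rel in files:
        abs_path = base / rel
        owner = _level_dir_of(abs_path.parent, level_dirs)
        if owner is None:
            continue
        policy, license_ = _policy_of(owner)
        if owner.kind is LevelKind.ASSAY and owner.path in assay_chain:
            chain = assay_chain[owner.path]
        elif owner.kind is LevelKind.STUDY:
            chain = study_assay_chain[owner.path]
        else:
            chain = (node.name, INVESTIGATION_FILES_STUDY, node.name)
        # title is the project-relative path: unique within any container,
        # which keeps title-match idempotency sound for nested subdirectories
        plan.items.append(UploadItem("data_file", rel, chain, rel, policy, license_))
    return plan


@dataclass(frozen=True)
class TranscriptEntry:
    kind: str
    title: str
    local_path: Optional[str]
    remote_id: str
    action: str  # created | exists


class SeekEndpoint(Protocol):
    """The minimal JSON-API surface the executor needs."""

    def find(self, kind: str, title: str, parent_id: Optional[str]) -> Optional[str]: ...

    def create(self, kind: str, title: str, parent_id: Optional[str], attrs: dict) -> str: ...

    def upload_blob(self, remote_id: str, local_path: str) -> None: ...


class InMemorySeekEndpoint:
    """An offline SEEK-compatible endpoint recording every call.

    Objects are stored as ``{id: {kind, title, parent, attrs}}``; titles are
    unique within a parent, which is what makes re-runs idempotent.  Set
    ``fail_after`` to make the n-th create call raise, for resumability
    tests.
    """

    def __init__(self, fail_after: Optional[int] = None):
        self.objects: dict[str, dict] = {}
        self.blobs: dict[str, str] = {}
        self.create_calls = 0
        self.fail_after = fail_after
        self._next = 1

    def find(self, kind, title, parent_id):
        for oid, obj in self.objects.items():
            if obj["kind"] == kind and obj["title"] == title and obj["parent"] == parent_id:
                return oid
        return None

    def create(self, kind, title, parent_id, attrs):
        self.create_calls += 1
        if self.fail_after is not None and self.create_calls > self.fail_after:
            raise IOError("simulated endpoint failure")
        oid = str(self._next)
        self._next += 1
        self.objects[oid] = {"kind": kind, "title": title, "parent": parent_id, "attrs": dict(attrs)}
        return oid

    def upload_blob(self, remote_id, local_path):
        self.blobs[remote_id] = local_path


def execute_plan(
    plan: UploadPlan,
    endpoint: SeekEndpoint,
    base_dir: Optional[Union[str, Path]] = None,
) -> list[TranscriptEntry]:
    """Create remote objects in plan order; returns the transcript.

    Re-running against an endpoint that already holds matching objects
    (same kind + title within the same parent) creates nothing new.  On a
    remote failure a :class:`SeekSyncError` carries the transcript of the
    steps completed so far, so the run is resumable.
    """
    transcript: list[TranscriptEntry] = []
    container_ids: dict[tuple[str, ...], str] = {(): plan.project_id}
    try:
        for item in plan.items:
            parent_id = container_ids.get(item.attach_to)
            if parent_id is None:
                raise SeekSyncError(
                    f"container {'/'.join(item.attach_to)} not created before {item.title!r}",
                    transcript,
                )
            attrs = {"policy": item.policy}
            if item.license:
                attrs["license"] = item.license
            existing = endpoint.find(item.object_kind, item.title, parent_id)
            if existing is not None:
                remote_id = existing
                action = "exists"
            else:
                remote_id = endpoint.create(item.object_kind, item.title, parent_id, attrs)
                action = "created"
                if item.object_kind == "data_file" and item.local_path:
                    local = (
                        str(Path(base_dir) / item.local_path) if base_dir else item.local_path
                    )
                    endpoint.upload_blob(remote_id, local)
            if item.object_kind != "data_file":
                container_ids[item.attach_to + (item.title,)] = remote_id
            transcript.append(
                TranscriptEntry(item.object_kind, item.title, item.local_path, remote_id, action)
            )
    except SeekSyncError:
        raise
    except Exception as exc:
        raise SeekSyncError(f"upload aborted: {exc}", transcript) from exc
    return transcript
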