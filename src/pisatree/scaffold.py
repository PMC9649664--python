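"""Create levels on disk: project, investigation, study and assay scaffolding.

Each creation writes the prefixed directory, its metadata file (answers
resolved against the level's prompt template plus the type template for
assays, with common.ini pairs appended), and the level-appropriate
subdirectories.  Investigations additionally seed header-only phenodata and
featuredata tables; assay types may seed extra files such as ``analytes.txt``.

Creation is atomic per level: the directory is assembled under a temporary
name inside the parent and renamed into place only when complete, so a
failed request leaves no partial directory behind.
"""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Mapping, Optional, Union

from .errors import (
    AlreadyExistsError,
    ConfigurationError,
    HierarchyError,
    InvalidNameError,
    PisaError,
)
from .levels import (
    LevelKind,
    LevelNode,
    classify_dirname,
    metadata_filename,
    write_metadata_file,
)
from .templates import (
    ASSAY_CLASSES,
    LEVEL_SUBDIRS,
    TemplateRepository,
    bundled_templates_dir,
    default_repository,
    resolve_answers,
)

__all__ = ["CreationRequest", "make_level", "sanitise_name", "init_tree_root"]

# Windows-reserved device basenames are rejected for portability.
_RESERVED = {"CON", "PRN", "AUX", "NUL"} | {f"COM{i}" for i in range(1, 10)} | {
    f"LPT{i}" for i in range(1, 10)
}

_PHENODATA_HEADER = ["SampleID", "Study", "SampleName", "Description"]
_FEATUREDATA_HEADER = ["FeatureID", "Description", "Unit"]


@dataclass
class CreationRequest:
    """Everything needed to create one level directory."""

    parent: Path
    kind: LevelKind
    name: str
    assay_class: Optional[str] = None
    assay_type: Optional[str] = None
    answers: Mapping[str, str] = field(default_factory=dict)
    date_stamp: Optional[str] = None  # yyyymmdd for seeded tables; default today


def sanitise_name(raw: str) -> str:
    """Normalise a level name for use in a directory basename.

    Spaces become ``-``; characters outside ``[A-Za-z0-9._-]`` are removed;
    leading/trailing dots, spaces and hyphens are stripped.  Idempotent.
    Raises :class:`InvalidNameError` when nothing usable remains or the
    result is a Windows-reserved device name.
    """
    name = raw.replace(" ", "-")
    name = re.sub(r"[^A-Za-z0-9._-]", "", name)
    name = name.strip(".-")
    if not name:
        raise InvalidNameError(f"name {raw!r} is empty after sanitisation")
    if name.upper() in _RESERVED or name.split(".")[0].upper() in _RESERVED:
        raise InvalidNameError(f"name {name!r} is a reserved device name on Windows")
    return name


def _dirname_for(req: CreationRequest, name: str) -> str:
    if req.kind is LevelKind.ASSAY:
        return f"{LevelKind.ASSAY.prefix}{name}-{req.assay_type}"
    return f"{req.kind.prefix}{name}"


def _check_hierarchy(req: CreationRequest) -> None:
    parent_cls = classify_dirname(Path(req.parent).name)
    if req.kind is LevelKind.PROJECT:
        if parent_cls is not None:
            raise HierarchyError("a project cannot be created inside another level")
        return
    required = LevelKind(req.kind - 1)
    if parent_cls is None or parent_cls[0] is not required:
        raise HierarchyError(
            f"a {req.kind.label} must be created under a {required.label} "
            f"(parent {Path(req.parent).name!r} is not one)"
        )


def make_level(req: CreationRequest, templates: Optional[TemplateRepository] = None) -> LevelNode:
    """Create one level directory per the request; returns the new node.

    Never overwrites: an existing target raises :class:`AlreadyExistsError`
    and leaves the tree unchanged.  The strict project > investigation >
    study > assay nesting is enforced.
    """
    templates = templates or default_repository()
    name = sanitise_name(req.name)
    _check_hierarchy(req)

    type_spec = None
    if req.kind is LevelKind.ASSAY:
        if req.assay_class not in ASSAY_CLASSES or not req.assay_type:
            raise ConfigurationError("assay creation requires --class wet|dry and --type")
        type_spec = templates.find_type(req.assay_type, req.assay_class)
        if type_spec is None:
            raise ConfigurationError(
                f"unknown assay type {req.assay_type!r} in class {req.assay_class!r}"
            )
    elif req.assay_class or req.assay_type:
        raise ConfigurationError("assay class/type are only valid when creating an assay")

    parent = Path(req.parent)
    dirname = _dirname_for(req, name)
    target = parent / dirname
    if target.exists():
        raise AlreadyExistsError(f"{target} already exists; refusing to overwrite")

    prompts = list(templates.level_prompts.get(req.kind, []))
    if type_spec is not None:
        prompts += type_spec.prompts
    answers = dict(req.answers)
    answers.setdefault("Title", name)
    if req.kind is LevelKind.ASSAY:
        answers["Assay class"] = req.assay_class
    record = resolve_answers(prompts, answers, templates.common_pairs, level=req.kind)
    if req.kind is LevelKind.ASSAY and "Assay type" not in record:
        record.set("Assay type", req.assay_type)

    stamp = req.date_stamp or _date.today().strftime("%Y%m%d")

    tmp = parent / f".tmp-{dirname}"
    if tmp.exists():
        shutil.rmtree(tmp)
    try:
        tmp.mkdir(parents=True)
        write_metadata_file(record, tmp / metadata_filename(req.kind))
        subdirs = type_spec.subdirs if type_spec is not None else LEVEL_SUBDIRS[req.kind]
        for sub in subdirs:
            (tmp / Path(sub)).mkdir(parents=True, exist_ok=True)
        if req.kind is LevelKind.INVESTIGATION:
            (tmp / f"phenodata_{stamp}.txt").write_text(
                "\t".join(_PHENODATA_HEADER) + "\n", encoding="utf-8"
            )
            (tmp / f"featuredata_{stamp}.txt").write_text(
                "\t".join(_FEATUREDATA_HEADER) + "\n", encoding="utf-8"
            )
        if type_spec is not None:
            for fname, text in type_spec.extra_files:
                dest = tmp / fname
                dest.parent.mkdir(parents=True, exist_ok=True)
                dest.write_text(text, encoding="utf-8")
        tmp.rename(target)
    except Exception:
        if tmp.exists():
            shutil.rmtree(tmp, ignore_errors=True)
        raise

    record.source_path = target / metadata_filename(req.kind)
    return LevelNode(
        kind=req.kind,
        name=name,
        dirname=dirname,
        path=target,
        metadata=record,
        assay_type=req.assay_type,
    )


def init_tree_root(path: Union[str, Path]) -> tuple[Path, bool]:
    """Install the bundled Templates repository beside future projects.

    Returns ``(templates_path, created)``; a second call is a no-op.  The
    installed tree uses only relative references, so the whole root can be
    moved or copied freely afterwards.
    """
    root = Path(path)
    target = root / "Templates"
    if target.exists():
        return target, False
    if not root.is_dir():
        raise PisaError(f"{root} is not a directory")
    source = bundled_templates_dir() / "Templates"
    try:
        shutil.copytree(source, target)
    except PermissionError as exc:
        raise PisaError(f"cannot write to {root}: {exc}") from exc
    return target, True
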