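"""Template repository: assay classes/types, prompt definitions, common.ini.

The repository is a plain directory tree::

    Templates/
      x.lib/                  <Level>_Template.txt  (level prompt sets)
      DRY/                    <Type>_Template.txt   (dry-lab assay types)
      WET/                    <Type>_Template.txt   (wet-lab assay types)

Each template file is a sequence of prompt lines in the key-value dialect:
``key:<TAB>choice1/choice2`` defines a menu, an empty value a free-text
prompt, and a single slash-free value a free-text prompt with a default.
A leading ``!`` marks the key as mandatory for completeness checking.
Optional companions per type: ``<Type>_subdirs.txt`` (one relative path per
line, overriding the class-default subdirectories) and ``<Type>__<name>``
(extra file seeded into new assays under the name after the double
underscore, e.g. ``RNAisol__analytes.txt`` -> ``analytes.txt``).

Adding a new ``*_Template.txt`` file and reloading the repository makes the
type available without any code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .errors import ConfigurationError, InvalidChoiceError, TemplateError
from .levels import KeyValuePair, LevelKind, MetadataRecord, parse_metadata

__all__ = [
    "PromptSpec",
    "AssayTypeSpec",
    "TemplateRepository",
    "parse_prompt_line",
    "load_repository",
    "default_repository",
    "resolve_answers",
    "CLASS_DEFAULT_SUBDIRS",
    "LEVEL_SUBDIRS",
    "ASSAY_CLASSES",
]

ASSAY_CLASSES = ("wet", "dry")

# Default subdirectories created per level / assay class.
LEVEL_SUBDIRS: dict[LevelKind, list[str]] = {
    LevelKind.PROJECT: [],
    LevelKind.INVESTIGATION: ["reports", "presentations"],
    LevelKind.STUDY: ["reports"],
    LevelKind.ASSAY: [],  # depends on class, see below
}
CLASS_DEFAULT_SUBDIRS: dict[str, list[str]] = {
    "wet": ["output", "output/raw", "reports", "other"],
    "dry": ["input", "scripts", "output", "reports", "other"],
}


@dataclass(frozen=True)
class PromptSpec:
    """One metadata question: a key plus optional menu choices."""

    key: str
    choices: tuple[str, ...] = ()
    allows_other: bool = True
    mandatory: bool = False
    default: Optional[str] = None

    @property
    def is_free_text(self) -> bool:
        return not self.choices


@dataclass
class AssayTypeSpec:
    """A named assay template within the wet or dry class."""

    class_name: str
    type_name: str
    prompts: list[PromptSpec] = field(default_factory=list)
    subdirs: list[str] = field(default_factory=list)
    extra_files: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TemplateRepository:
    root: Path
    classes: dict[str, list[AssayTypeSpec]] = field(default_factory=dict)
    level_prompts: dict[LevelKind, list[PromptSpec]] = field(default_factory=dict)
    common_pairs: list[KeyValuePair] = field(default_factory=list)

    def types(self, class_name: str) -> list[AssayTypeSpec]:
        return self.classes.get(class_name, [])

    def find_type(self, type_name: str, class_name: Optional[str] = None) -> Optional[AssayTypeSpec]:
        pools = [class_name] if class_name else list(self.classes)
        for cls in pools:
            for spec in self.classes.get(cls, []):
                if spec.type_name == type_name:
                    return spec
        return None


def parse_prompt_line(line: str, context: str = "<template>") -> PromptSpec:
    """Parse one template line into a :class:`PromptSpec`.

    ``!`` prefix => mandatory.  Value semantics: empty => free text;
    contains ``/`` => menu (choices in order, first is the default, "other"
    escape allowed); single slash-free value => free text with default.
    """
    stripped = line.rstrip("\r\n")
    mandatory = stripped.startswith("!")
    if mandatory:
        stripped = stripped[1:]
    if "\t" not in stripped:
        raise TemplateError(f"{context}: prompt line has no tab separator: {line!r}")
    key_token, value = stripped.split("\t", 1)
    key = key_token[:-1] if key_token.endswith(":") else key_token
    if not key.strip():
        raise TemplateError(f"{context}: prompt line has empty key: {line!r}")
    value = value.strip()
    if value == "":
        return PromptSpec(key=key, mandatory=mandatory)
    if "/" in value:
        choices = tuple(c.strip() for c in value.split("/") if c.strip())
        return PromptSpec(
            key=key, choices=choices, allows_other=True,
            mandatory=mandatory, default=choices[0] if choices else None,
        )
    return PromptSpec(key=key, mandatory=mandatory, default=value)


def _parse_template_file(path: Path) -> list[PromptSpec]:
    prompts: list[PromptSpec] = []
    text = path.read_bytes().decode("utf-8")
    if text.startswith("﻿"):
        text = text[1:]
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        prompts.append(parse_prompt_line(line, context=f"{path.name}:{lineno}"))
    return prompts


_LEVEL_TEMPLATE_NAMES = {
    LevelKind.PROJECT: "Project_Template.txt",
    LevelKind.INVESTIGATION: "Investigation_Template.txt",
    LevelKind.STUDY: "Study_Template.txt",
    LevelKind.ASSAY: "Assay_Template.txt",
}


def load_repository(root: Union[str, Path]) -> TemplateRepository:
    """Load a template repository rooted at ``root`` (or at ``root/Templates``)."""
    root = Path(root)
    templates = root / "Templates" if (root / "Templates").is_dir() else root
    if not (templates / "DRY").is_dir() or not (templates / "WET").is_dir():
        raise ConfigurationError(f"{templates}: missing Templates/DRY or Templates/WET")

    repo = TemplateRepository(root=templates)
    for class_name, class_dir_name in (("dry", "DRY"), ("wet", "WET")):
        class_dir = templates / class_dir_name
        specs: list[AssayTypeSpec] = []
        for tpl in sorted(class_dir.glob("*_Template.txt")):
            type_name = tpl.name[: -len("_Template.txt")]
            if any(s.type_name == type_name for s in specs):
                raise ConfigurationError(f"duplicate assay type {type_name!r} in {class_dir_name}")
            if "-" in type_name:
                raise ConfigurationError(
                    f"assay type name {type_name!r} contains a hyphen "
                    "(reserved for the -<AssayType> dirname suffix)"
                )
            spec = AssayTypeSpec(class_name=class_name, type_name=type_name,
                                 prompts=_parse_template_file(tpl))
            subdirs_file = class_dir / f"{type_name}_subdirs.txt"
            if subdirs_file.is_file():
                spec.subdirs = [
                    ln.strip().replace("\\", "/")
                    for ln in subdirs_file.read_text(encoding="utf-8").splitlines()
                    if ln.strip()
                ]
            else:
                spec.subdirs = list(CLASS_DEFAULT_SUBDIRS[class_name])
            for extra in sorted(class_dir.glob(f"{type_name}__*")):
                target_name = extra.name.split("__", 1)[1]
                spec.extra_files.append((target_name, extra.read_text(encoding="utf-8")))
            specs.append(spec)
        repo.classes[class_name] = specs

    xlib = templates / "x.lib"
    for kind, fname in _LEVEL_TEMPLATE_NAMES.items():
        tpl = xlib / fname
        repo.level_prompts[kind] = _parse_template_file(tpl) if tpl.is_file() else []

    for ini_dir in (templates, templates.parent):
        ini = ini_dir / "common.ini"
        if ini.is_file():
            repo.common_pairs = list(parse_metadata(ini.read_text(encoding="utf-8")).pairs)
            break
    return repo


def default_repository() -> TemplateRepository:
    """The repository bundled with the package."""
    return load_repository(bundled_templates_dir())


def bundled_templates_dir() -> Path:
    from importlib import resources

    return Path(str(resources.files("pisatree").joinpath("templates_data")))


def resolve_answers(
    prompts: Sequence[PromptSpec],
    answers: Mapping[str, str],
    common: Sequence[KeyValuePair] = (),
    level: Optional[LevelKind] = None,
) -> MetadataRecord:
    """Build a metadata record from prompts, supplied answers and common pairs.

    Menu prompts require the answer to be one of the choices unless the
    ``other:<free text>`` escape is used.  Unanswered prompts fall back to
    the prompt default or an empty value (completeness checking happens
    later).  Common pairs are appended once, never overriding prompt keys.
    Deterministic: prompt order is preserved, keys are never reordered.
    """
    record = MetadataRecord(level=level)
    answered = {k.strip(): v for k, v in answers.items()}
    for prompt in prompts:
        raw = answered.get(prompt.key.strip())
        if raw is None:
            value = prompt.default if prompt.default is not None else ""
        elif prompt.choices:
            if raw in prompt.choices:
                value = raw
            elif prompt.allows_other and raw.startswith("other:"):
                value = raw[len("other:"):].strip()
            else:
                raise InvalidChoiceError(
                    f"answer {raw!r} for {prompt.key!r} is not one of "
                    f"{'/'.join(prompt.choices)} (use 'other:<text>' to override)"
                )
        else:
            value = raw[len("other:"):].strip() if raw.startswith("other:") else raw
        record.entries.append(KeyValuePair(prompt.key, value))
    prompt_keys = {p.key.strip() for p in prompts}
    for pair in common:
        if pair.key.strip() not in prompt_keys:
            record.entries.append(pair)
    return record
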