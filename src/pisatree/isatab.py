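"""Conversion of one investigation to an ISA-Tab file set.

An export produces exactly one ``i_Investigation.txt``, one ``s_<study>.txt``
per study and one ``a_<study>_<assay>.txt`` per assay.  Which pISA metadata
key lands in which ISA-Tab investigation-file field is driven by a flat
tab-separated mapping file (a bundled default ships with the package);
every unmapped key is carried into a ``Comment[pISA:<key>]`` row so the
conversion is lossless.  Study sample tables derive from the investigation's
master phenodata table: rows are attributed to studies by a ``Study`` column
when present, otherwise every sample attaches to every study (with a
warning).  Assay tables enumerate the files under ``output/raw`` (wet) as
Raw Data File entries or under ``output`` (dry) as Derived Data File
entries, pairing them cyclically with the study's samples.

Structural self-validation replaces an external validator: required
sections, referenced file names and sample-name closure are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .errors import ConfigurationError, ExportError
from .levels import LevelKind, LevelNode, rel_to_project
from .tables import SampleTable

__all__ = [
    "MappingSpec",
    "IsaTabDocument",
    "StudyBlock",
    "AssayTable",
    "load_mapping",
    "default_mapping",
    "build_isatab",
    "write_isatab",
    "read_isatab",
    "validate_isatab_structure",
]

INVESTIGATION_SECTIONS = (
    "ONTOLOGY SOURCE REFERENCE",
    "INVESTIGATION",
    "INVESTIGATION PUBLICATIONS",
    "INVESTIGATION CONTACTS",
)
STUDY_SECTIONS = (
    "STUDY",
    "STUDY DESIGN DESCRIPTORS",
    "STUDY PUBLICATIONS",
    "STUDY FACTORS",
    "STUDY ASSAYS",
    "STUDY PROTOCOLS",
    "STUDY CONTACTS",
)
_ALL_SECTIONS = set(INVESTIGATION_SECTIONS) | set(STUDY_SECTIONS)

# canonical field labels always emitted, even when empty
_INVESTIGATION_FIELDS = (
    "Investigation Identifier",
    "Investigation Title",
    "Investigation Description",
    "Investigation Submission Date",
    "Investigation Public Release Date",
)
_STUDY_FIELDS = (
    "Study Identifier",
    "Study Title",
    "Study Description",
    "Study Submission Date",
    "Study Public Release Date",
    "Study File Name",
)
_ONTOLOGY_FIELDS = (
    "Term Source Name",
    "Term Source File",
    "Term Source Version",
    "Term Source Description",
)


@dataclass
class MappingSpec:
    """pISA-key -> ISA-Tab field mapping plus per-assay-type ISA annotations."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    assay_config: dict[str, tuple[str, str]] = field(default_factory=dict)
    class_defaults: dict[str, tuple[str, str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def field_for(self, pisa_key: str, scope: str) -> Optional[tuple[str, str]]:
        """Mapped (section, field) of a key within scope 'INVESTIGATION' or 'STUDY'."""
        for key, section, fld in self.entries:
            if key.strip() == pisa_key.strip() and section.startswith(scope):
                return section, fld
        return None

    def assay_annotation(self, assay_type: Optional[str], class_name: str) -> tuple[str, str]:
        if assay_type and assay_type in self.assay_config:
            return self.assay_config[assay_type]
        default = self.class_defaults.get(
            class_name, ("data collection", "unknown technology")
        )
        self.warnings.append(
            f"assay type {assay_type!r} not in mapping; using class default {default}"
        )
        return default


def load_mapping(path: Union[str, Path]) -> MappingSpec:
    """Parse a flat TSV mapping file.

    Plain lines: ``<pisa key>\t<section>\t<field>``.  Directive lines:
    ``@assay\t<type>\t<measurement>\t<technology>`` and
    ``@class\t<wet|dry>\t<measurement>\t<technology>``.
    """
    spec = MappingSpec()
    path = Path(path)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "@assay":
            if len(parts) != 4:
                raise ConfigurationError(f"{path.name}:{lineno}: @assay needs 3 fields")
            spec.assay_config[parts[1]] = (parts[2], parts[3])
        elif parts[0] == "@class":
            if len(parts) != 4:
                raise ConfigurationError(f"{path.name}:{lineno}: @class needs 3 fields")
            spec.class_defaults[parts[1]] = (parts[2], parts[3])
        else:
            if len(parts) != 3:
                raise ConfigurationError(
                    f"{path.name}:{lineno}: expected <key>\\t<section>\\t<field>"
                )
            key, section, fld = parts
            if section not in _ALL_SECTIONS:
                raise ConfigurationError(
                    f"{path.name}:{lineno}: unknown ISA-Tab section {section!r}"
                )
            spec.entries.append((key, section, fld))
    return spec


def default_mapping() -> MappingSpec:
    from importlib import resources

    return load_mapping(Path(str(resources.files("pisatree").joinpath(
        "templates_data", "isatab_mapping.tsv"))))


@dataclass
class AssayTable:
    name: str
    file_name: str
    measurement_type: str
    technology_type: str
    header: list[str] = field(default_factory=list)
    rows: list[list[str]] = field(default_factory=list)


@dataclass
class StudyBlock:
    name: str
    file_name: str
    fields: list[tuple[str, str]] = field(default_factory=list)  # (section\x00label, value)
    sample_header: list[str] = field(default_factory=list)
    sample_rows: list[list[str]] = field(default_factory=list)
    assays: list[AssayTable] = field(default_factory=list)


@dataclass
class IsaTabDocument:
    investigation_fields: list[tuple[str, str]] = field(default_factory=list)
    studies: list[StudyBlock] = field(default_factory=list)
    source_identifiers: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:  # warnings are advisory, not content
        if not isinstance(other, IsaTabDocument):
            return NotImplemented
        return (
            self.investigation_fields == other.investigation_fields
            and self.studies == other.studies
            and self.source_identifiers == other.source_identifiers
        )


def _sec(section: str, label: str) -> str:
    return f"{section}\x00{label}"


def _study_column(columns: list[str]) -> Optional[str]:
    for col in columns:
        if col.strip().lower() == "study":
            return col
    return None


def _map_record(pairs, mapping: MappingSpec, scope: str) -> tuple[dict, list[tuple[str, str]]]:
    mapped: dict[str, str] = {}
    comments: list[tuple[str, str]] = []
    for pair in pairs:
        hit = mapping.field_for(pair.key, scope)
        if hit is not None:
            mapped[_sec(*hit)] = pair.value
        else:
            comments.append((f"Comment[pISA:{pair.key.strip()}]", pair.value))
    return mapped, comments


def _data_files(assay: LevelNode) -> tuple[str, list[str]]:
    """(data-file column label, relative file paths) for one assay node."""
    cls = (assay.metadata.get("Assay class") or "").strip().lower()
    wet = cls == "wet" or (cls == "" and (assay.path / "output" / "raw").is_dir())
    sub = assay.path / "output" / "raw" if wet else assay.path / "output"
    label = "Raw Data File" if wet else "Derived Data File"
    files: list[str] = []
    if sub.is_dir():
        files = sorted(
            rel_to_project(p, assay.path)
            for p in sub.rglob("*")
            if p.is_file()
        )
    return label, files


def build_isatab(
    inv: LevelNode,
    phenodata: SampleTable,
    mapping: Optional[MappingSpec] = None,
    project_metadata=None,
) -> IsaTabDocument:
    """Build the ISA-Tab document for one investigation.

    ``project_metadata`` (the enclosing project's record) contributes to the
    investigation file alongside the investigation's own metadata.
    """
    if inv.kind is not LevelKind.INVESTIGATION:
        raise ExportError(f"{inv.dirname} is not an investigation")
    if phenodata is None:
        raise ExportError("investigation has no phenodata table; cannot export")
    mapping = mapping or default_mapping()

    doc = IsaTabDocument()
    pairs = list(project_metadata.pairs) if project_metadata is not None else []
    pairs += list(inv.metadata.pairs)
    mapped, comments = _map_record(pairs, mapping, "INVESTIGATION")

    fields: list[tuple[str, str]] = []
    for label in _ONTOLOGY_FIELDS:
        fields.append((_sec("ONTOLOGY SOURCE REFERENCE", label), ""))
    inv_fields = dict.fromkeys(_INVESTIGATION_FIELDS, "")
    inv_fields["Investigation Identifier"] = inv.name
    for key, value in mapped.items():
        section, label = key.split("\x00")
        if section == "INVESTIGATION" and label in inv_fields:
            inv_fields[label] = value
        else:
            fields.append((key, value))
    for label, value in inv_fields.items():
        fields.append((_sec("INVESTIGATION", label), value))
    for label, value in comments:
        fields.append((_sec("INVESTIGATION", label), value))
    fields.sort(key=lambda kv: (_section_rank(kv[0]),))
    doc.investigation_fields = fields

    ids = phenodata.identifiers
    doc.source_identifiers = list(ids)
    study_col = _study_column(phenodata.columns)
    other_cols = [
        c for c in phenodata.columns[1:] if study_col is None or c != study_col
    ]

    for study in inv.children:
        s_file = f"s_{study.name}.txt"
        block = StudyBlock(name=study.name, file_name=s_file)
        s_mapped, s_comments = _map_record(study.metadata.pairs, mapping, "STUDY")
        study_fields = dict.fromkeys(_STUDY_FIELDS, "")
        study_fields["Study Identifier"] = study.name
        study_fields["Study Title"] = study.metadata.get("Title") or study.name
        study_fields["Study File Name"] = s_file
        for key, value in s_mapped.items():
            section, label = key.split("\x00")
            if section == "STUDY" and label in study_fields:
                if label not in ("Study Identifier", "Study File Name"):
                    study_fields[label] = value
            else:
                block.fields.append((key, value))
        for label, value in study_fields.items():
            block.fields.append((_sec("STUDY", label), value))
        for label, value in s_comments:
            block.fields.append((_sec("STUDY", label), value))
        block.fields.sort(key=lambda kv: (_section_rank(kv[0]),))

        if study_col is not None:
            df = phenodata.data
            keep = df[df[study_col].astype(str).str.strip().isin({study.name, study.dirname})]
        else:
            keep = phenodata.data
            doc.warnings.append(
                f"phenodata has no Study column; attaching all samples to {study.name!r}"
            )
        block.sample_header = ["Source Name", "Sample Name"] + [
            f"Comment[{c}]" for c in other_cols
        ]
        for _, row in keep.iterrows():
            ident = str(row.iloc[0])
            block.sample_rows.append(
                [ident, ident] + [str(row[c]) for c in other_cols]
            )
        sample_names = [r[1] for r in block.sample_rows]

        for assay in study.children:
            cls = (assay.metadata.get("Assay class") or "").strip().lower() or "dry"
            measurement, technology = mapping.assay_annotation(assay.assay_type, cls)
            label, files = _data_files(assay)
            a_name = assay.dirname[len("_A_"):]
            table = AssayTable(
                name=a_name,
                file_name=f"a_{study.name}_{a_name}.txt",
                measurement_type=measurement,
                technology_type=technology,
                header=["Sample Name", label],
            )
            if files:
                for i, f in enumerate(files):
                    sample = sample_names[i % len(sample_names)] if sample_names else ""
                    table.rows.append([sample, f])
                for j in range(len(files), len(sample_names)):
                    table.rows.append([sample_names[j], ""])
            else:
                for sample in sample_names:
                    table.rows.append([sample, ""])
            block.assays.append(table)
        doc.studies.append(block)
    doc.warnings.extend(mapping.warnings)
    return doc


_SECTION_ORDER = {name: i for i, name in enumerate(INVESTIGATION_SECTIONS + STUDY_SECTIONS)}


def _section_rank(key: str) -> int:
    return _SECTION_ORDER[key.split("\x00")[0]]


def write_isatab(doc: IsaTabDocument, outdir: Union[str, Path]) -> list[Path]:
    """Write i_/s_/a_ files; returns the paths written (deterministic order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    lines: list[str] = []

    def emit_fields(fields: list[tuple[str, str]], study: Optional[StudyBlock]) -> None:
        current = None
        for key, value in fields:
            section, label = key.split("\x00")
            if section != current:
                lines.append(section)
                current = section
            lines.append(f"{label}\t{value}")
        if study is not None:
            lines.append("STUDY ASSAYS")
            lines.append(
                "Study Assay File Name\t" + "\t".join(a.file_name for a in study.assays)
            )
            lines.append(
                "Study Assay Measurement Type\t"
                + "\t".join(a.measurement_type for a in study.assays)
            )
            lines.append(
                "Study Assay Technology Type\t"
                + "\t".join(a.technology_type for a in study.assays)
            )

    emit_fields(doc.investigation_fields, None)
    for study in doc.studies:
        emit_fields(study.fields, study)
    i_path = outdir / "i_Investigation.txt"
    i_path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    written.append(i_path)

    for study in doc.studies:
        s_path = outdir / study.file_name
        s_lines = ["\t".join(study.sample_header)]
        s_lines += ["\t".join(r) for r in study.sample_rows]
        s_path.write_text("".join(l + "\n" for l in s_lines), encoding="utf-8")
        written.append(s_path)
        for assay in study.assays:
            a_path = outdir / assay.file_name
            a_lines = ["\t".join(assay.header)] + ["\t".join(r) for r in assay.rows]
            a_path.write_text("".join(l + "\n" for l in a_lines), encoding="utf-8")
            written.append(a_path)
    return written


def read_isatab(outdir: Union[str, Path]) -> IsaTabDocument:
    """Re-parse an exported file set into an equal :class:`IsaTabDocument`."""
    outdir = Path(outdir)
    doc = IsaTabDocument()
    lines = (outdir / "i_Investigation.txt").read_text(encoding="utf-8").splitlines()
    section = None
    current: Optional[StudyBlock] = None
    assay_meta: dict[str, list[str]] = {}

    def flush_assays(block: StudyBlock, meta: dict[str, list[str]]) -> None:
        names = meta.get("Study Assay File Name", [])
        meas = meta.get("Study Assay Measurement Type", [])
        tech = meta.get("Study Assay Technology Type", [])
        for i, fname in enumerate(names):
            if not fname:
                continue
            a_lines = (outdir / fname).read_text(encoding="utf-8").splitlines()
            stem = fname[len("a_"):-len(".txt")]
            if block.name and stem.startswith(block.name + "_"):
                stem = stem[len(block.name) + 1:]
            table = AssayTable(
                name=stem,
                file_name=fname,
                measurement_type=meas[i] if i < len(meas) else "",
                technology_type=tech[i] if i < len(tech) else "",
                header=a_lines[0].split("\t") if a_lines else [],
                rows=[l.split("\t") for l in a_lines[1:]],
            )
            block.assays.append(table)

    for line in lines:
        if line in _ALL_SECTIONS and "\t" not in line:
            if line == "STUDY":
                if current is not None:
                    flush_assays(current, assay_meta)
                current = StudyBlock(name="", file_name="")
                doc.studies.append(current)
                assay_meta = {}
            section = line
            continue
        label, *values = line.split("\t")
        value = values[0] if values else ""
        if section == "STUDY ASSAYS" and label.startswith("Study Assay"):
            assay_meta[label] = values
            continue
        target = doc.investigation_fields if current is None else current.fields
        target.append((_sec(section, label), value))
        if current is not None and label == "Study Identifier":
            current.name = value
        if current is not None and label == "Study File Name":
            current.file_name = value
    if current is not None:
        flush_assays(current, assay_meta)

    for study in doc.studies:
        s_lines = (outdir / study.file_name).read_text(encoding="utf-8").splitlines()
        study.sample_header = s_lines[0].split("\t") if s_lines else []
        study.sample_rows = [l.split("\t") for l in s_lines[1:]]
        if not study.name:
            study.name = study.file_name[len("s_"):-len(".txt")]
    # source identifiers are not serialised; recover them from the samples
    seen: list[str] = []
    for study in doc.studies:
        for row in study.sample_rows:
            if row and row[0] not in seen:
                seen.append(row[0])
    doc.source_identifiers = seen
    return doc


def validate_isatab_structure(doc: IsaTabDocument) -> list[str]:
    """Structural findings: required sections, file references, name closure."""
    findings: list[str] = []
    sections = {k.split("\x00")[0] for k, _ in doc.investigation_fields}
    for required in ("ONTOLOGY SOURCE REFERENCE", "INVESTIGATION"):
        if required not in sections:
            findings.append(f"missing required section {required}")
    file_names = {s.file_name for s in doc.studies}
    for study in doc.studies:
        declared = dict(study.fields).get(_sec("STUDY", "Study File Name"), study.file_name)
        if declared not in file_names:
            findings.append(f"study file {declared} not present in document")
        sample_names = {r[1] for r in study.sample_rows if len(r) > 1}
        sources = {r[0] for r in study.sample_rows if r}
        known = set(doc.source_identifiers)
        for src in sorted(sources - known):
            findings.append(f"study {study.name}: source {src!r} not in phenodata")
        for assay in study.assays:
            for row in assay.rows:
                if row and row[0] and row[0] not in sample_names:
                    findings.append(
                        f"assay {assay.file_name}: dangling Sample Name {row[0]!r}"
                    )
    return findings
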