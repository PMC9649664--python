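# Methods

## Data model

A tree nests exactly four level kinds with a fixed total order:
project < Investigation < Study < Assay. On disk a level is a directory
whose basename is `<prefix><name>`, with prefixes `_p_`, `_I_`, `_S_`,
`_A_`; assay basenames additionally carry a `-<AssayType>` suffix. The
type is taken from the substring after the **last** hyphen, so assay names
may contain hyphens but type names must not (enforced when the template
repository loads). Nesting is strict: an investigation can only be created
under a project, a study under an investigation, an assay under a study,
and nothing nests under an assay. The four-level depth is a fixed property
of the model, not a configuration knob.

## Metadata dialect

Each level holds one metadata file, written as `_<LEVEL>_METADATA.TXT`
(uppercase level name) and located case-insensitively on read, since
hand-maintained trees mix case. A line is `key`, a colon, a tab, then the
value; values may be empty but must not contain tabs (a tab would be
indistinguishable from the separator, so it is rejected on write — the
files are also hand-edited, and a silent tab would corrupt the record).
Parsing is lossless: blank and malformed (tab-less) lines are retained
verbatim in the entry stream, so `write(parse(f))` reproduces the file
byte-for-byte up to the configured line terminator (LF by default; CRLF
and a UTF-8 BOM are accepted and normalised on read). Duplicate keys are
preserved and reported as warnings rather than errors; key lookup trims
surrounding whitespace on both sides and returns the first match.

Sample tables are plain TSV with a header row. The master sample table
(phenodata) and the variable-description table (featuredata) live at the
investigation level as `<role>_yyyymmdd.txt`; the filename date stamp is
treated as an opaque version ordinal and the "latest" table is the one
with the lexicographically greatest stamp. Phenodata identifiers (first
column) must be unique; featuredata and analyte tables have no such
constraint. Keeping samples at investigation level gives unique sample IDs
across all of an investigation's studies.

## Templates and prompts

The template repository is `Templates/{x.lib,DRY,WET}`. Level prompt sets
live in `x.lib/<Level>_Template.txt`; each `<Type>_Template.txt` under a
class directory defines one assay type. A prompt line uses the metadata
dialect; its value field is interpreted as:

- empty — free-text prompt;
- `a/b/c` — menu of choices in order, first choice is the default, and a
  literal `other:<text>` answer escapes the menu;
- a single slash-free value — free-text prompt with that default (this is
  how `Upload to FAIRDOMHub` defaults to `Yes` while remaining editable).

A leading `!` marks a key as mandatory for the completeness check; this
marking convention keeps each template a single editable text file.
Optional per-type companions: `<Type>_subdirs.txt` replaces the
class-default subdirectory list, and `<Type>__<name>` files seed extra
files into new assays (the bundled `RNAisol__analytes.txt` seeds
`analytes.txt`). `common.ini`, in the same dialect at the repository or
tree root, is appended once to every new level's record without
overriding prompt-derived keys. The bundled prompt sets are
representative defaults, not a canonical standard; adding a template file
and reloading is the supported extension path.

Default subdirectories: investigation `reports` + `presentations`; study
`reports`; wet assay `output`, `output/raw`, `reports`, `other`; dry assay
`input`, `scripts`, `output`, `reports`, `other`.

Scaffolding is atomic per level: the directory is assembled under a
temporary name inside the parent and renamed into place, so a failure
leaves no partial level. Existing targets are never overwritten. Names are
sanitised (spaces to `-`, charset `[A-Za-z0-9._-]`, Windows device names
rejected) — the operation is idempotent, so pre-sanitised names pass
through unchanged.

## Validation

The completeness check (`xcheck`) walks the subtree and reports, sorted by
path then key: mandatory keys whose value is empty or absent
(`missing_value`), levels without a metadata file (`missing_file`) and
metadata lines that do not parse (`malformed_line`). Problems are
findings, never exceptions, so one broken level does not hide the rest.

The path-length check measures the absolute path string of every file and
directory as it would appear under a configurable mount prefix (the
longest prefix the tree will ever be mounted under — a network-drive path
is typically longer than the local one) and flags anything over 247
characters, the limit on stock Windows installations; a path of exactly
247 passes. The check reports, it does not rename.

## ISA-Tab export

One investigation exports to `i_Investigation.txt`, one `s_<study>.txt`
per study and one `a_<study>_<assay>.txt` per assay. A flat TSV mapping
file (`<pISA key> <section> <field>` lines plus `@assay`/`@class`
directives for measurement/technology annotations) routes metadata keys
into investigation-file fields; every unmapped key becomes a
`Comment[pISA:<key>]` row in its section, so conversion is total. The
original tooling used XML mapping templates; a flat TSV carries the same
content and stays hand-editable, so no XML reader is shipped. Assay types
missing from the mapping fall back to a class-based default annotation
with a warning.

Study sample rows come from the investigation's latest phenodata: when a
`Study` column (case-insensitive) exists, rows are attributed by it
(matching the study's name or dirname); otherwise every sample attaches to
every study, with a warning — a lossless default for trees that predate
the convention. Assay tables list files under `output/raw` (wet, as Raw
Data File) or `output` (dry, as Derived Data File), one row per file with
the study's samples assigned cyclically; samples beyond the file count get
rows with an empty file cell so every sample is represented. Structural
self-validation checks required sections, referenced file names and
sample-name closure (every assay Sample Name appears in its study file,
every study source in the phenodata). Output is deterministic: re-export
of an unchanged tree is byte-identical.

## Upload planning

`seekignore.txt` holds one glob per line (`#` comments allowed), matched
against project-root-relative paths with `/` separators; a pattern
excludes a path when it matches the path, any ancestor directory, or
either at any depth, so `output/raw` prunes every assay's raw directory.
There is no negation — the simplest predictable subset of ignore-file
semantics.

The upload set for an investigation is every file under it, minus ignore
matches, minus the whole subtree of any level whose
`Upload to FAIRDOMHub` key is `No` (the gate inherits downward; absent
keys mean yes). The plan then follows the assay-level attachment
convention of the target repository: a synthetic study named
`Investigation files` containing an assay named after the investigation
receives investigation-level files, and each study gains a synthetic
assay named after itself for study-level files; real assays receive their
own files. Every item carries a sharing policy from `Sharing permission`
(default `Private`) and a license from `License` (omitted when empty).
Containers always precede their contents, and data-file item titles are
the project-relative paths, which keeps title-based matching unique.

Planning never touches the network. Execution takes any object with
`find`/`create`/`upload_blob`; re-runs are idempotent by matching kind and
title within the parent container (the remote's behaviour on re-upload is
not specified anywhere authoritative, so this package defines it), and a
failure raises with the transcript of completed steps so a run can resume.
The bundled in-memory endpoint implements the protocol for offline use and
testing; the remote project itself must already exist, since that is where
user roles and permissions are defined.

## Fixture generators

Two deterministic generators mirror published project *shapes* (never
their data): an insect-pesticide project — 3 investigations, 16 studies,
11 of them under `_I_01_LabTrials` whose feeding-trial studies hold wet
RNA-isolation assays with analyte tables — and a potato-transcriptome
project — one `_I_STRT` investigation with 4 dry-lab studies, one per
bioinformatics procedure, their assays populated with `input`/`scripts`/
`output` placeholders. A third generator produces seeded random trees of
arbitrary size with every mandatory key answered. All file contents are
short text derived from seed and relative path, and all date stamps are
fixed at `20200101`, so a given spec always yields a byte-identical tree.
These fixtures emulate tree structure, metadata completeness and file
placement; they do not emulate real measurement data, file sizes or
concurrent multi-user editing, so passing tests demonstrate structural
correctness of the tooling, not robustness against every hand-built tree
in the wild.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale trees: the two example
shapes (≤ 30 level directories), random trees of 1–3 investigations, and
1,000-record round-trip batches — the properties checked (round-trips,
closures, set algebra, threshold probes) are size-independent. Sibling
order in all reports is case-insensitive lexicographic with the raw name
as tie-break; findings sort by path then key; every generator and the
acceptance script take an explicit seed.

## Known limitations

- Values cannot contain tabs; the original dialect's behaviour for such
  values is unknown, so they are rejected rather than escaped.
- Assay type names cannot contain hyphens (dirname suffix ambiguity).
- No file/directory version control and no locking — order-keeping is a
  data-steward duty; phenodata versioning is by filename date stamp only.
- ISA-Tab export covers the investigation-file metadata and the
  sample/data-file skeleton; ontology annotations, protocols and factors
  are emitted as empty canonical sections.
- No HTTP client is bundled; execution targets the endpoint protocol, and
  wiring it to a live JSON API is left to the caller.
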