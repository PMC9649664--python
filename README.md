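# pisatree

Standardised **p**roject / **I**nvestigation / **S**tudy / **A**ssay directory
trees for life-science research data management.

Many labs keep project data on a shared drive long before anything reaches a
public repository. `pisatree` turns that shared drive into a FAIR-friendly
record: every project is a plain directory tree whose levels follow the ISA
model (Investigation — the experimental question; Study — one coherent sample
collection; Assay — one measurement or analysis step), with each level
directory carrying a prefix (`_p_`, `_I_`, `_S_`, `_A_`) and a metadata file
of tab-delimited `key:<TAB>value` pairs filled in from editable templates.
Because everything is directories and text files, the system needs no server,
no database and no admin rights, and the whole tree can be moved or copied
freely.

The package provides, as a library and a `pisa` command line:

- **Scaffolding** — create levels with the right prefix, metadata prompts
  (with menu choices and an `other:` escape), level-appropriate
  subdirectories (wet-lab assays get `output/raw`, dry-lab assays get
  `input`/`scripts`/`output`), seeded sample tables (`phenodata_yyyymmdd.txt`,
  `featuredata_yyyymmdd.txt`) and per-type extras such as `analytes.txt`.
- **Inspection** — a deterministic tree report (`TREE.TXT`), aggregated
  metadata in plain text or markdown, a completeness check for mandatory
  keys, and a path-length check against the 247-character Windows limit.
- **ISA-Tab export** — one `i_Investigation.txt`, per-study `s_*.txt` sample
  files and per-assay `a_*.txt` files, driven by a flat mapping file;
  unmapped keys are carried as `Comment[pISA:<key>]` so nothing is dropped.
- **SEEK/FAIRDOMHub upload planning** — `seekignore.txt` glob rules,
  per-level `Upload to FAIRDOMHub` gates, `Sharing permission` / `License`
  policies, and the assay-level placement convention (a synthetic
  "Investigation files" study and per-study assays hold files that live
  above assay level). Planning is pure; execution runs against any object
  implementing the small endpoint protocol (an in-memory implementation is
  bundled).
- **Fixture generators** — deterministic example trees mirroring two
  published project shapes, and seeded random trees.

## Worked example

```bash
$ pisa demo strt --out demo/strt
demo/strt/_p_StRT
$ pisa tree --start demo/strt/_p_StRT --levels-only
_p_StRT
    _I_STRT
        _S_01_Preprocessing
            _A_Step1-NGS
        _S_02_DeNovoAssembly
            _A_Step2-Ranalysis
        _S_03_CultivarTranscriptomes
            _A_Step3-Ranalysis
        _S_04_PanTranscriptome
            _A_Step4-Ranalysis
[project: 1, investigation: 1, study: 4, assay: 4]
```

The demo reproduces the shape of a published transcriptome-assembly project:
one investigation whose four studies are the four consecutive bioinformatics
procedures, each holding one dry-lab assay. The bracketed counts are the
per-level totals from the tree report (also written to `TREE.TXT`).

```bash
$ pisa export-isatab --investigation demo/strt/_p_StRT/_I_STRT --out demo/isatab
$ pisa seek plan --investigation demo/strt/_p_StRT/_I_STRT --project-id 161 | head -9
[
  {
    "object_kind": "investigation",
    "title": "STRT",
    "attach_to": [],
    "local_path": null,
    "policy": "Private",
    "license": null
  },
```

The export writes 1 investigation + 4 study + 4 assay ISA-Tab files; the
upload plan starts with the investigation container (default sharing policy
`Private`), then studies, assays and finally every file as a `data_file`
item attached to an assay-level object.

## Documentation

See `docs/methods.md` for the data model, the metadata dialect, the
template format, export and upload conventions, and known limitations.
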