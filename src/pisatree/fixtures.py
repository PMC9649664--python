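"""Deterministic synthetic trees: the two published example shapes and random trees.

``generate_cpb_fixture`` mirrors the insect-pesticide project shape (three
investigations, 16 studies altogether, 11 of them under ``_I_01_LabTrials``,
wet RNA-isolation assays with analyte tables in the feeding-trial studies).
``generate_strt_fixture`` mirrors the potato-transcriptome project shape
(one investigation ``_I_STRT``, four studies for the four consecutive
bioinformatics procedures, dry assays only).  ``generate_random_tree``
builds arbitrary-size valid trees for property tests.

Only the published tree *shapes* are reproduced; file contents are short
deterministic placeholders derived from the seed and the relative path, and
all date stamps are fixed, so the same spec always yields a byte-identical
tree.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import PisaError
from .levels import LevelKind, LevelNode, load_tree
from .scaffold import CreationRequest, init_tree_root, make_level
from .templates import PromptSpec, TemplateRepository, load_repository

__all__ = [
    "FixtureSpec",
    "generate_cpb_fixture",
    "generate_strt_fixture",
    "generate_random_tree",
]

FIXTURE_DATE = "20200101"


@dataclass
class FixtureSpec:
    """Size parameters for a randomly shaped (but fully valid) tree."""

    seed: int = 0
    n_investigations: int = 2
    studies_per_investigation: Sequence[int] = (2, 1)
    assay_mix: Sequence[tuple[str, str, int]] = (("wet", "RNAisol", 1), ("dry", "NGS", 1))
    loose_files_per_level: int = 1


def _placeholder(seed: int, rel: str) -> str:
    tag = zlib.crc32(f"{seed}:{rel}".encode()) & 0xFFFFFFFF
    return f"placeholder {tag:08x} for {rel}\n"


def _require_empty(root: Path) -> None:
    if root.exists() and any(root.iterdir()):
        raise PisaError(f"fixture target {root} is not empty")
    root.mkdir(parents=True, exist_ok=True)


def _answers_for(prompts: Sequence[PromptSpec], **given: str) -> dict[str, str]:
    """Answer every mandatory default-less prompt so the tree passes xcheck."""
    answers = dict(given)
    for p in prompts:
        if p.mandatory and p.default is None and p.key not in answers:
            answers[p.key] = f"{p.key} (fixture)"
    return answers


def _mk(parent, kind, name, repo, *, assay_class=None, assay_type=None, **answers) -> LevelNode:
    prompts = list(repo.level_prompts.get(kind, []))
    if assay_type:
        spec = repo.find_type(assay_type, assay_class)
        if spec:
            prompts += spec.prompts
    req = CreationRequest(
        parent=Path(parent),
        kind=kind,
        name=name,
        assay_class=assay_class,
        assay_type=assay_type,
        answers=_answers_for(prompts, **answers),
        date_stamp=FIXTURE_DATE,
    )
    return make_level(req, repo)


def _seed_phenodata(inv_path: Path, rows: list[tuple[str, str, str, str]]) -> None:
    lines = ["SampleID\tStudy\tSampleName\tDescription"]
    lines += ["\t".join(r) for r in rows]
    (inv_path / f"phenodata_{FIXTURE_DATE}.txt").write_text(
        "".join(l + "\n" for l in lines), encoding="utf-8"
    )


def _repo_for(root: Path) -> TemplateRepository:
    init_tree_root(root)
    return load_repository(root)


def generate_cpb_fixture(root: Union[str, Path], seed: int = 0) -> LevelNode:
    """The Example-1 shape: 3 investigations, 16 studies, 11 under _I_01_LabTrials."""
    root = Path(root)
    _require_empty(root)
    repo = _repo_for(root)
    project = _mk(root, LevelKind.PROJECT, "CPB", repo,
                  Title="Insect pesticide development (dsRNA)")

    inv1 = _mk(project.path, LevelKind.INVESTIGATION, "01_LabTrials", repo,
               Title="Laboratory trials")
    dsrna = ["01_dsRNA-design", "02_dsRNA-production", "03_dsRNA-QC"]
    feeding = [f"{i:02d}_FeedingTrial{i - 3}" for i in range(4, 12)]
    pheno_rows = []
    for name in dsrna:
        _mk(inv1.path, LevelKind.STUDY, name, repo)
    for n, name in enumerate(feeding, start=1):
        study = _mk(inv1.path, LevelKind.STUDY, name, repo)
        assay = _mk(study.path, LevelKind.ASSAY, f"Trial{n}", repo,
                    assay_class="wet", assay_type="RNAisol")
        raw = assay.path / "output" / "raw"
        rel = f"{name}/raw_{n}.txt"
        (raw / f"raw_{n}.txt").write_text(_placeholder(seed, rel), encoding="utf-8")
        for r in range(1, 3):
            pheno_rows.append((f"CPB_{n:02d}_{r}", name, f"Trial{n}-rep{r}", "gut sample"))
    _seed_phenodata(inv1.path, pheno_rows)

    inv2 = _mk(project.path, LevelKind.INVESTIGATION, "02_FieldTrials", repo,
               Title="Field trials")
    for name in ["01_Field2019", "02_Field2020", "03_Field2021"]:
        _mk(inv2.path, LevelKind.STUDY, name, repo)
    _seed_phenodata(inv2.path, [("FLD_01", "01_Field2019", "plot-1", "field plot")])

    inv3 = _mk(project.path, LevelKind.INVESTIGATION, "03_Bioinformatics", repo,
               Title="Target identification")
    for name in ["01_TargetSelection", "02_OffTargetScreen"]:
        study = _mk(inv3.path, LevelKind.STUDY, name, repo)
        _mk(study.path, LevelKind.ASSAY, "Screen", repo, assay_class="dry", assay_type="NGS")
    _seed_phenodata(inv3.path, [("BIO_01", "01_TargetSelection", "target-set", "in silico")])
    return load_tree(project.path)


def generate_strt_fixture(root: Union[str, Path], seed: int = 0) -> LevelNode:
    """The Example-2 shape: one investigation _I_STRT with four dry-lab studies."""
    root = Path(root)
    _require_empty(root)
    repo = _repo_for(root)
    project = _mk(root, LevelKind.PROJECT, "StRT", repo,
                  Title="Potato reference transcriptomes")
    inv = _mk(project.path, LevelKind.INVESTIGATION, "STRT", repo,
              Title="Reference transcriptome assembly")
    procedures = [
        ("01_Preprocessing", "NGS"),
        ("02_DeNovoAssembly", "Ranalysis"),
        ("03_CultivarTranscriptomes", "Ranalysis"),
        ("04_PanTranscriptome", "Ranalysis"),
    ]
    pheno_rows = []
    for n, (name, assay_type) in enumerate(procedures, start=1):
        study = _mk(inv.path, LevelKind.STUDY, name, repo)
        assay = _mk(study.path, LevelKind.ASSAY, f"Step{n}", repo,
                    assay_class="dry", assay_type=assay_type)
        for sub, fname in (("input", "input.txt"), ("scripts", "run.sh"),
                           ("output", "result.txt")):
            rel = f"{name}/{sub}/{fname}"
            (assay.path / sub / fname).write_text(_placeholder(seed, rel), encoding="utf-8")
        pheno_rows.append((f"STRT_{n:02d}", name, f"cultivar-{n}", "RNA-seq library"))
    _seed_phenodata(inv.path, pheno_rows)
    return load_tree(project.path)


def generate_random_tree(
    spec: FixtureSpec, root: Union[str, Path], repo: Optional[TemplateRepository] = None
) -> LevelNode:
    """A valid tree with the sizes in ``spec``; same spec => byte-identical tree."""
    root = Path(root)
    _require_empty(root)
    rng = random.Random(spec.seed)
    repo = repo or _repo_for(root)
    project = _mk(root, LevelKind.PROJECT, f"Rand{spec.seed}", repo)

    def loose_files(level_dir: Path, rel_prefix: str) -> None:
        target = level_dir / "reports"
        if not target.is_dir():
            target = level_dir
        for i in range(spec.loose_files_per_level):
            rel = f"{rel_prefix}/file{i}.txt"
            (target / f"file{i}.txt").write_text(_placeholder(spec.seed, rel), encoding="utf-8")

    assay_pool: list[tuple[str, str]] = []
    for cls, type_name, count in spec.assay_mix:
        assay_pool += [(cls, type_name)] * count

    for i in range(spec.n_investigations):
        n_studies = (
            spec.studies_per_investigation[i % len(spec.studies_per_investigation)]
            if spec.studies_per_investigation else 0
        )
        inv = _mk(project.path, LevelKind.INVESTIGATION, f"{i + 1:02d}_Inv", repo)
        pheno_rows = []
        loose_files(inv.path, f"inv{i}")
        for j in range(n_studies):
            study = _mk(inv.path, LevelKind.STUDY, f"{j + 1:02d}_Study", repo)
            loose_files(study.path, f"inv{i}/study{j}")
            pheno_rows.append((f"S{i}_{j}", f"{j + 1:02d}_Study", f"sample-{i}-{j}", "synthetic"))
            for k, (cls, type_name) in enumerate(assay_pool):
                if rng.random() < 0.8:
                    assay = _mk(study.path, LevelKind.ASSAY, f"A{k + 1}", repo,
                                assay_class=cls, assay_type=type_name)
                    loose_files(assay.path, f"inv{i}/study{j}/assay{k}")
        _seed_phenodata(inv.path, pheno_rows)
    return load_tree(project.path)
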