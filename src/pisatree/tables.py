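"""Sample/feature/analyte tables: versioned TSV files at fixed locations.

The master sample table (*phenodata*) and the measured-variable table
(*featuredata*) live at the investigation level as ``<role>_yyyymmdd.txt``;
the date stamp in the filename is treated as an opaque version ordinal and
``latest_table`` picks the lexicographically greatest stamp.  Assay-level
analyte tables are a single fixed ``analytes.txt``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import PisaError, ValidationError

__all__ = ["SampleTable", "load_table", "save_table", "latest_table"]

_STAMPED = re.compile(r"^(phenodata|featuredata)_(\d{8})\.txt$")

ROLES = ("phenodata", "featuredata", "analytes")


@dataclass
class SampleTable:
    """A header-rowed TSV table with a role and optional filename date stamp.

    The first column holds identifiers; for phenodata these must be unique.
    All cells are kept as strings (no NA coercion) so round-trips are exact.
    """

    role: str
    data: pd.DataFrame
    date_stamp: Optional[str] = None
    source_path: Optional[Path] = None

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def identifiers(self) -> list[str]:
        return list(self.data.iloc[:, 0]) if len(self.data.columns) else []

    def __len__(self) -> int:
        return len(self.data)


def _role_and_stamp(basename: str) -> tuple[Optional[str], Optional[str]]:
    m = _STAMPED.match(basename)
    if m:
        return m.group(1), m.group(2)
    if basename == "analytes.txt":
        return "analytes", None
    return None, None


def load_table(path: Union[str, Path], role: Optional[str] = None) -> SampleTable:
    """Load a tab-separated table with a header row.

    ``role`` is inferred from the filename when omitted.  Phenodata tables
    with duplicate identifiers raise :class:`ValidationError` listing them.
    """
    path = Path(path)
    inferred, stamp = _role_and_stamp(path.name)
    role = role or inferred
    if role not in ROLES:
        raise PisaError(f"cannot infer table role from filename {path.name!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = SampleTable(role=role, data=df, date_stamp=stamp, source_path=path)
    if role == "phenodata" and len(df.columns):
        ids = table.identifiers
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(
                f"{path.name}: duplicate sample identifiers: {', '.join(dupes)}"
            )
    return table


def save_table(table: SampleTable, path: Union[str, Path]) -> None:
    table.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def latest_table(directory: Union[str, Path], role: str) -> SampleTable:
    """The table of ``role`` with the greatest ``yyyymmdd`` filename stamp.

    Analyte tables are unversioned, so for role ``analytes`` this loads the
    fixed ``analytes.txt``.
    """
    directory = Path(directory)
    if role == "analytes":
        p = directory / "analytes.txt"
        if not p.is_file():
            raise FileNotFoundError(f"no analytes.txt in {directory}")
        return load_table(p)
    candidates = sorted(
        (p for p in directory.iterdir() if _STAMPED.match(p.name) and p.name.startswith(role + "_")),
        key=lambda p: p.name,
    )
    if not candidates:
        raise FileNotFoundError(f"no {role}_yyyymmdd.txt file in {directory}")
    return load_table(candidates[-1])
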