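"""Packaged transcriptions of the published result tables.

Three tables ship with the package as TSV files transcribed verbatim from
the printed report, including locale-formatted integers ("65,243"), explicit
"NA" markers and blank cells:

* ``table1`` — the known-miRNA catalogue (member, miR/miR* sequence and
  read counts), 94 records in 40 families;
* ``table3`` — the 20 most highly conserved miRNAs with their cross-species
  conservation rates and seed read counts;
* ``table5`` — nine plant/human miRNA pairs with r-values and alignment
  patterns.

Each table is checked against an embedded manifest (SHA-256 digest and row
count) so silent corruption of a fixture surfaces as
:class:`FixtureIntegrityError` rather than a wrong number downstream.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FixtureIntegrityError

_COUNT_RE = re.compile(r"^(?:\d+|\d{1,3}(?:[.,]\d{3})+)$")

_FILES = {
    "table1": "table1_known_mirnas.tsv",
    "table3": "table3_conservation.tsv",
    "table5": "table5_mircompare.tsv",
}

# (sha256, n_rows) per table; guards the packaged transcriptions.
_MANIFEST = {
    "table1": ("bd2e58ce8556ebd060120ca7eb48bc8794e9ecb170c47379619b12b5e3ce922f", 94),
    "table3": ("8c25d60a7646b2c6567c0fa81dcb516c524954093e37591ca8427c2e35ecedf3", 20),
    "table5": ("f70f443f948138cc4d718b539e7dfcadec92f41341a508de19811b6a098df3f1", 9),
}


@dataclass
class FixtureTable:
    """A loaded fixture table with rows in printed order."""

    table_id: str
    rows: pd.DataFrame


def parse_count(cell: object) -> object:
    """Parse a printed read-count cell.

    Locale-formatted integers use "," or "." as 3-digit group separators
    ("65,243" -> 65243, "4.007" -> 4007).  "NA" and blank cells parse to
    :data:`pandas.NA` (an absent value, never zero).
    """
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return pd.NA
    text = str(cell).strip()
    if text in ("", "NA"):
        return pd.NA
    if not _COUNT_RE.match(text):
        raise FixtureIntegrityError(f"unparseable count cell: {cell!r}")
    return int(text.replace(",", "").replace(".", ""))


def _verify(path: Path, table_id: str) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected_digest, _ = _MANIFEST[table_id]
    if digest != expected_digest:
        raise FixtureIntegrityError(
            f"{table_id}: checksum mismatch (got {digest[:12]}..., "
            f"expected {expected_digest[:12]}...)"
        )


def _load(path: Path, table_id: str, verify: bool = True) -> FixtureTable:
    if verify:
        _verify(path, table_id)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _, expected_rows = _MANIFEST[table_id]
    if len(df) != expected_rows:
        raise FixtureIntegrityError(
            f"{table_id}: expected {expected_rows} rows, found {len(df)}"
        )
    if table_id == "table1":
        for col in ("mir_count", "mirstar_count"):
            df[col] = df[col].map(parse_count)
    elif table_id == "table3":
        df["conservation_rate"] = df["conservation_rate"].astype(int)
        df["read_counts"] = df["read_counts"].map(parse_count)
    elif table_id == "table5":
        df["r_value"] = df["r_value"].astype(float)
    return FixtureTable(table_id=table_id, rows=df)


def load_fixture(table_id: str) -> FixtureTable:
    """Load a packaged fixture table by id (``table1``/``table3``/``table5``)."""
    if table_id not in _FILES:
        raise KeyError(f"unknown fixture table {table_id!r}")
    with resources.as_file(
        resources.files("mirseed.data").joinpath(_FILES[table_id])
    ) as path:
        return _load(Path(path), table_id)
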