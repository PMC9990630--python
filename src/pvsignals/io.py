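"""Reading and writing FAERS-style quarterly ASCII extracts.

The FDA quarterly extract ships each quarter as a set of '$'-delimited text
tables (DEMO, DRUG, REAC, plus INDI/OUTC/RPSR/THER which we pass through
untyped).  The dialect has a single header line, no quoting and no escape
character, so an embedded '$' inside a value is unrepresentable and is
treated as a malformed line.

Legacy extracts (before 2012Q4, when the system was still called AERS) name
the report identifier ``ISR`` and the case identifier ``CASE``; a header
alias table maps those onto the modern ``primaryid``/``caseid`` names so the
same row types cover the whole 2004--2021 span.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: legacy AERS header names -> modern FAERS names
HEADER_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
}

MANDATORY_COLUMNS = {
    "demo": ("primaryid", "caseid"),
    "drug": ("primaryid", "drugname"),
    "reac": ("primaryid", "pt"),
}


class SchemaError(ValueError):
    """A mandatory column is missing from a table header."""


class ParseError(ValueError):
    """A data line cannot be parsed (wrong field count)."""


@dataclass
class DemoRow:
    """One report version from a DEMO table.

    ``primaryid`` identifies the report version, ``caseid`` the underlying
    case; several versions of one case share a caseid.  All fields are kept
    as verbatim strings; empty string means missing.
    """

    primaryid: str
    caseid: str = ""
    fda_dt: str = ""
    sex: str = ""
    age: str = ""
    age_cod: str = ""
    occp_cod: str = ""
    event_dt: str = ""
    rept_dt: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class DrugRow:
    """One drug entry. ``role_cod`` is PS/SS/C/I (or empty)."""

    primaryid: str
    drug_seq: str = ""
    role_cod: str = ""
    drugname: str = ""
    prod_ai: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class ReacRow:
    """One reaction entry; ``pt`` is a MedDRA Preferred Term."""

    primaryid: str
    pt: str = ""
    extras: dict = field(default_factory=dict)


_ROW_TYPES = {"demo": DemoRow, "drug": DrugRow, "reac": ReacRow}
_TYPED_FIELDS = {
    "demo": ("primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
             "occp_cod", "event_dt", "rept_dt"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "reac": ("primaryid", "pt"),
}


@dataclass
class ParsedTable:
    """Rows plus parse bookkeeping (no silent row loss)."""

    rows: list
    n_input: int = 0
    n_parsed: int = 0
    n_errored: int = 0
    errors: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass
class QuarterBundle:
    """One quarter's DEMO/DRUG/REAC content.

    Orphan primaryids (present in DRUG or REAC but not in DEMO) are recorded,
    never silently dropped; downstream analysis counts reports off DEMO.
    """

    quarter: str
    demo: list
    drug: list
    reac: list
    source_paths: dict = field(default_factory=dict)
    orphans: dict = field(default_factory=dict)

    def row_counts(self) -> tuple[int, int, int]:
        return len(self.demo), len(self.drug), len(self.reac)

    def find_orphans(self) -> dict:
        known = {r.primaryid for r in self.demo}
        self.orphans = {
            "drug": sorted({r.primaryid for r in self.drug} - known),
            "reac": sorted({r.primaryid for r in self.reac} - known),
        }
        return self.orphans


def read_table(path, schema: str, strict: bool = True) -> ParsedTable:
    """Read one '$'-delimited FAERS table.

    Parameters
    ----------
    path : str or Path
        File with a '$'-delimited header line.
    schema : {'demo', 'drug', 'reac'}
        Which typed row to produce.
    strict : bool
        If True (default), a malformed data line raises :class:`ParseError`
        with its line number; if False it is counted and skipped.
    """
    schema = schema.lower()
    if schema not in _ROW_TYPES:
        raise ValueError(f"unknown table schema {schema!r}")
    path = Path(path)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        columns = [HEADER_ALIASES.get(c.strip().lower(), c.strip().lower())
                   for c in header_line.split(DELIMITER)]
        for col in MANDATORY_COLUMNS[schema]:
            if col not in columns:
                raise SchemaError(
                    f"{path.name}: mandatory column {col!r} missing from "
                    f"header (found: {columns})")
        typed = _TYPED_FIELDS[schema]
        row_cls = _ROW_TYPES[schema]
        ncol = len(columns)
        result = ParsedTable(rows=[])
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            result.n_input += 1
            fields = line.split(DELIMITER)
            if len(fields) != ncol:
                result.n_errored += 1
                msg = (f"{path.name}:{lineno}: expected {ncol} fields, got "
                       f"{len(fields)} (embedded '$' is not representable)")
                result.errors.append(msg)
                if strict:
                    raise ParseError(msg)
                logger.warning(msg)
                continue
            values = dict(zip(columns, (f.strip() for f in fields)))
            kwargs = {k: values.pop(k) for k in typed if k in values}
            row = row_cls(**kwargs)
            if values:
                row.extras = values
            result.rows.append(row)
            result.n_parsed += 1
    return result


_QUARTER_RE = re.compile(r"(?:^|[^0-9])(\d{2}|\d{4})q([1-4])", re.IGNORECASE)


def _quarter_from_filename(name: str) -> str | None:
    m = _QUARTER_RE.search(Path(name).stem)
    if not m:
        return None
    year, q = m.group(1), m.group(2)
    if len(year) == 2:
        year = ("20" if int(year) < 50 else "19") + year
    return f"{year}Q{q}"


def read_quarter(directory, strict: bool = True) -> QuarterBundle:
    """Load a quarter directory containing DEMO/DRUG/REAC files.

    Files are identified case-insensitively by filename prefix (e.g.
    ``DEMO19Q2.txt``); all three are mandatory.
    """
    directory = Path(directory)
    found: dict[str, Path] = {}
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        prefix = p.name[:4].lower()
        if prefix in ("demo", "drug", "reac") and prefix not in found:
            found[prefix] = p
    missing = [k.upper() for k in ("demo", "drug", "reac") if k not in found]
    if missing:
        raise FileNotFoundError(
            f"{directory}: missing mandatory table(s) {missing}; "
            f"found files: {[p.name for p in sorted(directory.iterdir())]}")
    quarter = _quarter_from_filename(found["demo"].name) or directory.name
    bundle = QuarterBundle(
        quarter=quarter,
        demo=read_table(found["demo"], "demo", strict=strict).rows,
        drug=read_table(found["drug"], "drug", strict=strict).rows,
        reac=read_table(found["reac"], "reac", strict=strict).rows,
        source_paths={k: str(v) for k, v in found.items()},
    )
    bundle.find_orphans()
    n_orph = sum(len(v) for v in bundle.orphans.values())
    if n_orph:
        logger.warning("%s: %d orphan primaryids in DRUG/REAC without a DEMO "
                       "row", quarter, n_orph)
    return bundle


def _write_table(rows: Iterable, schema: str, path: Path) -> None:
    typed = list(_TYPED_FIELDS[schema])
    extra_keys = sorted({k for r in rows for k in r.extras})
    columns = typed + extra_keys
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(columns) + "\n")
        for r in rows:
            vals = [getattr(r, k) for k in typed]
            vals += [r.extras.get(k, "") for k in extra_keys]
            for v in vals:
                if DELIMITER in v:
                    raise ParseError(
                        f"value {v!r} contains the '$' delimiter; the FAERS "
                        "dialect has no escaping")
            fh.write(DELIMITER.join(vals) + "\n")


def write_quarter(bundle: QuarterBundle, directory) -> dict[str, str]:
    """Write a bundle as '$'-delimited DEMO/DRUG/REAC files.

    Output is byte-stable for identical input (fixed column order, rows in
    list order) and round-trips through :func:`read_quarter`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = re.match(r"(\d{4})Q([1-4])$", bundle.quarter)
    tag = f"{m.group(1)[2:]}Q{m.group(2)}" if m else bundle.quarter
    paths = {}
    for schema, rows in (("demo", bundle.demo), ("drug", bundle.drug),
                         ("reac", bundle.reac)):
        p = directory / f"{schema.upper()}{tag}.txt"
        _write_table(rows, schema, p)
        paths[schema] = str(p)
    return paths
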