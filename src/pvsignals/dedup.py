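"""Case-level deduplication of report versions.

FAERS stores every transmitted version of a safety report; one case
(``caseid``) can appear as several report versions (``primaryid``).  The
FDA-recommended reduction keeps, per case, the version with the latest
``fda_dt`` (date FDA received it), breaking ties on the higher
``primaryid``.  Counting is then report-based on the surviving rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .io import DemoRow

logger = logging.getLogger(__name__)

RULE_SINGLETON = "singleton"
RULE_LATEST_DATE = "latest-date"
RULE_HIGHER_PRIMARYID = "higher-primaryid"


@dataclass
class DedupResult:
    kept: set
    dropped: set
    n_cases: int
    #: caseid -> (kept primaryid, rule applied)
    audit: dict = field(default_factory=dict)
    kept_rows: list = field(default_factory=list)


def _pid_key(primaryid: str):
    # "higher PRIMARYID" is numeric; ids that are not purely numeric after
    # digit-stripping fall back to lexicographic order and sort below any
    # numeric id.
    digits = "".join(ch for ch in primaryid if ch.isdigit())
    if digits:
        return (1, int(digits), primaryid)
    logger.debug("non-numeric primaryid %r compared lexicographically",
                 primaryid)
    return (0, 0, primaryid)


def _date_key(fda_dt: str):
    # empty dates sort before any real YYYYMMDD string
    return fda_dt or ""


def deduplicate(demo: Iterable[DemoRow]) -> DedupResult:
    """Collapse report versions to one :class:`DemoRow` per case.

    Per ``caseid``: keep the row with maximal ``fda_dt``; among ties, keep
    the maximal ``primaryid`` (numeric comparison).  Rows with empty
    ``fda_dt`` sort before any real date.  Rows with an empty ``caseid``
    cannot be linked to a case and are kept as singletons.
    """
    by_case: dict[str, list[DemoRow]] = {}
    for row in demo:
        key = row.caseid if row.caseid else f"\x00pid:{row.primaryid}"
        by_case.setdefault(key, []).append(row)

    kept, dropped, audit, kept_rows = set(), set(), {}, []
    for caseid in sorted(by_case):
        rows = by_case[caseid]
        if len(rows) == 1:
            winner, rule = rows[0], RULE_SINGLETON
        else:
            winner = max(rows, key=lambda r: (_date_key(r.fda_dt),
                                              _pid_key(r.primaryid)))
            best_dt = _date_key(winner.fda_dt)
            n_at_best = sum(1 for r in rows if _date_key(r.fda_dt) == best_dt)
            rule = RULE_HIGHER_PRIMARYID if n_at_best > 1 else RULE_LATEST_DATE
        kept.add(winner.primaryid)
        kept_rows.append(winner)
        dropped.update(r.primaryid for r in rows if r is not winner)
        audit[caseid] = (winner.primaryid, rule)

    return DedupResult(kept=kept, dropped=dropped, n_cases=len(by_case),
                       audit=audit, kept_rows=kept_rows)


def write_audit(result: DedupResult, path) -> None:
    """Write the per-case decision audit as TSV (caseid, kept, rule)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("caseid\tkept_primaryid\trule\n")
        for caseid, (pid, rule) in sorted(result.audit.items()):
            fh.write(f"{caseid}\t{pid}\t{rule}\n")
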