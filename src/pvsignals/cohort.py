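"""Cohort selection: event-term matching, primary-suspect drugs, and the
report-level drug/event incidence index.

The unit of counting throughout is the deduplicated report: a report counts
once for a (drug, event) pair no matter how many drug or reaction rows
repeat it.  Only drugs reported with role code PS (primary suspect) enter
drug counts, which keeps the false-positive rate of disproportionality
statistics down relative to counting concomitant medication.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

#: sentinel event name for "any target PT on the report"
COMPOSITE = "__composite__"


@dataclass(frozen=True)
class PtList:
    """A set of MedDRA Preferred Terms matched case-insensitively after
    whitespace trimming (exact equality, never substring)."""

    terms: frozenset

    def __post_init__(self):
        object.__setattr__(self, "_by_key",
                           {t.strip().casefold(): t.strip()
                            for t in self.terms})

    def match(self, pt: str) -> str | None:
        """Return the canonical-case term if ``pt`` is a member."""
        return self._by_key.get(pt.strip().casefold())

    def __len__(self):
        return len(self._by_key)

    def __iter__(self):
        return iter(sorted(self._by_key.values()))


def load_pt_list(path) -> PtList:
    """Load a PT list file (one term per line; '#' comments ignored)."""
    terms = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.append(line)
    return PtList(terms=frozenset(terms))


def gip_pt_list() -> PtList:
    """The default gastrointestinal-perforation PT list (24 terms from the
    SMQ-derived set)."""
    ref = resources.files("pvsignals.data") / "gip_pts.txt"
    with resources.as_file(ref) as p:
        return load_pt_list(Path(p))


def load_drug_list(path) -> list[str]:
    """Load a target-drug list (one canonical name per line)."""
    drugs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                drugs.append(line.lower())
    return drugs


def default_target_drugs() -> list[str]:
    ref = resources.files("pvsignals.data") / "target_drugs.txt"
    with resources.as_file(ref) as p:
        return load_drug_list(Path(p))


def match_gip_pts(reac: Iterable, pts: PtList) -> dict[str, set]:
    """Map each primaryid to its set of matched target PTs.

    Matching is case-insensitive exact string equality after trimming;
    reports with no matching PT are absent from the result.
    """
    out: dict[str, set] = {}
    for row in reac:
        hit = pts.match(row.pt)
        if hit is not None:
            out.setdefault(row.primaryid, set()).add(hit)
    return out


def select_ps_drugs(drug_rows: Iterable, outcomes: Iterable) -> dict[str, set]:
    """Map each primaryid to its set of canonical primary-suspect drugs.

    ``outcomes`` is the per-row normalization result aligned with
    ``drug_rows``.  Only rows with ``role_cod == 'PS'`` contribute;
    multi-ingredient outcomes contribute every ingredient; unmatched rows
    contribute nothing.
    """
    out: dict[str, set] = {}
    for row, outcome in zip(drug_rows, outcomes, strict=True):
        if row.role_cod.strip().upper() != "PS":
            continue
        if not outcome.canonical:
            continue
        out.setdefault(row.primaryid, set()).update(outcome.canonical)
    return out


@dataclass
class CaseEventIndex:
    """Report-level incidence structure with cached margins.

    ``n_event`` counts reports per matched target PT; ``n_composite``
    counts reports with at least one matched PT.  ``all_pts_by_case``
    retains every PT on the report (needed to fit the empirical-Bayes
    prior on the full drug x PT pair table).
    """

    N: int
    pids: list
    drugs_by_case: dict
    events_by_case: dict
    all_pts_by_case: dict
    n_drug: Counter = field(default_factory=Counter)
    n_event: Counter = field(default_factory=Counter)
    n_composite: int = 0
    cases_by_drug: dict = field(default_factory=dict)
    cases_by_event: dict = field(default_factory=dict)
    composite_cases: set = field(default_factory=set)

    def event_cases(self, event: str) -> set:
        if event == COMPOSITE:
            return self.composite_cases
        return self.cases_by_event.get(event, set())

    def drug_cases(self, drug: str) -> set:
        return self.cases_by_drug.get(drug, set())


def build_index(kept_demo: Iterable, ps_map: dict, gip_map: dict,
                all_pt_map: dict | None = None) -> CaseEventIndex:
    """Assemble the :class:`CaseEventIndex` over deduplicated reports.

    ``kept_demo`` fixes the report universe (N); ps/gip maps keyed by
    primaryid are restricted to it, so orphan or dropped-version rows never
    leak into the margins.
    """
    pids = [r.primaryid for r in kept_demo]
    universe = set(pids)
    all_pt_map = all_pt_map or {}

    idx = CaseEventIndex(N=len(pids), pids=pids, drugs_by_case={},
                         events_by_case={}, all_pts_by_case={})
    for pid in pids:
        drugs = frozenset(ps_map.get(pid, ()))
        events = frozenset(gip_map.get(pid, ()))
        if drugs:
            idx.drugs_by_case[pid] = drugs
            for d in drugs:
                idx.n_drug[d] += 1
                idx.cases_by_drug.setdefault(d, set()).add(pid)
        if events:
            idx.events_by_case[pid] = events
            idx.n_composite += 1
            idx.composite_cases.add(pid)
            for e in events:
                idx.n_event[e] += 1
                idx.cases_by_event.setdefault(e, set()).add(pid)
        pts = frozenset(all_pt_map.get(pid, ()))
        if pts:
            idx.all_pts_by_case[pid] = pts
    # sanity: maps must not reference reports outside the universe
    stray = (set(ps_map) | set(gip_map)) - universe
    if stray:
        # restricted silently above; record count for callers that care
        idx.n_stray = len(stray)  # type: ignore[attr-defined]
    return idx
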