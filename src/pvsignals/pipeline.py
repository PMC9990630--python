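"""End-to-end analysis: bundles -> dedup -> normalize -> cohort -> signals.

Thin orchestration over the stage modules so that the CLI, tests and the
reproduction script all run the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cohort as cohort_mod
from . import dedup as dedup_mod
from . import normalize as norm_mod
from . import report as report_mod
from . import stats as stats_mod
from .cohort import COMPOSITE


@dataclass
class PipelineResult:
    dedup: dedup_mod.DedupResult
    index: cohort_mod.CaseEventIndex
    prior: stats_mod.MgpsPrior | None
    results: list
    summaries: dict
    unmatched_rate: float = 0.0
    descriptive: report_mod.DescriptiveTable | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flat signal table (one row per drug-event pair)."""
        rows = []
        for r in self.results:
            t = r.table
            rows.append({
                "drug": r.drug,
                "event": ("Any target PT" if r.event == COMPOSITE
                          else r.event),
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": r.ror.ror, "ror05": r.ror.ror05,
                "ror95": r.ror.ror95,
                "ic": r.ic.ic, "ic025": r.ic.ic025, "ic975": r.ic.ic975,
                "ebgm": r.ebgm.ebgm if r.ebgm else float("nan"),
                "ebgm05": r.ebgm.ebgm05 if r.ebgm else float("nan"),
                "ebgm95": r.ebgm.ebgm95 if r.ebgm else float("nan"),
                "sig_ror": r.ror.significant,
                "sig_ic": r.ic.significant,
                "sig_ebgm": bool(r.ebgm and r.ebgm.significant),
            })
        return pd.DataFrame(rows)


def run_pipeline(bundles, dictionary=None, pts=None, target_drugs=None,
                 include_composite: bool = True,
                 prior: stats_mod.MgpsPrior | None = None,
                 fit_seed: int = 0,
                 describe: bool = True) -> PipelineResult:
    """Run the full analysis over a list of quarter bundles.

    Quarters are pooled first, then deduplicated globally; drug counting
    uses primary-suspect rows only; the mixture prior is fitted on the
    full drug x PT pair table of the deduplicated data unless one is
    supplied.
    """
    dictionary = dictionary or norm_mod.default_dictionary()
    pts = pts or cohort_mod.gip_pt_list()

    demo, drug_rows, reac_rows = [], [], []
    for b in bundles:
        demo.extend(b.demo)
        drug_rows.extend(b.drug)
        reac_rows.extend(b.reac)

    ded = dedup_mod.deduplicate(demo)
    kept = ded.kept

    kept_drug_rows = [r for r in drug_rows if r.primaryid in kept]
    outcomes = [norm_mod.normalize_drug(r, dictionary)
                for r in kept_drug_rows]
    n_unmatched = sum(1 for o in outcomes if not o.matched)
    unmatched_rate = n_unmatched / len(outcomes) if outcomes else 0.0

    ps_map = cohort_mod.select_ps_drugs(kept_drug_rows, outcomes)
    kept_reac = [r for r in reac_rows if r.primaryid in kept]
    gip_map = cohort_mod.match_gip_pts(kept_reac, pts)
    all_pt_map: dict[str, set] = {}
    for r in kept_reac:
        pt = r.pt.strip()
        if pt:
            all_pt_map.setdefault(r.primaryid, set()).add(pt)

    index = cohort_mod.build_index(ded.kept_rows, ps_map, gip_map,
                                   all_pt_map)

    if target_drugs is None:
        drugs = sorted(index.n_drug)
    else:
        drugs = [d.lower() for d in target_drugs]
    events = list(pts)
    if include_composite:
        events = [COMPOSITE] + events

    if prior is None:
        try:
            _, a_arr, e_arr = stats_mod.pair_table(index)
            prior = stats_mod.fit_mgps_prior(a_arr, e_arr, seed=fit_seed)
        except ValueError:
            prior = None

    results = stats_mod.compute_signals(index, drugs, events, prior=prior,
                                        fit_seed=fit_seed)
    summaries = stats_mod.classify_signals(results)

    descriptive = None
    if describe:
        cohort_rows = [r for r in ded.kept_rows
                       if r.primaryid in index.composite_cases
                       and index.drugs_by_case.get(r.primaryid)]
        if cohort_rows:
            descriptive = report_mod.summarize_cohort(cohort_rows)

    return PipelineResult(dedup=ded, index=index, prior=prior,
                          results=results, summaries=summaries,
                          unmatched_rate=unmatched_rate,
                          descriptive=descriptive)
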