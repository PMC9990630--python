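"""Synthetic spontaneous-report generator with known ground truth.

Emulates the statistical structure a disproportionality analysis assumes:
each case independently draws a set of primary-suspect drugs from per-drug
marginal probabilities, and each adverse-event term fires with its marginal
probability, multiplied by a planted rate ratio RR when a planted
(drug, event) pair's drug is present on the case (capped at 1).  On top of
that sit the data artefacts the cleaning pipeline must handle: versioned
duplicate reports (same caseid, later fda_dt, higher primaryid), messy drug
name variants (trade names, salts, dose strings, case noise), concomitant
drug rows with non-PS role codes, and demographic missingness.

Everything is driven by one seeded generator, so identical configs produce
byte-identical output files; the returned :class:`GroundTruth` records the
per-case assignments and margins that tests use as oracles.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import DemoRow, DrugRow, QuarterBundle, ReacRow
from .normalize import SynonymDictionary

#: background adverse-event terms (never targets)
BACKGROUND_PTS = (
    ("Nausea", 0.06), ("Diarrhoea", 0.05), ("Fatigue", 0.05),
    ("Vomiting", 0.04), ("Headache", 0.04), ("Pyrexia", 0.03),
    ("Rash", 0.03), ("Abdominal pain", 0.03), ("Dizziness", 0.03),
    ("Drug ineffective", 0.05),
)

_SALTS = ("HYDROCHLORIDE", "MALATE", "MESYLATE", "SODIUM", "TARTRATE")
_DOSES = ("100MG", "250MG", "50MG/5ML", "400MG/16ML", "25 MG")


@dataclass
class DrugSpec:
    """One drug in the generative model: canonical name, marginal
    probability of appearing as primary suspect, optional trade names used
    by the name-noise channel."""

    name: str
    p: float
    trade_names: tuple = ()


@dataclass
class EventSpec:
    pt: str
    p: float


@dataclass
class PlantedSignal:
    """Multiplicative disproportionality on one (drug, event) pair."""

    drug: str
    event: str
    rr: float


@dataclass
class SyntheticConfig:
    n_cases: int = 10_000
    drugs: list = field(default_factory=list)
    events: list = field(default_factory=list)
    planted: list = field(default_factory=list)
    #: probability a case emits at least one extra report version
    duplicate_rate: float = 0.19
    #: fraction of duplicate versions sharing fda_dt with the previous one
    #: (exercises the higher-primaryid tie-break)
    tie_rate: float = 0.0
    #: probability a drug row's drugname uses a noisy variant
    name_noise: float = 0.3
    #: probability of an extra concomitant (non-PS) drug row per case
    concomitant_rate: float = 0.5
    # per-field missingness
    missing_sex: float = 0.43
    missing_age: float = 0.30
    missing_occp: float = 0.03
    p_female: float = 0.474
    age_mean: float = 62.0
    age_sd: float = 15.0
    occp_probs: dict = field(default_factory=lambda: {
        "MD": 0.55, "OT": 0.22, "CN": 0.17, "PH": 0.05, "HP": 0.01})
    date_start: str = "20040101"
    date_end: str = "20210930"
    #: canonical names drawn on for concomitant rows and drug-less cases
    background_pool: tuple = ("acetaminophen", "aspirin", "metformin",
                              "omeprazole", "paclitaxel")
    filler_pt: str = "Drug ineffective"
    seed: int = 0

    def validate(self) -> None:
        names = {d.name for d in self.drugs}
        events = {e.pt for e in self.events}
        for d in self.drugs:
            if not 0 <= d.p <= 1:
                raise ValueError(f"drug probability out of [0,1]: {d}")
        for e in self.events:
            if not 0 <= e.p <= 1:
                raise ValueError(f"event probability out of [0,1]: {e}")
        for pl in self.planted:
            if pl.rr <= 0:
                raise ValueError(f"planted RR must be > 0: {pl}")
            if pl.drug not in names:
                raise ValueError(f"planted pair references unknown drug "
                                 f"{pl.drug!r}")
            if pl.event not in events:
                raise ValueError(f"planted pair references unknown event "
                                 f"{pl.event!r}")
        for rate in (self.duplicate_rate, self.tie_rate, self.name_noise,
                     self.concomitant_rate, self.missing_sex,
                     self.missing_age, self.missing_occp, self.p_female):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0,1]")


@dataclass
class GroundTruth:
    """What the generator actually planted, for use as a test oracle."""

    n_cases: int
    #: caseid -> frozenset of canonical PS drugs (incl. filler)
    drugs_by_case: dict
    #: caseid -> frozenset of event PTs
    events_by_case: dict
    n_drug: Counter
    n_event: Counter
    pair_a: Counter
    n_demo_rows: int = 0
    n_drug_rows: int = 0
    n_reac_rows: int = 0
    #: fraction of event draws whose probability hit the cap at 1
    cap_fraction: float = 0.0
    cap_warning: bool = False


def dictionary_for_config(config: SyntheticConfig) -> SynonymDictionary:
    """A synonym dictionary resolving every name variant the generator can
    emit (trade names need entries; salt/dose/case noise is handled by key
    normalization)."""
    d = SynonymDictionary()
    for spec in config.drugs:
        d.add(spec.name, [spec.name])
        for trade in spec.trade_names:
            d.add(trade, [spec.name])
    for name in config.background_pool:
        d.add(name, [name])
    return d


def _date_range_days(config) -> tuple[dt.date, int]:
    start = dt.datetime.strptime(config.date_start, "%Y%m%d").date()
    end = dt.datetime.strptime(config.date_end, "%Y%m%d").date()
    return start, (end - start).days


def _quarter_of(date: dt.date) -> str:
    return f"{date.year}Q{(date.month - 1) // 3 + 1}"


def _noisy_name(rng, spec: DrugSpec) -> str:
    kinds = ["salt", "dose", "case"]
    if spec.trade_names:
        kinds.append("trade")
    kind = kinds[rng.integers(len(kinds))]
    base = spec.name.upper()
    if kind == "trade":
        name = spec.trade_names[rng.integers(len(spec.trade_names))].upper()
        if rng.random() < 0.5:
            name += " " + _DOSES[rng.integers(len(_DOSES))]
        return name
    if kind == "salt":
        return base + " " + _SALTS[rng.integers(len(_SALTS))]
    if kind == "dose":
        return base + " " + _DOSES[rng.integers(len(_DOSES))]
    return spec.name.title()


def generate(config: SyntheticConfig,
             seed: int | None = None) -> tuple[list[QuarterBundle],
                                               GroundTruth]:
    """Generate FAERS-format quarter bundles plus ground truth.

    ``seed`` overrides ``config.seed`` when given.  Deterministic: the same
    config and seed yield identical bundles (and, through
    :func:`pvsignals.io.write_quarter`, byte-identical files).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cases

    drug_names = [d.name for d in config.drugs]
    event_names = [e.pt for e in config.events]
    planted_by_event: dict[int, list] = {}
    for pl in config.planted:
        planted_by_event.setdefault(event_names.index(pl.event), []).append(
            (drug_names.index(pl.drug), pl.rr))

    # --- case-level incidence draws (fixed draw order for determinism) ----
    drug_mat = np.zeros((n, len(config.drugs)), dtype=bool)
    for j, spec in enumerate(config.drugs):
        drug_mat[:, j] = rng.random(n) < spec.p

    cap_hits = 0
    cap_total = 0
    event_mat = np.zeros((n, len(config.events)), dtype=bool)
    for k, spec in enumerate(config.events):
        p_vec = np.full(n, spec.p)
        for j, rr in planted_by_event.get(k, ()):
            mask = drug_mat[:, j]
            p_vec[mask] = np.maximum(p_vec[mask], spec.p * rr)
        capped = p_vec > 1.0
        cap_hits += int(capped.sum())
        cap_total += n
        np.minimum(p_vec, 1.0, out=p_vec)
        event_mat[:, k] = rng.random(n) < p_vec

    # filler PS drug for cases that drew none (every report has >= 1 drug)
    no_drug = ~drug_mat.any(axis=1)
    filler_idx = rng.integers(len(config.background_pool), size=n)

    # demographics
    sex_female = rng.random(n) < config.p_female
    sex_missing = rng.random(n) < config.missing_sex
    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, n),
                        0.0, 100.0)
    age_missing = rng.random(n) < config.missing_age
    age_unit_pick = rng.random(n)  # YR / DEC / MON
    occ_missing = rng.random(n) < config.missing_occp
    occ_codes = list(config.occp_probs)
    occ_p = np.array([config.occp_probs[c] for c in occ_codes], dtype=float)
    occ_p = occ_p / occ_p.sum()
    occ_idx = rng.choice(len(occ_codes), size=n, p=occ_p)

    start_date, span = _date_range_days(config)
    base_offset = rng.integers(0, span + 1, size=n)

    # versioning
    has_dup = rng.random(n) < config.duplicate_rate
    n_extra = np.where(has_dup, rng.integers(1, 3, size=n), 0)
    dup_tie = rng.random(n) < config.tie_rate
    dup_gap = rng.integers(30, 400, size=n)

    concomitant = rng.random(n) < config.concomitant_rate
    conc_idx = rng.integers(len(config.background_pool), size=n)
    conc_role = np.array(["C", "SS", "I"])[rng.integers(3, size=n)]
    noise_draw = rng.random  # consumed per drug row below

    truth = GroundTruth(n_cases=n, drugs_by_case={}, events_by_case={},
                        n_drug=Counter(), n_event=Counter(),
                        pair_a=Counter(),
                        cap_fraction=cap_hits / max(cap_total, 1),
                        cap_warning=cap_hits / max(cap_total, 1) > 0.01)

    bundles: dict[str, QuarterBundle] = {}

    def bundle_for(date: dt.date) -> QuarterBundle:
        q = _quarter_of(date)
        if q not in bundles:
            bundles[q] = QuarterBundle(quarter=q, demo=[], drug=[], reac=[])
        return bundles[q]

    for i in range(n):
        caseid = str(10_000_000 + i)
        case_drugs = [drug_names[j] for j in np.nonzero(drug_mat[i])[0]]
        ps_specs = [config.drugs[j] for j in np.nonzero(drug_mat[i])[0]]
        if no_drug[i]:
            filler = config.background_pool[filler_idx[i]]
            case_drugs = [filler]
            ps_specs = [DrugSpec(filler, 0.0)]
        case_events = [event_names[k] for k in np.nonzero(event_mat[i])[0]]
        reac_pts = case_events if case_events else [config.filler_pt]

        truth.drugs_by_case[caseid] = frozenset(case_drugs)
        truth.events_by_case[caseid] = frozenset(case_events)
        for d in case_drugs:
            truth.n_drug[d] += 1
            for e in case_events:
                truth.pair_a[(d, e)] += 1
        for e in case_events:
            truth.n_event[e] += 1

        sex = "" if sex_missing[i] else ("F" if sex_female[i] else "M")
        if age_missing[i]:
            age, age_cod = "", ""
        elif age_unit_pick[i] < 0.85:
            age, age_cod = f"{age_years[i]:.0f}", "YR"
        elif age_unit_pick[i] < 0.95:
            age, age_cod = f"{age_years[i] / 10:.1f}", "DEC"
        else:
            age, age_cod = f"{age_years[i] * 12:.0f}", "MON"
        occp = "" if occ_missing[i] else occ_codes[occ_idx[i]]

        # drug/reac row payload, identical across versions of the case
        drug_payload = []
        seq = 1
        for spec in ps_specs:
            if noise_draw() < config.name_noise:
                name, prod_ai = _noisy_name(rng, spec), ""
            else:
                name, prod_ai = spec.name.upper(), spec.name.upper()
            drug_payload.append((str(seq), "PS", name, prod_ai))
            seq += 1
        if concomitant[i]:
            cname = config.background_pool[conc_idx[i]].upper()
            drug_payload.append((str(seq), str(conc_role[i]), cname, cname))

        n_versions = 1 + int(n_extra[i])
        offset = int(base_offset[i])
        for v in range(1, n_versions + 1):
            if v > 1 and not (dup_tie[i] and v == n_versions):
                offset = min(offset + int(dup_gap[i]), span)
            date = start_date + dt.timedelta(days=offset)
            fda_dt = date.strftime("%Y%m%d")
            pid = f"{caseid}{v}"
            b = bundle_for(date)
            b.demo.append(DemoRow(primaryid=pid, caseid=caseid,
                                  fda_dt=fda_dt, sex=sex, age=age,
                                  age_cod=age_cod, occp_cod=occp))
            for seq_s, role, name, prod_ai in drug_payload:
                b.drug.append(DrugRow(primaryid=pid, drug_seq=seq_s,
                                      role_cod=role, drugname=name,
                                      prod_ai=prod_ai))
            for pt in reac_pts:
                b.reac.append(ReacRow(primaryid=pid, pt=pt))
        truth.n_demo_rows += n_versions
        truth.n_drug_rows += n_versions * len(drug_payload)
        truth.n_reac_rows += n_versions * len(reac_pts)

    ordered = [bundles[q] for q in sorted(bundles)]
    for b in ordered:
        b.find_orphans()
    return ordered, truth


def expected_cells(config: SyntheticConfig) -> dict:
    """Closed-form expected 2x2 cells per declared (drug, event) pair.

    Under the generative model the expected pair count is
    ``n * p_drug * min(1, RR * p_event)`` with RR = 1 for unplanted pairs;
    event probability for drug-free cases stays at its marginal.
    """
    rr = {(pl.drug, pl.event): pl.rr for pl in config.planted}
    out = {}
    n = config.n_cases
    for dspec in config.drugs:
        for espec in config.events:
            r = rr.get((dspec.name, espec.pt), 1.0)
            p_pair = dspec.p * min(1.0, espec.p * r)
            a = n * p_pair
            b = n * dspec.p - a
            c = n * (1.0 - dspec.p) * espec.p
            d = n - a - b - c
            out[(dspec.name, espec.pt)] = (a, b, c, d)
    return out


def default_config(n_cases: int = 10_000, seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults: target antineoplastics at realistic PS
    marginals, the 24 perforation PTs at rare-event marginals, background
    drugs/events, and a handful of planted signals at RR = 10."""
    from .cohort import gip_pt_list

    targets = [
        DrugSpec("bevacizumab", 0.008, ("Avastin",)),
        DrugSpec("cetuximab", 0.004, ("Erbitux",)),
        DrugSpec("lenvatinib", 0.003, ("Lenvima",)),
        DrugSpec("atezolizumab", 0.003, ("Tecentriq",)),
        DrugSpec("nivolumab", 0.005, ("Opdivo",)),
        DrugSpec("pembrolizumab", 0.005, ("Keytruda",)),
        DrugSpec("sunitinib", 0.003, ("Sutent",)),
        DrugSpec("sorafenib", 0.003, ("Nexavar",)),
        DrugSpec("rituximab", 0.006, ("Rituxan", "Mabthera")),
        DrugSpec("erlotinib", 0.003, ("Tarceva",)),
    ]
    background = [
        DrugSpec("aspirin", 0.02), DrugSpec("metformin", 0.02),
        DrugSpec("atorvastatin", 0.015), DrugSpec("lisinopril", 0.015),
        DrugSpec("omeprazole", 0.015), DrugSpec("paclitaxel", 0.01),
    ]
    gip_events = [EventSpec(pt, 0.0008) for pt in gip_pt_list()]
    events = gip_events + [EventSpec(pt, p) for pt, p in BACKGROUND_PTS]
    planted = [
        PlantedSignal("bevacizumab", "Gastrointestinal perforation", 10.0),
        PlantedSignal("bevacizumab", "Intestinal perforation", 10.0),
        PlantedSignal("cetuximab", "Rectal perforation", 10.0),
        PlantedSignal("lenvatinib", "Lower gastrointestinal perforation",
                      10.0),
        PlantedSignal("atezolizumab", "Duodenal perforation", 10.0),
    ]
    return SyntheticConfig(n_cases=n_cases, drugs=targets + background,
                           events=events, planted=planted, seed=seed)
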