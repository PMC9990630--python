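"""Descriptive cohort summaries and signal-matrix reports.

Reproduces the usual pharmacovigilance baseline table (sex, age bands,
reporter occupation, report year, each as count + percent of the cohort)
and emits drug x PT matrices of an indicator's significant lower bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import COMPOSITE

logger = logging.getLogger(__name__)

MISSING = "Unclear or Missing"

#: age-unit code -> factor converting the stored value to years
AGE_UNIT_FACTORS = {
    "DEC": 10.0,          # decades
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_BANDS = ("0-18", "19-45", "46-65", "65-100")

OCCUPATION_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "CN": "Consumer",
    "OT": "Other health-professional",
    "HP": "Other health-professional",
}


def age_in_years(age: str, age_cod: str) -> float | None:
    """Convert a (value, unit-code) age to years; None when unusable.

    An empty unit with a value present is assumed to be years (the
    dominant convention in the data).  Negative ages and ages above 150
    years are treated as missing.
    """
    if age is None or str(age).strip() == "":
        return None
    try:
        value = float(str(age).strip())
    except ValueError:
        return None
    unit = (age_cod or "").strip().upper()
    if unit == "":
        logger.debug("age %r without unit assumed to be years", age)
        unit = "YR"
    factor = AGE_UNIT_FACTORS.get(unit)
    if factor is None:
        return None
    years = value * factor
    if years < 0 or years > 150:
        return None
    return years


def assign_age_band(age_years: float | None) -> str:
    """Band an age in years; 65 goes to the elder band."""
    if age_years is None:
        return MISSING
    if 0 <= age_years <= 18:
        return "0-18"
    if 18 < age_years <= 45:
        return "19-45"
    if 45 < age_years < 65:
        return "46-65"
    if 65 <= age_years <= 100:
        return "65-100"
    return MISSING


def percentage(count: int, total: int) -> float:
    """100*count/total rounded half-away-from-zero to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DescriptiveTable:
    """Counts and percentages per category over one cohort.

    ``categories`` maps category name (Sex/Age/Reporter/Report Years) to an
    ordered {label: count} dict; every label set partitions the cohort, so
    counts within a category sum to ``total``.
    """

    total: int
    categories: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def pct(self, category: str, label: str) -> float:
        return percentage(self.categories[category][label], self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, counts in self.categories.items():
            for label, n in counts.items():
                rows.append((cat, label, n, percentage(n, self.total)))
        return pd.DataFrame(rows, columns=["category", "class", "cases",
                                           "percent"])


def summarize_cohort(demo_rows) -> DescriptiveTable:
    """Build the baseline characteristics table for a deduplicated cohort.

    Sex F/M else missing; reporter occupation mapped to Consumer /
    Physician / Pharmacist / Other health-professional; report year from
    ``fda_dt``.  The derived "over-45" share sums the two upper age bands.
    """
    demo_rows = list(demo_rows)
    total = len(demo_rows)
    sex_counts = {"Female": 0, "Male": 0, MISSING: 0}
    age_counts = {b: 0 for b in AGE_BANDS}
    age_counts[MISSING] = 0
    occ_counts = {"Consumer": 0, "Physician": 0, "Pharmacist": 0,
                  "Other health-professional": 0, MISSING: 0}
    year_counts: dict[str, int] = {}

    for r in demo_rows:
        sex = r.sex.strip().upper()
        sex_counts["Female" if sex == "F"
                   else "Male" if sex == "M" else MISSING] += 1
        age_counts[assign_age_band(age_in_years(r.age, r.age_cod))] += 1
        occ = OCCUPATION_LABELS.get(r.occp_cod.strip().upper(), MISSING)
        occ_counts[occ] += 1
        year = r.fda_dt.strip()[:4]
        year_counts[year if year.isdigit() else MISSING] = \
            year_counts.get(year if year.isdigit() else MISSING, 0) + 1

    years_ordered = dict(sorted(
        ((k, v) for k, v in year_counts.items() if k != MISSING),
        reverse=True))
    if MISSING in year_counts:
        years_ordered[MISSING] = year_counts[MISSING]

    table = DescriptiveTable(total=total, categories={
        "Sex": sex_counts,
        "Age": age_counts,
        "Reporter": occ_counts,
        "Report Years": years_ordered,
    })
    if total > 0:
        over45 = age_counts["46-65"] + age_counts["65-100"]
        table.derived["over_45_count"] = over45
        table.derived["over_45_pct"] = percentage(over45, total)
    return table


# ---------------------------------------------------------------------------
# signal matrices

_INDICATOR_BOUND = {
    "ror": lambda r: (r.ror.significant, r.ror.ror05),
    "ic": lambda r: (r.ic.significant, r.ic.ic025),
    "ebgm": lambda r: (bool(r.ebgm and r.ebgm.significant),
                       r.ebgm.ebgm05 if r.ebgm else None),
}


def signal_matrix(results, indicator: str) -> pd.DataFrame:
    """Drug x PT grid of an indicator's lower bound at significant cells.

    Non-significant cells are NA.  Rows (drugs) are ordered by descending
    significant-signal count then name; columns (PTs) alphabetically; the
    composite event, when present, comes first.
    """
    if indicator not in _INDICATOR_BOUND:
        raise ValueError(f"unknown indicator {indicator!r}")
    pick = _INDICATOR_BOUND[indicator]
    cells = {}
    sig_count: dict[str, int] = {}
    drugs, events = set(), set()
    for r in results:
        drugs.add(r.drug)
        events.add(r.event)
        sig, bound = pick(r)
        sig_count.setdefault(r.drug, 0)
        if sig:
            cells[(r.drug, r.event)] = bound
            sig_count[r.drug] += 1
    row_order = sorted(drugs, key=lambda d: (-sig_count.get(d, 0), d))
    col_order = sorted(events, key=lambda e: (e != COMPOSITE, e))
    grid = pd.DataFrame(index=row_order, columns=col_order, dtype=float)
    for (d, e), v in cells.items():
        grid.loc[d, e] = v
    grid.index.name = "drug"
    return grid


def write_signal_matrix(results, indicator: str, path,
                        plot_path=None) -> pd.DataFrame:
    """Write the signal matrix as TSV (blank = non-significant); optionally
    render a heatmap alongside."""
    grid = signal_matrix(results, indicator)
    out = grid.rename(columns={COMPOSITE: "Any target PT"})
    out.to_csv(path, sep="\t", float_format="%.2f", na_rep="")
    if plot_path is not None:
        plot_signal_matrix(grid, indicator, plot_path)
    return grid


def plot_signal_matrix(grid: pd.DataFrame, indicator: str, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * grid.shape[1] + 2),
                 max(3, 0.3 * grid.shape[0] + 2)))
    data = grid.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(grid.shape[1]))
    ax.set_xticklabels([c if c != COMPOSITE else "Any target PT"
                        for c in grid.columns], rotation=90, fontsize=7)
    ax.set_yticks(range(grid.shape[0]))
    ax.set_yticklabels(grid.index, fontsize=7)
    fig.colorbar(im, ax=ax, label=f"{indicator} lower bound (significant)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
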