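"""Disproportionality statistics for 2x2 spontaneous-report tables.

Three measures of excess co-reporting of a (drug, event) pair, each with
its conventional decision rule:

* **ROR** — reporting odds ratio ``(a*d)/(b*c)`` with a log-normal Wald 95%
  CI; signal when the lower bound ROR05 > 1 and the pair count a >= 2.
* **IC** — BCPNN information component ``log2((a+0.5)/(E+0.5))`` where
  ``E = (a+b)(a+c)/N`` is the expected count under independence.  The
  credible interval comes from the gamma posterior
  ``lambda ~ Gamma(a+0.5, E+0.5)`` (shape, rate) on the observed-to-expected
  ratio; signal when IC025 > 0.
* **EBGM** — DuMouchel's multi-item gamma Poisson shrinker.  A two-component
  gamma mixture prior on the true reporting-rate ratio ``lambda`` is fitted
  by maximum marginal likelihood over the whole pair table (the marginals
  are negative-binomial); EBGM is the posterior geometric mean
  ``exp(E[ln lambda])``.  Signal when the lower posterior bound EBGM05 > 2
  (the count condition ">= 0" of the decision rule is vacuous and kept as
  stated).

The Bayesian measures shrink small counts toward the null and are therefore
more conservative than the ROR: under the null their flag rates sit at or
below the ROR's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats as sps

from .cohort import COMPOSITE, CaseEventIndex

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile used for the two-sided 95% Wald interval

#: conventional starting point for the mixture-prior fit
DEFAULT_PRIOR_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the 2x2 report table for one (drug, event) pair.

    a: reports with drug (PS) and event; b: drug, no event;
    c: event, no drug; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        """Expected pair count under independence: (a+b)(a+c)/N."""
        if self.N == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.N


@dataclass
class RorResult:
    ror: float
    ror05: float
    ror95: float
    n_cases: int
    significant: bool
    defined: bool = True


@dataclass
class IcResult:
    ic: float
    ic025: float
    ic975: float
    significant: bool
    ic025_approx: float = math.nan


@dataclass
class MgpsPrior:
    """Hyperparameters of the two-component gamma mixture prior on lambda.

    Component i is Gamma(shape=alpha_i, rate=beta_i); p is the weight of
    component 1.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    loglik: float = math.nan
    converged: bool = False
    n_pairs: int = 0

    def as_tuple(self) -> tuple:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.p)

    def swapped(self) -> "MgpsPrior":
        """The same prior with component labels exchanged (mixtures are
        invariant under label switching)."""
        return MgpsPrior(self.alpha2, self.beta2, self.alpha1, self.beta1,
                         1.0 - self.p, self.loglik, self.converged,
                         self.n_pairs)

    @property
    def mean(self) -> float:
        return (self.p * self.alpha1 / self.beta1
                + (1 - self.p) * self.alpha2 / self.beta2)


@dataclass
class EbgmResult:
    ebgm: float
    ebgm05: float
    ebgm95: float
    q: float
    significant: bool


@dataclass
class SignalResult:
    drug: str
    event: str
    table: ContingencyTable
    ror: RorResult
    ic: IcResult
    ebgm: EbgmResult | None = None


def build_contingency(index: CaseEventIndex, drug: str,
                      event: str) -> ContingencyTable:
    """Count the 2x2 cells for one (drug, event) pair from the index.

    ``event`` is a target PT or :data:`~pvsignals.cohort.COMPOSITE` for
    "any target PT".
    """
    if drug not in index.n_drug:
        raise KeyError(f"drug {drug!r} not present in index")
    if event != COMPOSITE and event not in index.n_event:
        raise KeyError(f"event {event!r} not present in index")
    drug_cases = index.drug_cases(drug)
    event_cases = index.event_cases(event)
    a = len(drug_cases & event_cases)
    b = len(drug_cases) - a
    c = len(event_cases) - a
    d = index.N - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio with log-normal Wald 95% CI.

    Any zero cell leaves the estimate undefined (NaN, no continuity
    correction) and the pair non-significant; the n >= 2 case rule makes
    zero/one-count pairs non-signals regardless.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return RorResult(ror=math.nan, ror05=math.nan, ror95=math.nan,
                         n_cases=a, significant=False, defined=False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - Z95 * se)
    hi = math.exp(math.log(ror) + Z95 * se)
    return RorResult(ror=ror, ror05=lo, ror95=hi, n_cases=a,
                     significant=(lo > 1.0 and a >= 2))


def ic_point(a: float, E: float) -> float:
    """Shrunk information component log2((a+0.5)/(E+0.5))."""
    return math.log2((a + 0.5) / (E + 0.5))


def ic025_closed_form(a: float, E: float) -> float:
    """Closed-form approximation of the IC 2.5% credible bound:
    IC - 3.3(a+1/2)^(-1/2) - 2(a+1/2)^(-3/2)."""
    s = a + 0.5
    return ic_point(a, E) - 3.3 * s ** -0.5 - 2.0 * s ** -1.5


def compute_ic(t: ContingencyTable) -> IcResult:
    """BCPNN information component with exact gamma-posterior interval.

    The posterior on the observed-to-expected ratio is
    Gamma(shape=a+0.5, rate=E+0.5); the credible bounds are the 2.5% and
    97.5% quantiles of its log2.  The closed-form IC025 approximation is
    carried alongside as a cross-check.
    """
    if t.N <= 0:
        raise ValueError("empty table: N must be positive")
    a, E = t.a, t.E
    shape, rate = a + 0.5, E + 0.5
    lo, hi = sps.gamma.ppf([0.025, 0.975], shape, scale=1.0 / rate)
    ic = ic_point(a, E)
    ic025, ic975 = math.log2(lo), math.log2(hi)
    return IcResult(ic=ic, ic025=ic025, ic975=ic975,
                    significant=ic025 > 0.0,
                    ic025_approx=ic025_closed_form(a, E))


# ---------------------------------------------------------------------------
# MGPS: marginal likelihood of the gamma-mixture prior and its fit

def _log_nb(a, alpha, beta, E):
    """log NB marginal of a gamma-Poisson: a | lambda~Gamma(alpha, beta),
    a~Poisson(lambda*E)."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    return (special.gammaln(a + alpha) - special.gammaln(alpha)
            - special.gammaln(a + 1.0)
            + alpha * (np.log(beta) - np.log(beta + E))
            + a * (np.log(E) - np.log(beta + E)))


def _mixture_loglik(theta, a, E):
    la1, lb1, la2, lb2, logit_p = theta
    alpha1, beta1 = math.exp(la1), math.exp(lb1)
    alpha2, beta2 = math.exp(la2), math.exp(lb2)
    p = special.expit(logit_p)
    l1 = _log_nb(a, alpha1, beta1, E) + math.log(p)
    l2 = _log_nb(a, alpha2, beta2, E) + math.log1p(-p)
    return float(np.sum(np.logaddexp(l1, l2)))


def fit_mgps_prior(a, E, start: tuple = DEFAULT_PRIOR_START,
                   n_restarts: int = 3, seed: int = 0,
                   min_pairs: int = 50) -> MgpsPrior:
    """Fit the two-component gamma mixture prior by maximum marginal
    likelihood over the full (drug, event) pair table.

    Parameters
    ----------
    a, E : array-like
        Observed and expected pair counts over the fitting universe
        (conventionally all pairs with a >= 1).
    start : tuple
        (alpha1, beta1, alpha2, beta2, p) starting point; the conventional
        start is (0.2, 0.1, 2, 4, 1/3).
    n_restarts : int
        Number of jittered restarts in addition to the plain start; the
        best optimum is kept.
    min_pairs : int
        Floor on the number of pairs with a >= 1; below it the fit is
        refused.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if a.shape != E.shape:
        raise ValueError("a and E must have the same length")
    n_pos = int(np.sum(a >= 1))
    if n_pos < min_pairs:
        raise ValueError(
            f"only {n_pos} pairs with a >= 1; at least {min_pairs} required "
            "to fit the mixture prior")

    theta0 = np.array([math.log(start[0]), math.log(start[1]),
                       math.log(start[2]), math.log(start[3]),
                       special.logit(start[4])])
    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0.0, 0.4, size=5)
                         for _ in range(n_restarts)]

    # bounds on the log/logit scale keep the optimizer away from the
    # degenerate corners of the mixture (hyperparameters in [e-10, e10])
    bounds = [(-10.0, 10.0)] * 4 + [(-12.0, 12.0)]
    best = None
    for th0 in starts:
        res = optimize.minimize(lambda th: -_mixture_loglik(th, a, E),
                                np.clip(th0, -9.0, 9.0),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    la1, lb1, la2, lb2, logit_p = best.x
    prior = MgpsPrior(alpha1=math.exp(la1), beta1=math.exp(lb1),
                      alpha2=math.exp(la2), beta2=math.exp(lb2),
                      p=float(special.expit(logit_p)),
                      loglik=-float(best.fun),
                      converged=bool(best.success), n_pairs=len(a))
    if not prior.converged:
        logger.warning("MGPS prior fit did not converge: %s", best.message)
    return prior


def compute_ebgm(t: ContingencyTable, prior: MgpsPrior,
                 two_sided: bool = True) -> EbgmResult:
    """Empirical Bayes geometric mean of lambda under the fitted prior.

    The posterior is ``q Gamma(alpha1+a, beta1+E) + (1-q) Gamma(alpha2+a,
    beta2+E)`` with q the posterior weight of component 1 from the
    negative-binomial marginals.  EBGM = exp(E[ln lambda]); the interval
    bounds solve the posterior mixture CDF at 2.5/97.5% (``two_sided``,
    the default) or at 5/95% (the conventional one-sided EB05/EB95).
    """
    if not prior.converged:
        raise ValueError("refusing EBGM from a non-converged prior fit")
    a, E = t.a, t.E
    if E <= 0:
        raise ValueError(f"EBGM undefined for E={E} (empty margin)")
    l1 = _log_nb(a, prior.alpha1, prior.beta1, E) + math.log(prior.p)
    l2 = _log_nb(a, prior.alpha2, prior.beta2, E) + math.log1p(-prior.p)
    q = float(special.expit(l1 - l2))

    s1, r1 = prior.alpha1 + a, prior.beta1 + E
    s2, r2 = prior.alpha2 + a, prior.beta2 + E
    mean_log = (q * (special.digamma(s1) - math.log(r1))
                + (1 - q) * (special.digamma(s2) - math.log(r2)))
    ebgm = math.exp(mean_log)

    lo_q, hi_q = (0.025, 0.975) if two_sided else (0.05, 0.95)

    def cdf(x):
        return (q * sps.gamma.cdf(x, s1, scale=1.0 / r1)
                + (1 - q) * sps.gamma.cdf(x, s2, scale=1.0 / r2))

    def quantile(prob):
        lo = 0.5 * min(sps.gamma.ppf(1e-9, s1, scale=1.0 / r1),
                       sps.gamma.ppf(1e-9, s2, scale=1.0 / r2))
        hi = 2.0 * max(sps.gamma.ppf(1.0 - 1e-9, s1, scale=1.0 / r1),
                       sps.gamma.ppf(1.0 - 1e-9, s2, scale=1.0 / r2)) + 1.0
        try:
            return optimize.brentq(lambda x: cdf(x) - prob, lo, hi,
                                   xtol=1e-12, rtol=1e-12)
        except ValueError as exc:
            raise ArithmeticError(
                f"EBGM quantile root-finding failed for a={a}, E={E}: {exc}"
            ) from exc

    ebgm05 = quantile(lo_q)
    ebgm95 = quantile(hi_q)
    return EbgmResult(ebgm=ebgm, ebgm05=ebgm05, ebgm95=ebgm95, q=q,
                      significant=(ebgm05 > 2.0 and a >= 0))


# ---------------------------------------------------------------------------
# pair-table assembly and per-drug classification

def pair_table(index: CaseEventIndex, min_a: int = 1):
    """(a, E) over all canonical PS drug x PT pairs in the index.

    This is the fitting universe for the mixture prior: every pair of a
    normalized primary-suspect drug with any reported PT (not only target
    PTs), restricted to pairs with ``a >= min_a``.  Returns (labels, a, E)
    with labels a list of (drug, pt).
    """
    from collections import Counter
    pair_counts: Counter = Counter()
    pt_margin: Counter = Counter()
    for pid in index.pids:
        pts = index.all_pts_by_case.get(pid, ())
        for pt in pts:
            pt_margin[pt] += 1
        for d in index.drugs_by_case.get(pid, ()):
            for pt in pts:
                pair_counts[(d, pt)] += 1
    labels, a_list, e_list = [], [], []
    N = index.N
    for (d, pt), cnt in sorted(pair_counts.items()):
        if cnt < min_a:
            continue
        labels.append((d, pt))
        a_list.append(cnt)
        e_list.append(index.n_drug[d] * pt_margin[pt] / N)
    return labels, np.array(a_list, dtype=float), np.array(e_list,
                                                           dtype=float)


def compute_signals(index: CaseEventIndex, drugs, events,
                    prior: MgpsPrior | None = None,
                    fit_seed: int = 0) -> list[SignalResult]:
    """Run all three statistics for every (drug, event) combination.

    ``events`` may contain PTs and/or :data:`COMPOSITE`.  If ``prior`` is
    None it is fitted on the index's full pair table; when the table is too
    small to support a fit, EBGM results are omitted (None).
    """
    if prior is None:
        try:
            _, a_arr, e_arr = pair_table(index)
            prior = fit_mgps_prior(a_arr, e_arr, seed=fit_seed)
        except ValueError as exc:
            logger.warning("no MGPS prior: %s", exc)
            prior = None
    results = []
    for drug in drugs:
        if drug not in index.n_drug:
            continue
        for event in events:
            if event != COMPOSITE and event not in index.n_event:
                continue
            t = build_contingency(index, drug, event)
            ebgm = None
            if prior is not None and prior.converged and t.E > 0:
                ebgm = compute_ebgm(t, prior)
            results.append(SignalResult(drug=drug, event=event, table=t,
                                        ror=compute_ror(t),
                                        ic=compute_ic(t), ebgm=ebgm))
    return results


@dataclass
class DrugSummary:
    drug: str
    n_sig_ror: int
    n_sig_ic: int
    n_sig_ebgm: int
    n_sig_all3: int

    @property
    def in_overlap(self) -> bool:
        return self.n_sig_all3 >= 1


def classify_signals(results: list[SignalResult]) -> dict[str, DrugSummary]:
    """Per-drug signal counts and the three-indicator overlap set.

    A drug is in the overlap set when at least one of its events is
    significant on ROR, IC and EBGM simultaneously.
    """
    summaries: dict[str, DrugSummary] = {}
    for r in results:
        s = summaries.setdefault(r.drug, DrugSummary(r.drug, 0, 0, 0, 0))
        sig_ebgm = bool(r.ebgm and r.ebgm.significant)
        s.n_sig_ror += r.ror.significant
        s.n_sig_ic += r.ic.significant
        s.n_sig_ebgm += sig_ebgm
        s.n_sig_all3 += (r.ror.significant and r.ic.significant and sig_ebgm)
    return summaries
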