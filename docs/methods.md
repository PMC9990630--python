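# Methods

## Counting model

The unit of analysis is the deduplicated safety report. For a drug–event
pair, the 2×2 table is

|                | event | no event |
|----------------|-------|----------|
| **drug (PS)**  | a     | b        |
| **no drug**    | c     | d        |

with N = a+b+c+d and expected pair count under independence
E = (a+b)(a+c)/N. A report contributes at most once per pair regardless of
repeated drug or reaction rows; only primary-suspect (PS) drug rows enter
drug margins, because concomitant medication inflates false positives.
"Events" are MedDRA Preferred Terms matched by trimmed, case-insensitive
exact equality — never substrings — against a configurable list; the
shipped default is the 24-term gastrointestinal-perforation set. A
composite event ("any listed PT on the report") is exposed alongside the
per-PT events, since published per-drug case totals can be read either
way.

## Deduplication

FAERS retains every transmitted version of a report. Per case
(`caseid`): keep the version with the latest `fda_dt`; among ties, the
numerically higher `primaryid`. Missing `fda_dt` sorts below every real
date, so a case whose versions all lack dates falls through to the
primaryid rule. Non-numeric primaryids (absent from real extracts but
possible in hand-built files) compare lexicographically and below any
numeric id. All 71 quarters are pooled before deduplicating, so a case
re-transmitted across quarters still collapses to one row. The operation
is idempotent and order-independent; an audit trail records which branch
decided each case.

## Drug-name normalization

Verbatim `prod_ai`/`drugname` strings are resolved through a deterministic
synonym dictionary. The key canonicalization upper-cases, strips
punctuation, removes dose tokens (`400MG`, `16ML`, …) and packaging/form
stopwords, and strips one trailing salt suffix (`MALATE`,
`HYDROCHLORIDE`, …). Combination strings are split on `/ \ ; +` and the
words AND/WITH before lookup, each resolved ingredient contributing
separately. `prod_ai` is preferred over `drugname` because it is already
an active-ingredient field. Lookup never guesses: strings whose key is
absent are reported as unmatched and excluded from drug margins, while
their reports still count in N (the denominator is all deduplicated
reports). Edit-distance correction is deliberately out of scope — the
dictionary interface matches what an NLP concept mapper (e.g.
MedEx/RxNorm tooling) would emit, so a machine-generated dictionary can
be dropped in.

## Signal statistics

**ROR.** ror = ad/bc, CI = exp(ln ror ± 1.96·√(1/a+1/b+1/c+1/d)) with the
normal quantile taken as exactly 1.96. Signal: ROR05 > 1 and a ≥ 2. Any
zero cell leaves the estimate undefined (no continuity correction is
applied — the a ≥ 2 rule makes such pairs non-signals anyway), encoded as
NaN with `defined=False`.

**IC (BCPNN).** ic = log2((a+½)/(E+½)). Credible bounds are the exact
2.5%/97.5% quantiles of log2 λ with λ ~ Gamma(shape a+½, rate E+½) — the
current shrinkage-IC practice — rather than the original 1998
variance-propagation formula, which the analysis text alone cannot
distinguish. The closed-form approximation
IC025 ≈ ic − 3.3(a+½)^(−1/2) − 2(a+½)^(−3/2) is computed alongside as a
cross-check; on the grid a ≥ 3, E ∈ [0.1, 100] it stays within 0.05 of
the exact quantile (the tests assert < 0.1). Signal: IC025 > 0.

**EBGM (MGPS).** Prior: λ ~ p·Gamma(α₁, β₁) + (1−p)·Gamma(α₂, β₂)
(shape/rate). The marginal of a is then a two-component negative-binomial
mixture; hyperparameters are estimated by maximizing the summed log
marginal likelihood over the full pair table — every (normalized PS drug,
PT) pair with a ≥ 1, not only target pairs (inclusion of a = 0 pairs is a
config option; the default follows the common fit-on-observed-pairs
practice). Optimization: L-BFGS-B on (log α, log β, logit p) with box
bounds at ±10 (±12 for logit p) to keep the optimizer off the degenerate
mixture corners, from the conventional start (0.2, 0.1, 2, 4, 1/3) plus
three jittered restarts (N(0, 0.4) on the transformed scale), best
optimum kept. A fit needs ≥ 50 pairs with a ≥ 1; below that, or on
non-convergence, EBGM is refused rather than silently degraded.
Mixture components are not identifiable under label switching; the
recovery benchmark aligns the fitted components to the reference by
whichever permutation has the smaller summed relative error.

Posterior: q·Gamma(α₁+a, β₁+E) + (1−q)·Gamma(α₂+a, β₂+E) with q from the
marginal NB densities. EBGM = exp(q·[ψ(α₁+a) − ln(β₁+E)] + (1−q)·[ψ(α₂+a)
− ln(β₂+E)]) (ψ the digamma function), i.e. the posterior geometric mean.
Interval bounds solve the posterior mixture CDF at 2.5%/97.5% by bracketed
Brent root-finding (brackets from the component quantiles at 10⁻⁹;
failures raise with the offending (a, E)). The EBGM05 used by the signal
rule is the two-sided 2.5% bound by default, with `two_sided=False`
switching to the conventional one-sided EB05 at 5%. Signal: EBGM05 > 2
and a ≥ 0 — the count condition is kept as conventionally printed even
though it is vacuous.

On small or cleanly separated synthetic pair tables the ML mixture can
legitimately collapse toward two near-point components (very large α, β
with α/β finite); the box bounds keep this finite and the resulting
shrinkage estimates remain well-behaved. Real pair tables with thousands
of heterogeneous pairs yield diffuse components.

## Descriptive table

Ages convert to years by unit code (DEC×10, YR×1, MON÷12, WK÷52.18,
DY÷365.25, HR÷8766); an empty unit with a value present is assumed years;
negative or > 150-year ages are treated as missing. Age bands are 0–18,
19–45, 46–65, 65–100 with 65 assigned to the elder band (the two printed
band labels overlap at 65; this assignment is a package decision).
Reporter codes map MD→Physician, PH→Pharmacist, CN→Consumer,
OT/HP→Other health-professional, anything else (including LW) to missing.
Report year is taken from `fda_dt`, the FDA-stamped deduplication key,
rather than the event date. Percentages are rounded half-away-from-zero
at 2 decimals, which reproduces the published age and reporter rows
exactly; the published sex percentages are not reproducible from their
own printed counts under any standard rounding and are treated as a
source inconsistency, not a target.

## Synthetic generator

Each case independently draws each configured drug as primary suspect
with its marginal probability; each event fires with probability
p_event·RR when a planted (drug, event) pair's drug is present (capped at
1; cap hits beyond 1% of draws set a warning flag), else p_event. This
multiplicative-on-the-conditional model is exactly the alternative the
three statistics estimate, which makes closed-form expected cells
available as test oracles: a = n·p_d·min(1, RR·p_e), b = n·p_d − a,
c = n(1−p_d)·p_e, d = n − a − b − c. Layered on top are the artefacts the
pipeline must survive: duplicate versions (probability 0.19 per case,
matching the ~19% version excess implied by 16.84M raw vs 14.13M
deduplicated reports in the motivating full-database study; 1–2 extra
versions with strictly later dates, plus a tie-injection option for the
primaryid branch), drug-name noise (trade/salt/dose/case variants,
default 30%), concomitant non-PS drug rows (50%), and missingness
defaults matching the published cohort (sex 43%, age 30%, reporter 3%).
Demographics: P(female)=0.474 among non-missing, age ~ N(62, 15²) clipped
to [0, 100] and emitted in mixed units (85% YR, 10% DEC, 5% MON), receipt
dates uniform over 2004-01-01..2021-09-30. Cases drawing no drug receive
a background filler PS drug so every report has ≥ 1 drug row; caseless
reactions receive a filler PT.

What the generator does **not** emulate: polypharmacy correlation
structure, indication-channeling, reporting-rate drift over calendar
time, duplicate reports under *different* caseids, and free-text fields.
Passing tests therefore demonstrate correctness of the counting,
cleaning and estimation machinery under the independence-plus-effect
model — not robustness to real-world confounding.

## Benchmark problem sizes

The planted-signal benchmark uses 200,000 cases with five planted pairs
at RR = 10 (expected pair count 100 each); the null-calibration benchmark
uses 200 drugs × 50 events over 100,000 cases (expected pair count 10,
10,000 pairs); prior recovery uses 50,000 simulated pairs with
E ~ U(0.1, 10). These sizes put every benchmark's Monte-Carlo error well
inside its acceptance margin while keeping a full validation run at a few
minutes on one CPU.

## Known limitations

- The synonym dictionary ships with ~60 entries covering the target
  antineoplastics and common co-medications; real-FAERS use requires a
  fuller dictionary (the TSV format is one synonym–canonical pair per
  line).
- No multiple-comparison correction is applied, matching standard
  disproportionality practice.
- PRR, chi-square, omega and stratified/covariate-adjusted MGPS are out
  of scope, as is the "squashing" acceleration for very large pair
  tables.
- Orphan DRUG/REAC rows (primaryid absent from DEMO) are counted and
  reported but excluded from analysis, which is report-based on DEMO.
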