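# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `bptox` pipeline, in the order the data flow
through it.

## Input model and normalisation

FAERS-style quarterly tables are `$`-delimited text with a header row; the
readers accept the real FAERS column names case-insensitively (including the
legacy `ISR` id).  Every input line becomes either a typed record or a
logged reject with a reason, and the two always sum to the line count, so no
row is ever silently dropped.  Dates are kept as `PartialDate` values with an
explicit precision level (`year`/`month`/`day`); the padded digit string is
the sort key, which makes a month-precision date compare as the earliest
moment it could denote.  Ages are normalised to years at read time
(MON/12, WK/52.18, DY/365.25, DEC×10) because all descriptive strata are in
years.  Drug names and preferred terms are upper-cased and
whitespace-collapsed before any matching; drug matching is then a normalized
substring test, so "ALENDRONATE SODIUM 70 MG" matches the dictionary entry
"ALENDRONATE" without a product-name list.

## Deduplication

One report version survives per CASEID: the one maximising
(FDA_DT, PRIMARYID) lexicographically.  A missing FDA_DT sorts lowest (a
dated version is more informative), and the comparison is on the padded date
string so partial dates participate consistently.  Records without a CASEID
are kept as singletons and logged.  The rule is deterministic under any
input permutation and idempotent; tests verify it against a brute-force
per-group argmax.

## Cohort definition

A report joins a drug's cohort when that drug matches a **primary-suspect**
(PS) DRUG row; secondary-suspect, concomitant and interacting roles never
match.  A report is a *case* when at least one of its reaction PTs falls in
the oesophageal-toxicity SMQ.  A report naming two target drugs as PS
contributes to both cohorts and is logged.  Descriptive percentages use the
drug's full case count as denominator, missing categories included; the age
mean ± SD uses non-missing ages only (sample SD).  Age strata are
[0,18), [18,65), [65,85], (85,∞) — the boundary 85 belongs to the 65–85
stratum, matching the conventional "65–85"/">85" labels.  Yearly report
counts use the FDA receipt year by default (configurable to the event
year); any date precision supplies a year.

The packaged SMQ is a **synthetic stand-in**: the real MedDRA query is
licensed, so the fixture lists 172 plausible oesophageal preferred terms
(reflux disease, oesophagitis variants, ulceration, stenosis, perforation,
neoplasia, investigation findings, …).  Its size and role match the real
object; its exact membership does not.  The same holds for the packaged
PT→SOC map.  Users with a MedDRA licence point the pipeline at their own
two-column files.

## Contingency tables and counting level

The default counting unit is the distinct (report, PT) pair ("event level"),
under which a drug's event count can exceed its case count because one
report may carry several SMQ terms; this is the convention that makes an
"AE numbers" column larger than the case total.  Case-level counting (one
unit per report) is available behind a flag.  The comparator is every other
deduplicated report in the universe, the classical case/non-case design.
Which convention a given published per-SOC scan used is generally not
recoverable; event level is this package's default and both are tested.

## The four algorithms

* **ROR** ad/bc with the Woolf log-scale CI.  No Haldane 0.5 continuity
  correction by default: a zero cell yields an explicit "incomputable" NaN
  rather than a corrected value, because the significance criterion already
  requires a ≥ 3; a `continuity_correction` switch exists.
* **PRR** with the Pearson χ² of the same table, no Yates correction (the
  common PRR convention; switchable).
* **BCPNN IC** in the standard closed form with priors γ11 = 1, α1 = β1 = 1,
  α = β = 2, the joint prior count γ tied to the margins so E(IC) = 0 under
  exact independence; IC025 = E(IC) − 2√V(IC) with the delta-method
  variance.  The closed form is the log of posterior means; it agrees with
  the exact posterior mean of the log (and with a Monte-Carlo beta sampler)
  to well under 0.02 bits once a is a few dozen, which is the regime the
  a ≥ 3-guarded criteria operate in.
* **MGPS EBGM** under a two-component gamma mixture prior on the
  observed/expected ratio λ.  The marginal likelihood of a count is a
  mixture of negative binomials NB(size = αⱼ, prob = βⱼ/(βⱼ+E)); the five
  hyperparameters are fitted by Nelder-Mead in log/logit space.  The
  likelihood has degenerate basins — with mostly-null strata a single
  near-spike component can swallow the mixture — so the fit restarts from a
  fixed set of four starting points (the classical (0.2, 0.1, 2.0, 4.0, ⅓),
  two generic spreads, and a data-driven split at the median and upper-decile
  observed ratios) and keeps the best optimum; everything is deterministic
  and the result is never worse than its starting point.  EBGM is the
  posterior geometric mean `exp(Σⱼ wⱼ(ψ(αⱼ+a) − ln(βⱼ+E)))`; EBGM05 solves
  the posterior-mixture CDF at 0.05 by Brent root-finding to 10⁻¹²,
  bracketed by the component 4.9%/5.1% quantiles.

Joint significance is the conjunction of ROR (a ≥ 3, CI low > 1), PRR
(PRR ≥ 2, χ² ≥ 4), BCPNN (IC025 > 0) and MGPS (EBGM05 > 2).  The EBGM05
threshold of 2 is the conservative end of published practice.  All
thresholds live in `SignalCriteria` and the YAML config, not in code paths.

## Time-to-onset

Onset is the day count from the earliest day-precision therapy start of the
matched drug's THER rows (falling back to any THER row when sequence linkage
is absent) to the day-precision event date.  Month- or year-precision dates
and negative intervals are excluded, each with a logged reason; same-day
onset (0 days) is retained as valid.  All retained records are treated as
events — a spontaneous report exists because the event occurred — so there
is no censoring and the Kaplan–Meier curve equals the empirical survivor
function; the median is the first time cumulative incidence reaches 0.5.
Curves and the k-sample log-rank test come from lifelines.

## Outcomes

A case counts once per outcome kind it reports (HO and DE can both apply).
Pairwise contrasts are 2×2 Pearson χ² without Yates correction, raw
p-values by default (a Bonferroni option exists); a test with an expected
cell below 1 is flagged unreliable, never suppressed.

## The synthetic generator

*Stochastic mode* samples per-report drug (multinomial marginals), 1–3
preferred terms from per-drug weights — the injected signal matrix
multiplies a (drug, PT) weight by a rate ratio RR — demographics with
configurable missingness, lognormal onset times per drug, Bernoulli
outcomes, and duplicate CASEID clusters whose earlier versions carry
strictly earlier receipt dates, so the intended survivor set is exactly
recoverable.  A ground-truth ledger records everything per case.  Identical
seed and config give byte-identical files.

Because the per-report PT distribution renormalises, the pair-level odds
ratio implied for an injected (drug, PT) differs slightly from the nominal
RR; `validation.implied_pair_odds_ratio` computes the implied value exactly
and CI-coverage checks target it.  The injection experiments keep the event's
baseline share near 0.5% of pairs so the two scales nearly coincide
(nominal 8.0 → implied 8.00).

*Exact mode* (`paper_fixture`) deterministically expands fixed cell counts:
per-drug report totals 30,735/6,189/4,666, case totals 3,039/281/177, the
full sex/age/reporter/country case breakdowns, event totals 3,621/361/196
(extra SMQ terms on the leading cases), hospitalization/death counts
1,143/89/26 and 67/6/2, and onset samples of size 847/88/19 drawn as
mid-point lognormal quantiles (σ = 1.4) around medians 346/126/28 days —
quantile expansion makes the fixture non-flaky while an even-sized group's
KM median lands one quantile step from its target (risedronate: 124 vs 126).
The hospitalization count 89 for risedronate is the integer whose rate is
closest to the printed 31.5% (no integer over 281 yields it exactly).  The
background universe defaults to 500,000 non-bisphosphonate reports with an
0.5% SMQ share — large enough that each drug's comparator is dominated by
background reporting, as in a real database, while staying desk-sized; a
×1/10 `scaled` variant exists for quick runs.  A small block of duplicate
earlier versions exercises deduplication without changing post-dedup counts.

What the generator does **not** emulate: misspelled free text beyond
case/spacing/suffix variants, indication-driven channelling, reporting-rate
drift over calendar time, correlated demographics, polypharmacy beyond one
suspect drug per report.  Passing tests therefore demonstrate correctness of
the *computations* and calibration under the stated generative model, not
robustness to every real-data pathology.

## Validation experiments and the sizes used

* Null calibration: the default three-drug universe at 50,000 reports with
  every RR = 1; the joint criterion fires on ≤ 1% of drug-event pairs
  (observed: 0 of ~264).
* Injection: 100 replicates of a 10,000-report two-drug universe with one
  RR = 8 pair (a ≈ 140 per replicate); detection and 95%-CI coverage of the
  implied odds ratio are ≥ 95% / ≥ 93%.
* MGPS recovery: 5,000 (a, E) pairs simulated from the classical prior
  (0.2, 0.1, 2.0, 4.0, ⅓); the re-fit — started from a deliberately
  different point — reaches marginal log-likelihood within 1 unit of the
  generating prior's (it typically exceeds it slightly, as five free
  parameters allow).
* Log-rank: type-I error over 2,000 two-group replicates (n = 30 each) lies
  in [0.03, 0.07] at α = 0.05; the three-group configuration with the
  reported medians and usable-record counts separates at p < 10⁻⁴ in ≥ 95%
  of 50 replicates.

These sizes keep the full validation run at a few minutes on one CPU while
leaving comfortable Monte-Carlo margins around each acceptance band.

## Known limitations

Disproportionality measures reporting asymmetry, not incidence or causality;
the synthetic background universe is orders of magnitude smaller than a real
20-million-report database, so the *magnitudes* of ROR/PRR/IC/EBGM computed
on the fixture are not comparable to values published from the full corpus —
only the qualitative structure (all three drugs jointly significant, the
ranking of onset medians, the outcome-contrast pattern) carries over.  The
packaged SMQ and SOC map are synthetic stand-ins.  Stratified (age/sex/year)
MGPS, fuzzy cross-CASEID duplicate linkage, and route-based formulation
filtering are out of scope; the DRUG route field is exposed so a caller can
pre-filter.
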