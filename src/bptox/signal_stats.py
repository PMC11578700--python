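"""Disproportionality statistics for spontaneous-report signal detection.

Every statistic operates on the standard case/non-case 2x2 contingency table

    ==============  =============  ==============
                    event of        all other
                    interest        events
    ==============  =============  ==============
    target drug     a              b
    other drugs     c              d
    ==============  =============  ==============

built either at *event* level (the unit is a distinct (report, PT) pair; this
is the convention under which a drug's "AE number" can exceed its case count,
because one report may carry several PTs of the event set) or at *case* level
(the unit is a report).

Four algorithms are implemented, and a drug-event pair is called a joint
signal only when all four flag it simultaneously:

ROR
    reporting odds ratio ad/bc with a Woolf (log-scale normal) 95% CI.
PRR
    proportional reporting ratio [a/(a+b)] / [c/(c+d)], conventionally paired
    with the Pearson chi-square of the same table (no Yates correction by
    default).
BCPNN IC
    information component, the log2 observed-to-expected joint reporting
    probability under the Bayesian confidence propagation neural network with
    the standard closed-form beta priors (gamma11 = 1, alpha1 = beta1 = 1,
    alpha = beta = 2); IC025 = E(IC) - 2 sqrt(V(IC)).
MGPS EBGM
    empirical-Bayes geometric mean of the observed/expected reporting ratio
    under a two-component gamma mixture prior whose five hyperparameters are
    fitted by maximising the negative-binomial marginal likelihood over all
    drug-event strata; EBGM05 is the 5th percentile of the posterior mixture.

Zero cells make ROR/PRR incomputable (NaN) unless the optional Haldane 0.5
continuity correction is requested; the Bayesian statistics are regularised
by their priors and never need it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import CaseFlag, SafetyReport
from .io_faers import PtSocMap, SmqDefinition

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "UNMAPPED"


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


class ReportUniverse:
    """All deduplicated reports as a distinct (report, PT) pair frame.

    Holds the exploded reaction pairs once so that repeated table building and
    whole-vocabulary scans stay vectorised.
    """

    def __init__(self, pairs: pd.DataFrame, report_ids: Sequence[str]):
        self.pairs = pairs.drop_duplicates(ignore_index=True)
        self.report_ids = pd.Index(report_ids).unique()

    @classmethod
    def from_reports(cls, reports: Iterable[SafetyReport]) -> "ReportUniverse":
        ids, pids, pts = [], [], []
        for rep in reports:
            ids.append(rep.primaryid)
            for pt in rep.pts:
                pids.append(rep.primaryid)
                pts.append(pt)
        return cls(pd.DataFrame({"primaryid": pids, "pt": pts}), ids)

    @classmethod
    def from_frames(cls, demo: pd.DataFrame, reac: pd.DataFrame) -> "ReportUniverse":
        return cls(reac[["primaryid", "pt"]], demo["primaryid"])

    @property
    def n_reports(self) -> int:
        return len(self.report_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_table(
    case_flags: Iterable[CaseFlag],
    universe: ReportUniverse,
    target_drug: str,
    event_pts: Iterable[str],
    counting_level: str = "event",
) -> ContingencyTable:
    """2x2 table for (target_drug, event_pts) against the rest of the universe.

    Event level counts each distinct (report, matched PT) pair once; case
    level counts each report once.
    """
    if universe.n_reports == 0:
        raise ValueError("empty report universe")
    target_ids = {f.primaryid for f in case_flags if f.drug == target_drug}
    return build_table_for_ids(universe, target_ids, set(event_pts), counting_level)


def build_table_for_ids(
    universe: ReportUniverse,
    target_ids: set[str],
    event_pts: set[str],
    counting_level: str = "event",
) -> ContingencyTable:
    pairs = universe.pairs
    is_target = pairs["primaryid"].isin(target_ids).to_numpy()
    is_event = pairs["pt"].isin(event_pts).to_numpy()
    if counting_level == "event":
        a = int(np.sum(is_target & is_event))
        b = int(np.sum(is_target & ~is_event))
        c = int(np.sum(~is_target & is_event))
        d = int(np.sum(~is_target & ~is_event))
        return ContingencyTable(a, b, c, d)
    if counting_level == "case":
        event_ids = set(pairs.loc[is_event, "primaryid"])
        n_target = len(universe.report_ids.intersection(list(target_ids)))
        a = len(event_ids & target_ids)
        b = n_target - a
        c = len(event_ids) - a
        d = universe.n_reports - a - b - c
        return ContingencyTable(a, b, c, d)
    raise ValueError(f"unknown counting_level {counting_level!r}")


# ---------------------------------------------------------------------------
# Frequentist statistics
# ---------------------------------------------------------------------------

def ror(table: ContingencyTable, continuity_correction: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI: exp(ln ROR ± 1.96 se).

    A zero cell yields (nan, nan, nan) unless the Haldane 0.5 correction is
    requested.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            return (math.nan, math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (estimate, estimate * math.exp(-1.959963984540054 * se), estimate * math.exp(1.959963984540054 * se))


def prr_chi2(
    table: ContingencyTable, continuity_correction: bool = False, yates: bool = False
) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square (df = 1).

    PRR is incomputable (nan) when a margin is degenerate or c = 0 (without
    the optional continuity correction); the chi-square uses no Yates
    correction unless asked.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if continuity_correction and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    prr = math.nan
    if row1 > 0 and row2 > 0 and c > 0:
        prr = (a / row1) / (c / row2)
    chi2 = math.nan
    if min(row1, row2, col1, col2) > 0:
        diff = abs(a * d - b * c)
        if yates:
            diff = max(diff - n / 2, 0.0)
        chi2 = n * diff * diff / (row1 * row2 * col1 * col2)
    return (prr, chi2)


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

# standard closed-form prior choice
_G11, _A1, _B1, _A, _B = 1.0, 1.0, 1.0, 2.0, 2.0
_LN2 = math.log(2.0)


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float]:
    """Information component E(IC) and its lower bound IC025 = E - 2 sqrt(V).

    Closed-form posterior moments with beta priors p11 ~ Beta(g11, g - g11),
    p1. ~ Beta(a1, A - a1), p.1 ~ Beta(b1, B - b1) where the joint prior count
    g is tied to the margins so that E(IC) = 0 under exact independence.
    """
    a, n = float(table.a), float(table.n)
    r1 = float(table.a + table.b)  # target-drug margin
    c1 = float(table.a + table.c)  # event margin
    gamma = _G11 * (n + _A) * (n + _B) / ((r1 + _A1) * (c1 + _B1))
    e_ic = math.log((a + _G11) * (n + _A) * (n + _B) / ((n + gamma) * (r1 + _A1) * (c1 + _B1))) / _LN2
    v = (
        (n - a + gamma - _G11) / ((a + _G11) * (1 + n + gamma))
        + (n - r1 + _A - _A1) / ((r1 + _A1) * (1 + n + _A))
        + (n - c1 + _B - _B1) / ((c1 + _B1) * (1 + n + _B))
    ) / (_LN2 * _LN2)
    return (e_ic, e_ic - 2.0 * math.sqrt(v))


# ---------------------------------------------------------------------------
# MGPS: gamma-Poisson shrinker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the reporting-rate ratio lambda.

    Component j is Gamma(shape alpha_j, rate beta_j); p_mix is the weight of
    component 1.  The classical prior expresses "most pairs are near the null,
    a few are elevated".
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must be in (0, 1)")


DEFAULT_MGPS_START = MgpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p_mix=1.0 / 3.0)


def _mixture_logpmf(prior: MgpsPrior, a: np.ndarray, e: np.ndarray) -> np.ndarray:
    """log marginal pmf of observed counts: mixture of negative binomials.

    Poisson(lambda * E) with lambda ~ Gamma(alpha, beta) marginalises to
    NB(size = alpha, prob = beta / (beta + E)).
    """
    lp1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    return np.logaddexp(np.log(prior.p_mix) + lp1, np.log1p(-prior.p_mix) + lp2)


def mgps_marginal_loglik(prior: MgpsPrior, a: np.ndarray, e: np.ndarray) -> float:
    return float(np.sum(_mixture_logpmf(prior, np.asarray(a), np.asarray(e))))


def _tables_to_arrays(tables) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tables, tuple) and len(tables) == 2:
        a, e = (np.asarray(x, dtype=float) for x in tables)
    else:
        tabs = list(tables)
        a = np.array([t.a for t in tabs], dtype=float)
        e = np.array([t.expected for t in tabs], dtype=float)
    keep = e > 0
    return a[keep], e[keep]


def fit_mgps_prior(
    tables,
    start: MgpsPrior = DEFAULT_MGPS_START,
) -> MgpsPrior:
    """Fit the five hyperparameters by maximum marginal likelihood.

    ``tables`` is either a sequence of ContingencyTable or an ``(a, E)`` array
    pair.  Optimisation runs in log/logit-transformed space.  Because the
    mixture likelihood has degenerate basins (a single near-spike component
    can swallow the mixture when most strata are null), the search restarts
    from a fixed set of starting points — the supplied one, two generic
    spreads, and a data-driven split at the median and upper-decile observed
    ratios — and keeps the best optimum.  Everything is deterministic.
    """
    a, e = _tables_to_arrays(tables)
    if len(a) < 2:
        raise ValueError("need at least 2 strata with positive expected count")

    def unpack(theta):
        return MgpsPrior(
            alpha1=math.exp(theta[0]),
            beta1=math.exp(theta[1]),
            alpha2=math.exp(theta[2]),
            beta2=math.exp(theta[3]),
            p_mix=special.expit(theta[4]),
        )

    def neg_loglik(theta):
        if np.abs(theta).max() > 35:  # keep the search off the spike ridge
            return 1e300
        prior = unpack(theta)
        ll = mgps_marginal_loglik(prior, a, e)
        return 1e300 if not np.isfinite(ll) else -ll

    ratios = np.sort(a / e)
    m_lo = max(float(ratios[len(ratios) // 2]), 0.05)
    m_hi = max(float(ratios[int(len(ratios) * 0.9)]), 2.0 * m_lo)
    starts = [
        start,
        MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5),
        MgpsPrior(2.0, 2.0, 0.5, 0.1, 0.8),
        MgpsPrior(2.0, 2.0 / m_lo, 2.0, 2.0 / m_hi, 0.8),
    ]
    best = None
    for s in starts:
        theta0 = np.array(
            [math.log(s.alpha1), math.log(s.beta1), math.log(s.alpha2), math.log(s.beta2),
             special.logit(s.p_mix)]
        )
        res = optimize.minimize(
            neg_loglik,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000, "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"MGPS prior fit failed: {best.message}")
    if -best.fun < mgps_marginal_loglik(start, a, e) - 1e-6:
        raise RuntimeError("MGPS optimiser returned a point worse than its start")
    return unpack(best.x)


def _posterior_mixture(prior: MgpsPrior, a: float, e: float):
    """Posterior over lambda given count a: gamma mixture with updated weights."""
    lw1 = math.log(prior.p_mix) + float(stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e)))
    lw2 = math.log1p(-prior.p_mix) + float(stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e)))
    m = max(lw1, lw2)
    w1 = math.exp(lw1 - m)
    w2 = math.exp(lw2 - m)
    w1, w2 = w1 / (w1 + w2), w2 / (w1 + w2)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + e, prior.beta2 + e)
    return (w1, w2), shapes, rates


def ebgm(table: ContingencyTable | tuple[float, float], prior: MgpsPrior) -> tuple[float, float]:
    """Posterior geometric mean EBGM and 5th percentile EBGM05 of lambda.

    EBGM = exp(E[ln lambda | a]) in closed form via digamma; EBGM05 solves
    posterior CDF(q) = 0.05 by root-finding on the gamma-mixture CDF.
    """
    if isinstance(table, ContingencyTable):
        a, e = float(table.a), table.expected
    else:
        a, e = (float(x) for x in table)
    if e <= 0:
        raise ValueError("expected count must be positive")
    (w1, w2), shapes, rates = _posterior_mixture(prior, a, e)
    e_log = w1 * (special.digamma(shapes[0]) - math.log(rates[0])) + w2 * (
        special.digamma(shapes[1]) - math.log(rates[1])
    )
    point = math.exp(e_log)

    def cdf(q):
        return w1 * stats.gamma.cdf(q, shapes[0], scale=1.0 / rates[0]) + w2 * stats.gamma.cdf(
            q, shapes[1], scale=1.0 / rates[1]
        )

    lo = min(stats.gamma.ppf(0.049, shapes[0], scale=1.0 / rates[0]),
             stats.gamma.ppf(0.049, shapes[1], scale=1.0 / rates[1]))
    hi = max(stats.gamma.ppf(0.051, shapes[0], scale=1.0 / rates[0]),
             stats.gamma.ppf(0.051, shapes[1], scale=1.0 / rates[1]))
    lo = max(lo, 1e-300)
    q05 = float(optimize.brentq(lambda q: cdf(q) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return (point, q05)


# ---------------------------------------------------------------------------
# Joint evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm significance thresholds; joint signal = all four true."""

    min_count: int = 3
    ror_ci_low_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    continuity_correction: bool = False


DEFAULT_CRITERIA = SignalCriteria()


@dataclass
class SignalScores:
    drug: str
    level: str
    term: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_mgps: bool = False

    @property
    def joint_significant(self) -> bool:
        return self.flag_ror and self.flag_prr and self.flag_bcpnn and self.flag_mgps

    def as_row(self) -> dict:
        row = {k: getattr(self, k) for k in (
            "drug", "level", "term", "a", "b", "c", "d",
            "ror", "ror_ci_low", "ror_ci_high", "prr", "chi2",
            "ic", "ic025", "ebgm", "ebgm05",
            "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps",
        )}
        row["joint_significant"] = self.joint_significant
        return row


def score_table(
    table: ContingencyTable,
    prior: MgpsPrior,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    drug: str = "",
    level: str = "",
    term: str = "",
) -> SignalScores:
    ror_v, lo, hi = ror(table, continuity_correction=criteria.continuity_correction)
    prr_v, chi2_v = prr_chi2(table, continuity_correction=criteria.continuity_correction)
    ic_v, ic025_v = bcpnn_ic(table)
    if table.expected > 0:
        ebgm_v, ebgm05_v = ebgm(table, prior)
    else:  # empty drug or event margin: no expected count to shrink against
        ebgm_v = ebgm05_v = math.nan
    s = SignalScores(
        drug=drug, level=level, term=term,
        a=table.a, b=table.b, c=table.c, d=table.d,
        ror=ror_v, ror_ci_low=lo, ror_ci_high=hi,
        prr=prr_v, chi2=chi2_v, ic=ic_v, ic025=ic025_v,
        ebgm=ebgm_v, ebgm05=ebgm05_v,
    )
    enough = table.a >= criteria.min_count
    s.flag_ror = bool(enough and np.isfinite(lo) and lo > criteria.ror_ci_low_gt)
    s.flag_prr = bool(
        enough
        and np.isfinite(prr_v)
        and np.isfinite(chi2_v)
        and prr_v >= criteria.prr_ge
        and chi2_v >= criteria.chi2_ge
    )
    s.flag_bcpnn = bool(ic025_v > criteria.ic025_gt)
    s.flag_mgps = bool(ebgm05_v > criteria.ebgm05_gt)
    return s


def evaluate_signals(
    tables: Mapping[tuple[str, str, str], ContingencyTable],
    prior: MgpsPrior,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> list[SignalScores]:
    """Score a batch of tables keyed by (drug, level, term)."""
    return [
        score_table(t, prior, criteria, drug=drug, level=level, term=term)
        for (drug, level, term), t in tables.items()
    ]


# ---------------------------------------------------------------------------
# Whole-vocabulary scan
# ---------------------------------------------------------------------------

def _term_tables(
    universe: ReportUniverse,
    target_ids: set[str],
    term_of_pt: Mapping[str, str] | None,
    counting_level: str,
    restrict_pts: set[str] | None = None,
) -> dict[str, ContingencyTable]:
    """One table per term, where a PT's term is itself (PT level) or its SOC."""
    pairs = universe.pairs
    if restrict_pts is not None:
        pairs = pairs[pairs["pt"].isin(restrict_pts)]
    if term_of_pt is None:
        term = pairs["pt"]
    else:
        term = pairs["pt"].map(lambda p: term_of_pt.get(p, UNMAPPED_SOC))
    tables: dict[str, ContingencyTable] = {}
    if counting_level == "event":
        grand_a = universe.n_pairs
        is_target = universe.pairs["primaryid"].isin(target_ids).to_numpy()
        row1 = int(is_target.sum())  # target (report, PT) pairs in the whole universe
        df = pd.DataFrame({"term": term, "target": pairs["primaryid"].isin(target_ids)})
        grouped = df.groupby("term")["target"].agg(["sum", "count"])
        for t, (a, tot) in grouped.iterrows():
            a = int(a)
            tot = int(tot)
            tables[t] = ContingencyTable(a, row1 - a, tot - a, grand_a - row1 - (tot - a))
    elif counting_level == "case":
        n_reports = universe.n_reports
        n_target = len(universe.report_ids.intersection(list(target_ids)))
        df = pd.DataFrame(
            {"term": term, "primaryid": pairs["primaryid"], "target": pairs["primaryid"].isin(target_ids)}
        ).drop_duplicates(["term", "primaryid"])
        grouped = df.groupby("term")["target"].agg(["sum", "count"])
        for t, (a, tot) in grouped.iterrows():
            a = int(a)
            c = int(tot) - a
            tables[t] = ContingencyTable(a, n_target - a, c, n_reports - n_target - c)
    else:
        raise ValueError(f"unknown counting_level {counting_level!r}")
    return tables


def scan(
    case_flags: Iterable[CaseFlag],
    universe: ReportUniverse,
    levels: Sequence[str],
    pt_soc_map: PtSocMap,
    smq: SmqDefinition,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    counting_level: str = "event",
    prior: MgpsPrior | None = None,
    top_k: int | None = None,
) -> dict[str, list[SignalScores]]:
    """Score (drug, term) pairs at the requested levels: SMQ, SOC and/or PT.

    The MGPS prior, unless supplied, is fitted once on the full (drug, PT)
    stratification of the universe.  PT-level output is ranked by the event
    count ``a`` descending with alphabetical tie-break; ``top_k`` truncates
    that ranking.  PTs absent from the SOC map are bucketed under
    ``UNMAPPED`` and logged.
    """
    flags = list(case_flags)
    drugs = sorted({f.drug for f in flags})
    ids_of = {d: {f.primaryid for f in flags if f.drug == d} for d in drugs}

    if prior is None:
        strata: list[tuple[float, float]] = []
        for d in drugs:
            for t in _term_tables(universe, ids_of[d], None, counting_level).values():
                strata.append((t.a, t.expected))
        arr = np.array(strata, dtype=float)
        prior = fit_mgps_prior((arr[:, 0], arr[:, 1]))

    unmapped = {p for p in universe.pairs["pt"].unique() if pt_soc_map.soc_of(p) is None}
    if unmapped:
        logger.info("%d PTs absent from SOC map bucketed as %s", len(unmapped), UNMAPPED_SOC)

    out: dict[str, list[SignalScores]] = {}
    for level in levels:
        level = level.upper()
        rows: list[SignalScores] = []
        for d in drugs:
            if level == "SMQ":
                table = build_table_for_ids(universe, ids_of[d], set(smq.pts), counting_level)
                rows.append(score_table(table, prior, criteria, drug=d, level="SMQ", term=smq.smq_name))
            elif level == "SOC":
                term_of = dict(pt_soc_map.mapping)
                for t, tab in sorted(_term_tables(universe, ids_of[d], term_of, counting_level).items()):
                    rows.append(score_table(tab, prior, criteria, drug=d, level="SOC", term=t))
            elif level == "PT":
                tabs = _term_tables(universe, ids_of[d], None, counting_level, restrict_pts=set(smq.pts))
                ranked = sorted(tabs.items(), key=lambda kv: (-kv[1].a, kv[0]))
                if top_k is not None:
                    ranked = ranked[:top_k]
                for t, tab in ranked:
                    rows.append(score_table(tab, prior, criteria, drug=d, level="PT", term=t))
            else:
                raise ValueError(f"unknown level {level!r}")
        out[level] = rows
    return out
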