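"""Synthetic FAERS-like data with known ground truth.

Two modes:

*stochastic*
    :func:`generate` samples reports from a :class:`SynthConfig` — per-drug
    marginal probabilities, per-PT baseline reporting probabilities, an
    injected drug-event signal matrix of multiplicative reporting-rate
    ratios, duplicate CASEID clusters, missingness in sex/age/dates, per-drug
    lognormal time-to-onset distributions and per-drug outcome probabilities.
    A ground-truth ledger records, per case, the drug, its PTs, duplicate
    cluster membership, the true onset interval and the true outcome flags,
    so every pipeline stage can be scored exactly.

*exact*
    :func:`printed_counts_fixture` deterministically expands a fixed table of cell
    counts into report rows, so that descriptive statistics computed from the
    generated files are exact, not Monte-Carlo.  The expanded counts are the
    published totals of a large pharmacovigilance study of oral
    bisphosphonate oesophageal toxicity: per-drug report totals
    30,735 / 6,189 / 4,666 for alendronate / risedronate / ibandronate,
    per-drug oesophageal case totals 3,039 / 281 / 177, the full
    sex / age-stratum / reporter / country breakdowns of those cases,
    hospitalization and death counts matching the printed rates, and
    per-drug onset-time samples (n = 847 / 88 / 19) drawn as deterministic
    lognormal quantiles around medians 346 / 126 / 28 days.

Both modes emit the five quarterly-style tables in the ``$``-delimited
dialect, so the synthetic data exercises exactly the same readers as a real
download.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .io_faers import PtSocMap, SmqDefinition, read_pt_soc_map, read_smq

TARGET_DRUGS = ("ALENDRONATE", "RISEDRONATE", "IBANDRONATE")


def data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("bptox") / "data" / name))


def packaged_smq() -> SmqDefinition:
    """The packaged synthetic oesophageal-toxicity SMQ (172 PTs)."""
    return read_smq(data_path("smq_oesophageal_synthetic.csv"))


def packaged_pt_soc_map() -> PtSocMap:
    return read_pt_soc_map(data_path("pt_soc_map_synthetic.csv"))


def packaged_drug_dictionary() -> dict[str, str]:
    from .io_faers import read_drug_dictionary

    return read_drug_dictionary(data_path("drug_dictionary.csv"))


@dataclass
class SynthFrames:
    """Generator output: the five FAERS-style tables plus the truth ledger."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    ledger: pd.DataFrame


# ---------------------------------------------------------------------------
# Stochastic mode
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Full parameterization of the stochastic generator.

    ``drugs`` maps drug name to its marginal report probability (must sum to
    1); ``pts`` maps preferred term to its baseline relative reporting
    weight; ``signal`` multiplies a (drug, pt) weight by a reporting-rate
    ratio RR > 0.  Same seed and config give byte-identical output.
    """

    seed: int = 0
    n_reports: int = 10_000
    drugs: dict[str, float] = field(default_factory=dict)
    pts: dict[str, float] = field(default_factory=dict)
    signal: dict[tuple[str, str], float] = field(default_factory=dict)
    n_pts_dist: tuple[float, ...] = (0.65, 0.25, 0.10)  # P(1), P(2), P(3) PTs per report
    duplicate_rate: float = 0.0
    extra_versions_mean: float = 1.0  # mean number of extra versions per duplicated case
    missing_sex: float = 0.08
    missing_age: float = 0.25
    missing_event_dt: float = 0.3
    missing_start_dt: float = 0.3
    female_prob: dict[str, float] = field(default_factory=dict)  # per drug, default 0.6
    age_mean: float = 68.0
    age_sd: float = 12.0
    # drug -> (median_days, lognormal sigma); drugs absent get no THER rows
    tto: dict[str, tuple[float, float]] = field(default_factory=dict)
    # drug -> {"HO": p, "DE": p}
    outcome_probs: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.drugs and abs(sum(self.drugs.values()) - 1.0) > 1e-9:
            raise ValueError("drug marginal probabilities must sum to 1")
        if any(rr <= 0 for rr in self.signal.values()):
            raise ValueError("signal rate ratios must be positive")
        unknown = {d for d, _ in self.signal} - set(self.drugs) | {p for _, p in self.signal} - set(self.pts)
        if unknown:
            raise ValueError(f"signal refers to unknown drugs/PTs: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "signal" in raw:
            raw["signal"] = {(d, p): rr for d, p, rr in raw["signal"]}
        if "tto" in raw:
            raw["tto"] = {d: tuple(v) for d, v in raw["tto"].items()}
        for key in ("n_pts_dist",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_config(seed: int = 0, n_reports: int = 10_000) -> SynthConfig:
    """A realistic small-universe default: three target drugs against a
    background of common products, oesophageal signal injected for all three."""
    smq_pts = sorted(packaged_smq().pts)[:30]
    soc_map = packaged_pt_soc_map().mapping
    background_pts = sorted(set(soc_map) - set(packaged_smq().pts))
    drugs = {"ALENDRONATE": 0.06, "RISEDRONATE": 0.02, "IBANDRONATE": 0.015}
    n_bg = 15
    for i in range(n_bg):
        drugs[f"BACKGROUND DRUG {i + 1:02d}"] = (1.0 - sum(drugs.values())) / (n_bg - i)
    pts = {p: 1.0 for p in background_pts}
    pts.update({p: 0.05 for p in smq_pts})
    signal = {(d, p): 8.0 for d in TARGET_DRUGS for p in smq_pts[:10]}
    return SynthConfig(
        seed=seed,
        n_reports=n_reports,
        drugs=drugs,
        pts=pts,
        signal=signal,
        duplicate_rate=0.1,
        extra_versions_mean=1.0,
        female_prob={d: 0.85 for d in TARGET_DRUGS},
        tto={"ALENDRONATE": (346, 1.4), "RISEDRONATE": (126, 1.4), "IBANDRONATE": (28, 1.4)},
        outcome_probs={
            "ALENDRONATE": {"HO": 0.376, "DE": 0.022},
            "RISEDRONATE": {"HO": 0.315, "DE": 0.022},
            "IBANDRONATE": {"HO": 0.148, "DE": 0.011},
        },
    )


def _fmt_dates(ordinals: np.ndarray) -> np.ndarray:
    """datetime64[D] day numbers since epoch → YYYYMMDD strings."""
    days = ordinals.astype("datetime64[D]")
    return pd.DatetimeIndex(days).strftime("%Y%m%d").to_numpy()


def generate(config: SynthConfig) -> SynthFrames:
    """Sample a synthetic universe; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = list(config.drugs)
    pt_names = np.array(list(config.pts))
    base_w = np.array([config.pts[p] for p in pt_names], dtype=float)

    caseid = np.arange(1, n + 1)
    primaryid = caseid * 100 + 99  # originals always carry the highest version suffix
    drug_idx = rng.choice(len(drug_names), size=n, p=[config.drugs[d] for d in drug_names])
    drug_arr = np.array(drug_names)[drug_idx]

    # --- reactions: k PTs per report, drug-specific weights with injected RR
    k = rng.choice(np.arange(1, len(config.n_pts_dist) + 1), size=n, p=config.n_pts_dist)
    rep_for_pair = np.repeat(np.arange(n), k)
    pt_pick = np.empty(rep_for_pair.shape[0], dtype=int)
    for gi, gname in enumerate(drug_names):
        w = base_w.copy()
        for (d, p), rr in config.signal.items():
            if d == gname:
                w[pt_names == p] *= rr
        w /= w.sum()
        mask = drug_idx[rep_for_pair] == gi
        pt_pick[mask] = rng.choice(len(pt_names), size=int(mask.sum()), p=w)
    reac = pd.DataFrame(
        {"primaryid": primaryid[rep_for_pair].astype(str), "pt": pt_names[pt_pick]}
    ).drop_duplicates(ignore_index=True)
    pts_per_case = reac.groupby("primaryid")["pt"].agg(";".join)

    # --- demographics
    female_p = np.array([config.female_prob.get(d, 0.6) for d in drug_arr])
    sex = np.where(rng.random(n) < female_p, "F", "M")
    sex = np.where(rng.random(n) < config.missing_sex, "", sex)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 1, 100).round(0)
    age_str = np.where(rng.random(n) < config.missing_age, "", age.astype(int).astype(str))
    occp = rng.choice(["CN", "MD", "OT", "PH", "HP", "LW"], size=n, p=[0.38, 0.36, 0.14, 0.04, 0.02, 0.06])
    country = rng.choice(["US", "GB", "CA", "AU", "JP", "DE", "FR"], size=n,
                         p=[0.78, 0.05, 0.04, 0.02, 0.02, 0.05, 0.04])

    # --- therapy start / event onset / receipt dates
    epoch0 = np.datetime64("2004-01-01").astype("datetime64[D]").astype(int)
    start_ord = epoch0 + rng.integers(0, 6900, size=n)
    tto_days = np.full(n, -1, dtype=int)
    for d, (median, sigma) in config.tto.items():
        mask = drug_arr == d
        z = rng.standard_normal(int(mask.sum()))
        tto_days[mask] = np.maximum(0, np.rint(median * np.exp(sigma * z))).astype(int)
    has_tto = tto_days >= 0
    event_ord = np.where(has_tto, start_ord + np.maximum(tto_days, 0), start_ord + rng.integers(0, 200, size=n))
    fda_ord = event_ord + rng.integers(1, 90, size=n)

    event_dt = _fmt_dates(event_ord)
    event_dt = np.where(rng.random(n) < config.missing_event_dt, "", event_dt)
    start_dt = _fmt_dates(start_ord)
    start_missing = rng.random(n) < config.missing_start_dt
    # a slice of non-missing start dates is degraded to month precision
    partial = (~start_missing) & (rng.random(n) < 0.1)
    start_dt = np.where(start_missing, "", np.where(partial, [s[:6] for s in start_dt], start_dt))

    demo = pd.DataFrame(
        {
            "primaryid": primaryid.astype(str),
            "caseid": caseid.astype(str),
            "fda_dt": _fmt_dates(fda_ord),
            "event_dt": event_dt,
            "sex": sex,
            "age": age_str,
            "age_cod": np.where(age_str == "", "", "YR"),
            "occp_cod": occp,
            "occr_country": country,
        }
    )

    # free-text noise the reader must normalise away
    suffix = rng.choice(["", " SODIUM", " 70 MG", "  TABLET"], size=n, p=[0.5, 0.25, 0.15, 0.1])
    drugname = np.char.add(drug_arr.astype(str), suffix.astype(str))
    drug_tbl = pd.DataFrame(
        {
            "primaryid": primaryid.astype(str),
            "drug_seq": "1",
            "role_cod": "PS",
            "drugname": drugname,
            "route": np.where(np.isin(drug_arr, TARGET_DRUGS), "ORAL", "UNKNOWN"),
        }
    )

    ther = pd.DataFrame(
        {"primaryid": primaryid.astype(str), "dsg_drug_seq": "1", "start_dt": start_dt}
    )
    ther = ther[ther["start_dt"] != ""].reset_index(drop=True)

    # --- outcomes
    outc_rows = []
    for code in ("HO", "DE"):
        p = np.array([config.outcome_probs.get(d, {}).get(code, 0.0) for d in drug_arr])
        hit = rng.random(n) < p
        outc_rows.append(pd.DataFrame({"primaryid": primaryid[hit].astype(str), "outc_cod": code}))
    outc = pd.concat(outc_rows, ignore_index=True) if outc_rows else pd.DataFrame(columns=["primaryid", "outc_cod"])

    # --- duplicate clusters: earlier versions that deduplication must drop
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_idx = np.flatnonzero(dup_mask)
    extra_frames = []
    if dup_idx.size and config.extra_versions_mean > 0:
        n_extra = rng.geometric(1.0 / max(config.extra_versions_mean, 1.0), size=dup_idx.size)
        rep_idx = np.repeat(dup_idx, n_extra)
        version = np.concatenate([np.arange(1, m + 1) for m in n_extra])
        extra_pid = caseid[rep_idx] * 100 + version
        extra_fda = fda_ord[rep_idx] - rng.integers(30, 400, size=rep_idx.size)
        extra_demo = demo.iloc[rep_idx].copy()
        extra_demo["primaryid"] = extra_pid.astype(str)
        extra_demo["fda_dt"] = _fmt_dates(extra_fda)
        extra_frames.append(("demo", extra_demo))
        extra_drug = drug_tbl.iloc[rep_idx].copy()
        extra_drug["primaryid"] = extra_pid.astype(str)
        extra_frames.append(("drug", extra_drug))
        first_pt = reac.drop_duplicates("primaryid").set_index("primaryid")["pt"]
        extra_reac = pd.DataFrame(
            {"primaryid": extra_pid.astype(str), "pt": first_pt.loc[demo["primaryid"].iloc[rep_idx]].to_numpy()}
        )
        extra_frames.append(("reac", extra_reac))
    for kind, frame in extra_frames:
        if kind == "demo":
            demo = pd.concat([demo, frame], ignore_index=True)
        elif kind == "drug":
            drug_tbl = pd.concat([drug_tbl, frame], ignore_index=True)
        elif kind == "reac":
            reac = pd.concat([reac, frame], ignore_index=True)

    ledger = pd.DataFrame(
        {
            "caseid": caseid.astype(str),
            "survivor_primaryid": primaryid.astype(str),
            "drug": drug_arr,
            "true_pts": pts_per_case.reindex(primaryid.astype(str)).fillna("").to_numpy(),
            "is_duplicated": dup_mask,
            "true_tto_days": np.where(has_tto, tto_days, -1),
            "true_ho": demo["primaryid"].iloc[:n].isin(set(outc.loc[outc.outc_cod == "HO", "primaryid"])).to_numpy(),
            "true_de": demo["primaryid"].iloc[:n].isin(set(outc.loc[outc.outc_cod == "DE", "primaryid"])).to_numpy(),
        }
    )
    # shuffle row order so nothing downstream can rely on it
    demo = demo.sample(frac=1.0, random_state=config.seed).reset_index(drop=True)
    return SynthFrames(demo=demo, drug=drug_tbl, reac=reac, ther=ther, outc=outc, ledger=ledger)


# ---------------------------------------------------------------------------
# Exact mode: the printed-count fixture
# ---------------------------------------------------------------------------

# per-drug case characteristic counts (sex F/M/missing; age strata; reporter
# codes CN/HP/LW/MD/OT/PH/missing; countries US/GB/CA/AU/JP/other)
FIXTURE_REPORTS = {"ALENDRONATE": 30_735, "RISEDRONATE": 6_189, "IBANDRONATE": 4_666}
FIXTURE_CASES = {"ALENDRONATE": 3_039, "RISEDRONATE": 281, "IBANDRONATE": 177}
FIXTURE_EVENTS = {"ALENDRONATE": 3_621, "RISEDRONATE": 361, "IBANDRONATE": 196}
FIXTURE_SEX = {
    "ALENDRONATE": (2_527, 210, 302),
    "RISEDRONATE": (243, 25, 13),
    "IBANDRONATE": (168, 4, 5),
}
FIXTURE_AGE = {  # <18, 18-64.9, 65-85, >85, missing
    "ALENDRONATE": (2, 635, 618, 73, 1_711),
    "RISEDRONATE": (0, 88, 121, 12, 60),
    "IBANDRONATE": (0, 59, 53, 4, 61),
}
FIXTURE_REPORTER = {  # CN, HP, LW, MD, OT, PH, missing
    "ALENDRONATE": (1_112, 42, 72, 1_178, 435, 93, 107),
    "RISEDRONATE": (100, 10, 1, 70, 50, 21, 29),
    "IBANDRONATE": (119, 2, 6, 33, 8, 6, 3),
}
FIXTURE_COUNTRY = {  # US, GB, CA, AU, JP, other
    "ALENDRONATE": (2_531, 128, 85, 23, 14, 258),
    "RISEDRONATE": (139, 13, 46, 12, 20, 51),
    "IBANDRONATE": (156, 1, 1, 0, 4, 15),
}
FIXTURE_HOSP = {"ALENDRONATE": 1_143, "RISEDRONATE": 89, "IBANDRONATE": 26}
FIXTURE_DEATH = {"ALENDRONATE": 67, "RISEDRONATE": 6, "IBANDRONATE": 2}
FIXTURE_TTO_N = {"ALENDRONATE": 847, "RISEDRONATE": 88, "IBANDRONATE": 19}
FIXTURE_TTO_MEDIAN = {"ALENDRONATE": 346.0, "RISEDRONATE": 126.0, "IBANDRONATE": 28.0}
FIXTURE_TTO_SIGMA = 1.4

# SMQ preferred terms cycled over the cases, most common first (weights give
# a stable top-10 ranking with reflux disease leading)
_CASE_PT_WEIGHTS = [
    ("GASTROOESOPHAGEAL REFLUX DISEASE", 30),
    ("OESOPHAGITIS", 15),
    ("DYSPHAGIA", 12),
    ("OESOPHAGEAL PAIN", 8),
    ("BARRETT'S OESOPHAGUS", 6),
    ("OESOPHAGEAL ULCER", 5),
    ("OESOPHAGEAL STENOSIS", 4),
    ("OESOPHAGEAL DISORDER", 4),
    ("OESOPHAGEAL DISCOMFORT", 3),
    ("ODYNOPHAGIA", 3),
    ("OESOPHAGEAL HAEMORRHAGE", 2),
    ("ACQUIRED OESOPHAGEAL WEB", 1),
    ("OESOPHAGEAL CARCINOMA", 1),
]


def _expand(categories: list, counts: tuple[int, ...]) -> np.ndarray:
    return np.repeat(np.array(categories, dtype=object), np.array(counts))


def _tto_quantile_sample(median: float, sigma: float, n: int) -> np.ndarray:
    """Deterministic lognormal sample: inverse CDF at mid-point quantiles."""
    q = (np.arange(n) + 0.5) / n
    return np.maximum(0, np.rint(median * np.exp(sigma * special.ndtri(q)))).astype(int)


def printed_counts_fixture(
    background_n: int = 500_000,
    scaled: bool = False,
    duplicate_extra: int = 300,
    background_smq_rate: float = 0.005,
) -> SynthFrames:
    """Deterministic dataset whose deduplicated counts match the printed
    totals of the source study (see module docstring).

    ``scaled=True`` divides every count by 10 (and the background to 50,000)
    for fast runs; the percentage structure is then approximate because of
    integer rounding.  ``duplicate_extra`` earlier report versions are added
    so that deduplication is exercised; they never change post-dedup counts.
    """
    scale = 10 if scaled else 1
    if scaled:
        background_n = min(background_n, 50_000)
        duplicate_extra //= 10
    smq_pts = sorted(packaged_smq().pts)
    soc_map = packaged_pt_soc_map().mapping
    background_pts = sorted(set(soc_map) - set(smq_pts))

    demo_parts, drug_parts, reac_parts, ther_parts, outc_parts, ledger_parts = [], [], [], [], [], []
    next_case = 1

    reporter_codes = ["CN", "HP", "LW", "MD", "OT", "PH", ""]
    country_codes = ["US", "GB", "CA", "AU", "JP", "DE"]
    age_values = {  # deterministic representative ages per stratum
        "<18": lambda m: np.full(m, 12),
        "18-64.9": lambda m: np.linspace(30, 64, m).round(0) if m else np.array([]),
        "65-85": lambda m: np.linspace(65, 85, m).round(0) if m else np.array([]),
        ">85": lambda m: np.linspace(86, 97, m).round(0) if m else np.array([]),
    }

    pt_cycle = [pt for pt, w in _CASE_PT_WEIGHTS for _ in range(w)]

    for drug in TARGET_DRUGS:
        n_reports = FIXTURE_REPORTS[drug] // scale
        n_cases = FIXTURE_CASES[drug] // scale
        n_events = FIXTURE_EVENTS[drug] // scale
        caseids = np.arange(next_case, next_case + n_reports)
        next_case += n_reports
        pids = caseids * 100 + 99
        pid_str = pids.astype(str)
        is_case = np.zeros(n_reports, dtype=bool)
        is_case[:n_cases] = True

        def scaled_counts(counts, total):
            c = np.array(counts) // scale
            c[-1] += total - c.sum()  # keep the drug total exact under scaling
            return tuple(int(x) for x in c)

        sex = np.full(n_reports, "F", dtype=object)
        sex[n_cases:] = list(np.tile(["F", "F", "F", "F", "M", ""], n_reports)[: n_reports - n_cases])
        sex[:n_cases] = _expand(["F", "M", ""], scaled_counts(FIXTURE_SEX[drug], n_cases))

        strata = scaled_counts(FIXTURE_AGE[drug], n_cases)
        ages = np.concatenate(
            [age_values[s](m) for s, m in zip(("<18", "18-64.9", "65-85", ">85"), strata[:4])]
            + [np.full(strata[4], np.nan)]
        )
        age_str = np.full(n_reports, "", dtype=object)
        case_age = np.where(np.isnan(ages), "", ages.astype(object))
        age_str[:n_cases] = [("" if a == "" else str(int(a))) for a in case_age]
        age_str[n_cases:] = list(np.tile(["70", "65", "", "58", "80", ""], n_reports)[: n_reports - n_cases])

        occp = np.full(n_reports, "CN", dtype=object)
        occp[:n_cases] = _expand(reporter_codes, scaled_counts(FIXTURE_REPORTER[drug], n_cases))
        occp[n_cases:] = list(np.tile(["CN", "MD", "OT", "MD"], n_reports)[: n_reports - n_cases])

        ctry = np.full(n_reports, "US", dtype=object)
        ctry[:n_cases] = _expand(country_codes, scaled_counts(FIXTURE_COUNTRY[drug], n_cases))
        ctry[n_cases:] = list(np.tile(["US", "US", "US", "GB", "DE"], n_reports)[: n_reports - n_cases])

        # onset times: first tto_n cases carry day-precision start and event
        tto_n = FIXTURE_TTO_N[drug] // scale if scale == 1 else max(FIXTURE_TTO_N[drug] // scale, 3)
        tto_days = _tto_quantile_sample(FIXTURE_TTO_MEDIAN[drug], FIXTURE_TTO_SIGMA, tto_n)
        epoch0 = np.datetime64("2004-01-01").astype(int)
        start_ord = epoch0 + 365 + (np.arange(tto_n) * 97) % 6000
        event_ord = start_ord + tto_days
        start_dt = _fmt_dates(start_ord)
        event_full = np.full(n_reports, "", dtype=object)
        event_full[:tto_n] = _fmt_dates(event_ord)

        # receipt year cycles 2004-2023 so yearly counts are populated
        years = 2004 + (np.arange(n_reports) % 20)
        fda_dt = np.array([f"{y}0615" for y in years], dtype=object)

        demo_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid_str,
                    "caseid": caseids.astype(str),
                    "fda_dt": fda_dt,
                    "event_dt": event_full,
                    "sex": sex,
                    "age": age_str,
                    "age_cod": np.where(age_str == "", "", "YR"),
                    "occp_cod": occp,
                    "occr_country": ctry,
                }
            )
        )
        name_variants = np.tile([drug, f"{drug} SODIUM", f"{drug} 150 MG", drug.lower()], n_reports)[:n_reports]
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pid_str,
                    "drug_seq": "1",
                    "role_cod": "PS",
                    "drugname": name_variants,
                    "route": "ORAL",
                }
            )
        )
        # case PTs: one SMQ PT per case cycled by weight; the first
        # (n_events - n_cases) cases carry a second, distinct SMQ PT
        case_pts = [pt_cycle[i % len(pt_cycle)] for i in range(n_cases)]
        reac_parts.append(pd.DataFrame({"primaryid": pid_str[:n_cases], "pt": case_pts}))
        n_second = n_events - n_cases
        second = []
        for i in range(n_second):
            for candidate in (pt_cycle[(i + 7) % len(pt_cycle)], *smq_pts[(i + 11) % len(smq_pts):]):
                if candidate != case_pts[i]:
                    second.append(candidate)
                    break
        reac_parts.append(pd.DataFrame({"primaryid": pid_str[:n_second], "pt": second}))
        # non-case reports get background PTs
        bg = [background_pts[i % len(background_pts)] for i in range(n_reports - n_cases)]
        reac_parts.append(pd.DataFrame({"primaryid": pid_str[n_cases:], "pt": bg}))

        ther_parts.append(pd.DataFrame({"primaryid": pid_str[:tto_n], "dsg_drug_seq": "1", "start_dt": start_dt}))
        # cases beyond the usable-TTO slice carry a month-precision start so
        # the exclusion log is exercised
        if n_cases > tto_n:
            ther_parts.append(
                pd.DataFrame(
                    {"primaryid": pid_str[tto_n:n_cases], "dsg_drug_seq": "1", "start_dt": "201001"}
                )
            )

        n_ho = max(FIXTURE_HOSP[drug] // scale, 1)
        n_de = max(FIXTURE_DEATH[drug] // scale, 1)
        outc_parts.append(pd.DataFrame({"primaryid": pid_str[:n_ho], "outc_cod": "HO"}))
        outc_parts.append(pd.DataFrame({"primaryid": pid_str[:n_de], "outc_cod": "DE"}))

        ledger_parts.append(
            pd.DataFrame(
                {
                    "caseid": caseids.astype(str),
                    "survivor_primaryid": pid_str,
                    "drug": drug,
                    "is_case": is_case,
                    "true_tto_days": [int(tto_days[i]) if i < tto_n else -1 for i in range(n_reports)],
                }
            )
        )

    # background universe: non-bisphosphonate reports, a small share with SMQ PTs
    if background_n > 0:
        caseids = np.arange(next_case, next_case + background_n)
        pids = (caseids * 100 + 99).astype(str)
        n_smq_bg = int(round(background_smq_rate * background_n))
        pts = np.array(
            [smq_pts[i % len(smq_pts)] for i in range(n_smq_bg)]
            + [background_pts[i % len(background_pts)] for i in range(background_n - n_smq_bg)],
            dtype=object,
        )
        years = 2004 + (np.arange(background_n) % 20)
        demo_parts.append(
            pd.DataFrame(
                {
                    "primaryid": pids,
                    "caseid": caseids.astype(str),
                    "fda_dt": np.array([f"{y}0820" for y in years], dtype=object),
                    "event_dt": "",
                    "sex": np.tile(["F", "M", ""], background_n)[:background_n],
                    "age": np.tile(["55", "", "71"], background_n)[:background_n],
                    "age_cod": np.tile(["YR", "", "YR"], background_n)[:background_n],
                    "occp_cod": np.tile(["MD", "CN", "OT"], background_n)[:background_n],
                    "occr_country": np.tile(["US", "DE", "GB", "US"], background_n)[:background_n],
                }
            )
        )
        bg_drugs = [f"BACKGROUND DRUG {1 + (i % 40):02d}" for i in range(background_n)]
        drug_parts.append(
            pd.DataFrame(
                {"primaryid": pids, "drug_seq": "1", "role_cod": "PS", "drugname": bg_drugs, "route": "UNKNOWN"}
            )
        )
        reac_parts.append(pd.DataFrame({"primaryid": pids, "pt": pts}))
        outc_parts.append(pd.DataFrame({"primaryid": pids[:: 10], "outc_cod": "HO"}))

    demo = pd.concat(demo_parts, ignore_index=True)
    drug_tbl = pd.concat(drug_parts, ignore_index=True)
    reac = pd.concat(reac_parts, ignore_index=True)
    ther = pd.concat(ther_parts, ignore_index=True)
    outc = pd.concat(outc_parts, ignore_index=True)
    ledger = pd.concat(ledger_parts, ignore_index=True)

    # earlier versions of the first alendronate cases; dedup must drop them
    if duplicate_extra > 0:
        dup = demo.iloc[:duplicate_extra].copy()
        dup["primaryid"] = (dup["caseid"].astype(int) * 100 + 1).astype(str)
        dup["fda_dt"] = "20040105"
        demo = pd.concat([demo, dup], ignore_index=True)

    return SynthFrames(demo=demo, drug=drug_tbl, reac=reac, ther=ther, outc=outc, ledger=ledger)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "demo": "DEMO.txt",
    "drug": "DRUG.txt",
    "reac": "REAC.txt",
    "ther": "THER.txt",
    "outc": "OUTC.txt",
}


def write_tables(frames: SynthFrames, outdir: str | Path) -> dict[str, Path]:
    """Write the five tables in the ``$``-delimited dialect plus the ledger CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for attr, fname in _TABLE_FILES.items():
        path = outdir / fname
        getattr(frames, attr).to_csv(path, sep="$", index=False)
        paths[attr] = path
    ledger_path = outdir / "ground_truth_ledger.csv"
    frames.ledger.to_csv(ledger_path, index=False)
    paths["ledger"] = ledger_path
    return paths
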