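"""End-to-end orchestration: read tables, deduplicate, build the cohort, run
signal detection, time-to-onset and outcome analyses, and write a result
bundle (CSV/JSON files plus a manifest with config hash and stage counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import cohort as cohort_mod
from . import io_faers, outcomes as outcomes_mod, tto as tto_mod
from .dedup import deduplicate
from .signal_stats import DEFAULT_CRITERIA, ReportUniverse, SignalCriteria, scan
from .synth import data_path

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str = "results/pipeline"
    drug_dictionary: str = str(data_path("drug_dictionary.csv"))
    smq_file: str = str(data_path("smq_oesophageal_synthetic.csv"))
    pt_soc_file: str = str(data_path("pt_soc_map_synthetic.csv"))
    levels: Sequence[str] = ("SMQ", "SOC", "PT")
    counting_level: str = "event"
    top_k_pts: int = 10
    year_field: str = "fda_dt"
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    seed: int = 0
    dedup_report: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "criteria" in raw:
            raw["criteria"] = SignalCriteria(**raw["criteria"])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    descriptives: dict
    yearly: dict[str, dict[int, int]]
    signals: dict[str, list]
    km: dict[str, tto_mod.KMCurve]
    logrank: tuple[float, int, float] | None
    outcome_summary: outcomes_mod.OutcomeSummary
    manifest: dict
    case_reports: dict[str, list] = field(default_factory=dict)
    tto_records: list = field(default_factory=list)


def _read_tables(input_dir: Path) -> tuple[cohort_mod.Tables, dict]:
    counts = {}
    results = {}
    for kind, fname in (("DEMO", "DEMO.txt"), ("DRUG", "DRUG.txt"), ("REAC", "REAC.txt"),
                        ("THER", "THER.txt"), ("OUTC", "OUTC.txt")):
        path = input_dir / fname
        if not path.exists():
            if kind in ("THER", "OUTC"):
                results[kind] = io_faers.ReadResult(records=[], rejects=[])
                continue
            raise FileNotFoundError(f"missing required input table: {path}")
        results[kind] = io_faers.read_faers_table(path, kind)
        counts[kind] = {"records": len(results[kind].records), "rejects": len(results[kind].rejects)}
    tables = cohort_mod.Tables(
        demo=results["DEMO"].records,
        drug=results["DRUG"].records,
        reac=results["REAC"].records,
        ther=results["THER"].records,
        outc=results["OUTC"].records,
    )
    return tables, counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Missing inputs fail before any computation, listing all problems.
    """
    input_dir = Path(config.input_dir)
    problems = [str(p) for p in [input_dir / "DEMO.txt", input_dir / "DRUG.txt", input_dir / "REAC.txt"]
                if not p.exists()]
    for p in (config.drug_dictionary, config.smq_file, config.pt_soc_file):
        if not Path(p).exists():
            problems.append(str(p))
    if problems:
        raise FileNotFoundError("missing inputs: " + ", ".join(problems))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict = {}

    tables, read_counts = _read_tables(input_dir)
    stage_counts["read"] = read_counts

    dd = deduplicate(tables.demo)
    stage_counts["dedup"] = {
        "reports_in": len(tables.demo),
        "reports_kept": len(dd.kept),
        "reports_dropped": len(dd.dropped),
    }
    assert stage_counts["dedup"]["reports_in"] == stage_counts["dedup"]["reports_kept"] + stage_counts["dedup"]["reports_dropped"]
    if config.dedup_report:
        io_faers.write_report_table(
            [{"primaryid": p, "reason": r, "winner": w} for p, r, w in dd.dropped],
            out_dir / "dedup_dropped.csv",
        )

    reports, orphans = cohort_mod.assemble_reports(tables, dd.kept)
    stage_counts["assemble"] = {"reports": len(reports), "orphan_child_rows": len(orphans)}

    drug_dict = io_faers.read_drug_dictionary(config.drug_dictionary)
    smq = io_faers.read_smq(config.smq_file)
    pt_soc = io_faers.read_pt_soc_map(config.pt_soc_file)

    flags = cohort_mod.flag_cases(reports, drug_dict, smq)
    by_pid = {r.primaryid: r for r in reports}
    case_reports = {}
    drug_reports = {}
    for f in flags:
        drug_reports.setdefault(f.drug, []).append(by_pid[f.primaryid])
        if f.is_case:
            case_reports.setdefault(f.drug, []).append(by_pid[f.primaryid])
    case_reports = {d: case_reports.get(d, []) for d in sorted(drug_reports)}
    stage_counts["cohort"] = {
        d: {"reports": len(drug_reports[d]), "cases": len(case_reports[d])} for d in sorted(drug_reports)
    }

    descriptives = cohort_mod.describe_cohort(case_reports)
    io_faers.write_report_table(cohort_mod.descriptive_rows(descriptives), out_dir / "descriptives.csv")
    yearly = {d: cohort_mod.yearly_counts(reps, config.year_field) for d, reps in case_reports.items()}
    io_faers.write_report_table(
        [{"drug": d, "year": y, "count": c} for d, ys in yearly.items() for y, c in ys.items()],
        out_dir / "yearly_counts.csv",
    )

    universe = ReportUniverse.from_reports(reports)
    signals = scan(
        flags, universe, config.levels, pt_soc, smq,
        criteria=config.criteria, counting_level=config.counting_level,
        top_k=config.top_k_pts,
    )
    for level, rows in signals.items():
        io_faers.write_report_table([s.as_row() for s in rows], out_dir / f"signals_{level.lower()}.csv")

    tto_records, tto_excluded = tto_mod.extract_tto(case_reports)
    stage_counts["tto"] = {
        "usable": len(tto_records),
        "excluded": len(tto_excluded),
        "cases_in": sum(len(v) for v in case_reports.values()),
    }
    km = {}
    km_export = []
    groups = {}
    for d in case_reports:
        recs = [t for t in tto_records if t.drug == d]
        if recs:
            groups[d] = recs
            km[d] = tto_mod.km_curve(recs)
            km_export.extend(tto_mod.km_rows(km[d], d))
    io_faers.write_report_table(km_export, out_dir / "km_curves.csv")
    logrank_result = tto_mod.logrank(groups) if len(groups) >= 2 else None

    summary = outcomes_mod.outcome_rates(case_reports)
    with_cases = outcomes_mod.OutcomeSummary(
        per_drug={d: o for d, o in summary.per_drug.items() if o.n_cases > 0}
    )
    if len(with_cases.per_drug) >= 2:
        summary.tests = outcomes_mod.pairwise_chi2(with_cases)
    io_faers.write_report_table(outcomes_mod.summary_rows(summary), out_dir / "outcome_rates.csv")
    io_faers.write_report_table(
        [
            {
                "outcome": t.outcome, "drug1": t.drug1, "drug2": t.drug2,
                "chi2": t.chi2, "df": t.df, "p": t.p, "p_adjusted": t.p_adjusted,
                "significant": t.significant, "unreliable": t.unreliable,
            }
            for t in summary.tests
        ],
        out_dir / "outcome_tests.csv",
    )

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "logrank": None if logrank_result is None else {
            "statistic": logrank_result[0], "df": logrank_result[1], "p": logrank_result[2],
        },
        "tto_medians": {d: km[d].median for d in km},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline bundle written to %s", out_dir)

    return PipelineResult(
        descriptives=descriptives,
        yearly=yearly,
        signals=signals,
        km=km,
        logrank=logrank_result,
        outcome_summary=summary,
        manifest=manifest,
        case_reports=case_reports,
        tto_records=tto_records,
    )
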