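"""Cohort assembly, drug/SMQ matching, descriptive tables, yearly counts."""

import pytest

from bptox.cohort import (
    SafetyReport,
    Tables,
    age_stratum,
    assemble_reports,
    describe_cohort,
    flag_cases,
    yearly_counts,
)
from bptox.io_faers import DrugRecord, ReacRecord, SmqDefinition
from conftest import demo_record

SMQ = SmqDefinition(smq_name="OESO", pts=frozenset({"OESOPHAGITIS", "DYSPHAGIA"}))
DRUGS = {"ALENDRONATE": "ALENDRONATE"}


def drug(pid, name="ALENDRONATE", role="PS", seq="1"):
    return DrugRecord(primaryid=pid, drug_seq=seq, drugname=name, role_code=role)


def report(pid, drugs=(), pts=(), **demo_kw):
    return SafetyReport(
        demo=demo_record(pid, pid, **demo_kw),
        drugs=list(drugs),
        reactions=[ReacRecord(primaryid=pid, pt=p) for p in pts],
    )


class TestAssemble:
    def test_join_counts(self):
        demo = [demo_record("1", "1"), demo_record("2", "2")]
        drugs = [drug("1"), drug("1", seq="2"), drug("2"), drug("2", seq="2"), drug("2", seq="3")]
        reac = [ReacRecord("1", "NAUSEA")]
        reports, orphans = assemble_reports(Tables(demo=demo, drug=drugs, reac=reac), kept={"1", "2"})
        assert len(reports) == 2 and not orphans
        assert sum(len(r.drugs) for r in reports) == 5

    def test_orphan_child_rows_logged(self):
        demo = [demo_record("1", "1")]
        reac = [ReacRecord("1", "NAUSEA"), ReacRecord("999", "RASH")]
        reports, orphans = assemble_reports(Tables(demo=demo, drug=[], reac=reac), kept={"1"})
        assert orphans == [("REAC", "999")]

    def test_join_equals_nested_loop_oracle(self, rng):
        demo = [demo_record(str(i), str(i)) for i in range(100)]
        kept = {str(i) for i in range(0, 100, 2)}
        reac = [ReacRecord(str(rng.integers(0, 120)), f"PT{rng.integers(5)}") for _ in range(300)]
        reports, orphans = assemble_reports(Tables(demo=demo, drug=[], reac=reac), kept=kept)
        by_pid = {r.primaryid: r for r in reports}
        # oracle: brute-force nested scan
        for d in demo:
            for rec in reac:
                if rec.primaryid == d.primaryid and d.primaryid in kept:
                    assert rec in by_pid[d.primaryid].reactions
        n_matched = sum(1 for rec in reac if rec.primaryid in kept)
        assert sum(len(r.reactions) for r in reports) == n_matched
        assert len(orphans) == len(reac) - n_matched


class TestFlagging:
    def test_ps_substring_match_with_smq_hit(self):
        rep = report("1", drugs=[drug("1", "ALENDRONATE SODIUM")], pts=["OESOPHAGITIS"])
        flags = flag_cases([rep], DRUGS, SMQ)
        assert len(flags) == 1 and flags[0].is_case and flags[0].drug == "ALENDRONATE"

    def test_concomitant_role_never_matches(self):
        rep = report("1", drugs=[drug("1", role="C")], pts=["OESOPHAGITIS"])
        assert flag_cases([rep], DRUGS, SMQ) == []

    def test_ps_match_without_smq_pt_is_non_case(self):
        rep = report("1", drugs=[drug("1")], pts=["HEADACHE"])
        flags = flag_cases([rep], DRUGS, SMQ)
        assert len(flags) == 1 and not flags[0].is_case

    def test_two_target_drugs_contribute_to_both_cohorts(self):
        two = {"ALENDRONATE": "ALENDRONATE", "RISEDRONATE": "RISEDRONATE"}
        rep = report("1", drugs=[drug("1"), drug("1", "RISEDRONATE", seq="2")], pts=["DYSPHAGIA"])
        flags = flag_cases([rep], two, SMQ)
        assert {f.drug for f in flags} == {"ALENDRONATE", "RISEDRONATE"}

    def test_empty_drug_dict_rejected(self):
        with pytest.raises(ValueError):
            flag_cases([], {}, SMQ)


class TestDescriptives:
    def test_all_female_percentages(self):
        reps = [report(str(i), sex="F") for i in range(4)]
        table = describe_cohort({"ALENDRONATE": reps})
        assert table["sex"]["ALENDRONATE"]["Female"] == (4, 100.0)
        assert table["sex"]["ALENDRONATE"]["Male"] == (0, 0.0)

    def test_age_mean_and_sample_sd(self):
        reps = [report(str(i), age_years=a) for i, a in enumerate((60.0, 70.0, 80.0))]
        table = describe_cohort({"D": reps})
        assert table["age_mean_sd"]["D"] == (70.0, 10.0)

    def test_missing_included_in_denominator(self):
        # Table-1 style arithmetic: percentages over the full case total
        reps = [report("1", sex="F"), report("2", sex="F"), report("3", sex=None)]
        table = describe_cohort({"D": reps})
        assert table["sex"]["D"]["Female"] == (2, 66.7)
        assert table["sex"]["D"]["Missing"] == (1, 33.3)

    @pytest.mark.parametrize(
        "age, stratum",
        [(17.9, "<18"), (18.0, "18-64.9"), (64.9, "18-64.9"), (65.0, "65-85"),
         (85.0, "65-85"), (85.1, ">85"), (None, "Missing")],
    )
    def test_age_stratum_boundaries(self, age, stratum):
        assert age_stratum(age) == stratum

    def test_categorical_blocks_sum_to_case_total(self, rng):
        reps = [
            report(str(i), sex=rng.choice(["F", "M", None]),
                   age_years=rng.choice([12.0, 30.0, 70.0, 90.0, None]),
                   reporter_code=rng.choice(["CN", "MD", None, "ZZ"]),
                   country=rng.choice(["US", "DE", None]))
            for i in range(57)
        ]
        table = describe_cohort({"D": reps})
        for block in ("sex", "age", "reporter", "country"):
            assert sum(v[0] for v in table[block]["D"].values()) == 57


class TestYearlyCounts:
    def test_histogram(self):
        reps = [report(str(i), fda_dt=f"{y}0101") for i, y in enumerate([2017, 2017, 2017, 2018])]
        assert yearly_counts(reps) == {2017: 3, 2018: 1}

    def test_empty_input(self):
        assert yearly_counts([]) == {}

    def test_equals_brute_force_histogram(self, rng):
        years = rng.integers(2004, 2024, size=200)
        reps = [report(str(i), fda_dt=f"{y}06") for i, y in enumerate(years)]
        expected = {}
        for y in years:
            expected[int(y)] = expected.get(int(y), 0) + 1
        assert yearly_counts(reps) == expected
        assert sum(yearly_counts(reps).values()) == 200
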