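"""The synthetic FAERS generator: ground truth, duplicates, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from bptox.dedup import deduplicate
from bptox.io_faers import read_faers_table
from bptox.synth import (
    SynthConfig,
    default_config,
    generate,
    printed_counts_fixture,
    write_tables,
)


def small_config(**kw):
    base = dict(
        seed=7,
        n_reports=2000,
        drugs={"ALENDRONATE": 0.2, "OTHER": 0.8},
        pts={"OESOPHAGITIS": 0.2, "HEADACHE": 1.0, "NAUSEA": 1.0, "RASH": 1.0},
        signal={},
        duplicate_rate=0.0,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestStochastic:
    def test_no_duplicates_means_one_demo_row_per_report(self):
        frames = generate(small_config())
        assert len(frames.demo) == 2000
        dd = deduplicate_read(frames)
        assert len(dd.kept) == 2000

    def test_dedup_recovers_ledger_survivor_set(self):
        frames = generate(small_config(duplicate_rate=0.25, extra_versions_mean=2.0))
        assert len(frames.demo) > 2000
        dd = deduplicate_read(frames)
        assert dd.kept == set(frames.ledger["survivor_primaryid"])

    def test_same_seed_byte_identical_output(self, tmp_path):
        c = small_config(duplicate_rate=0.1)
        p1 = write_tables(generate(c), tmp_path / "a")
        p2 = write_tables(generate(c), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_differs(self):
        f1 = generate(small_config(seed=1))
        f2 = generate(small_config(seed=2))
        assert not f1.demo.equals(f2.demo)

    def test_realized_drug_counts_within_3_mc_sd(self):
        n = 20_000
        frames = generate(small_config(n_reports=n))
        count = (frames.ledger["drug"] == "ALENDRONATE").sum()
        expected, sd = 0.2 * n, np.sqrt(n * 0.2 * 0.8)
        assert abs(count - expected) <= 3 * sd

    def test_injected_signal_raises_event_share(self):
        cfg = small_config(signal={("ALENDRONATE", "OESOPHAGITIS"): 8.0}, n_reports=10_000)
        frames = generate(cfg)
        pairs = frames.reac.merge(
            frames.ledger[["survivor_primaryid", "drug"]],
            left_on="primaryid", right_on="survivor_primaryid",
        )
        share = pairs.groupby("drug")["pt"].apply(lambda s: (s == "OESOPHAGITIS").mean())
        assert share["ALENDRONATE"] > 4 * share["OTHER"]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(drugs={"A": 0.5, "B": 0.2})
        with pytest.raises(ValueError, match="positive"):
            small_config(signal={("ALENDRONATE", "HEADACHE"): -1.0})
        with pytest.raises(ValueError, match="unknown"):
            small_config(signal={("NOSUCHDRUG", "HEADACHE"): 2.0})

    def test_tto_ledger_matches_dates(self):
        cfg = small_config(tto={"ALENDRONATE": (100, 1.0)}, missing_event_dt=0.0, missing_start_dt=0.0)
        frames = generate(cfg)
        ledger = frames.ledger.set_index("survivor_primaryid")
        demo = frames.demo.set_index("primaryid")
        ther = frames.ther.set_index("primaryid")
        target = ledger[ledger["drug"] == "ALENDRONATE"].head(80)
        checked = 0
        for pid, row in target.iterrows():
            if pid not in ther.index or len(ther.loc[pid, "start_dt"]) != 8:
                continue  # a slice of start dates is degraded to month precision
            checked += 1
            start = pd.to_datetime(ther.loc[pid, "start_dt"], format="%Y%m%d")
            event = pd.to_datetime(demo.loc[pid, "event_dt"], format="%Y%m%d")
            assert (event - start).days == row["true_tto_days"]
        assert checked >= 30


def deduplicate_read(frames):
    from bptox.io_faers import DemoRecord, parse_date

    records = [
        DemoRecord(
            primaryid=r.primaryid, caseid=r.caseid, fda_dt=parse_date(r.fda_dt),
            event_dt=None, sex=None, age_years=None, reporter_code=None, country=None,
        )
        for r in frames.demo.itertuples()
    ]
    return deduplicate(records)


@pytest.fixture(scope="module")
def fixture_frames():
    return printed_counts_fixture(background_n=2000, duplicate_extra=50)


class TestPaperFixture:

    def test_per_drug_report_and_case_totals(self, fixture_frames):
        ledger = fixture_frames.ledger
        totals = ledger.groupby("drug").size()
        cases = ledger.groupby("drug")["is_case"].sum()
        assert totals["ALENDRONATE"] == 30_735 and cases["ALENDRONATE"] == 3_039
        assert totals["RISEDRONATE"] == 6_189 and cases["RISEDRONATE"] == 281
        assert totals["IBANDRONATE"] == 4_666 and cases["IBANDRONATE"] == 177

    def test_duplicates_removed_by_dedup(self, fixture_frames):
        dd = deduplicate_read(fixture_frames)
        assert len(dd.dropped) == 50
        # every intended survivor survives; nothing from the ledger is lost
        assert set(fixture_frames.ledger["survivor_primaryid"]) <= dd.kept
        assert len(dd.kept) == len(fixture_frames.demo) - 50

    def test_deterministic(self):
        f1 = printed_counts_fixture(background_n=500, duplicate_extra=10)
        f2 = printed_counts_fixture(background_n=500, duplicate_extra=10)
        assert f1.demo.equals(f2.demo) and f1.reac.equals(f2.reac)

    def test_scaled_variant_tenth_size(self):
        f = printed_counts_fixture(scaled=True, background_n=2000, duplicate_extra=0)
        totals = f.ledger.groupby("drug").size()
        assert totals["ALENDRONATE"] == 3_073
        assert f.ledger.groupby("drug")["is_case"].sum()["ALENDRONATE"] == 303

    def test_files_round_trip_without_rejects(self, fixture_frames, tmp_path):
        paths = write_tables(fixture_frames, tmp_path)
        for attr, kind in (("demo", "DEMO"), ("drug", "DRUG"), ("reac", "REAC"),
                           ("ther", "THER"), ("outc", "OUTC")):
            result = read_faers_table(paths[attr], kind)
            assert not result.rejects
            assert len(result.records) == len(getattr(fixture_frames, attr))
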