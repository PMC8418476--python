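import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemocorr.correction import RbcRatio, published_increment_fit
from hemocorr.exceptions import ValidationError
from hemocorr.indices import HemolysisIndex
from hemocorr.workflow import (
    Action,
    DecisionConfig,
    Purpose,
    SpecimenRecord,
    decide,
    read_specimens,
    run_pipeline,
    write_report,
    write_specimens,
)


@pytest.fixture(scope="module")
def model():
    return published_increment_fit().personalize(RbcRatio(0.31))


def make_record(nse, hi, purpose=Purpose.OTHER, prior=None, r=None, sid="s1"):
    return SpecimenRecord(
        specimen_id=sid,
        patient_id="p1",
        nse_meas=nse,
        hi=HemolysisIndex(0, censored_low=True) if hi < 1 else HemolysisIndex(hi),
        purpose=purpose,
        prior_nse=prior,
        r=RbcRatio(r) if r is not None else None,
    )


class TestDecide:
    def test_clean_specimen_released(self, model):
        e = decide(make_record(50.0, 3), model=model)
        assert e.action is Action.RELEASE

    def test_hemolyzed_low_nse_annotated(self, model):
        e = decide(make_record(10.0, 36), model=model)
        assert e.action is Action.RELEASE_WITH_HI_NOTE

    def test_diagnosis_with_ratio_corrected(self, model):
        e = decide(make_record(60.9, 36, Purpose.DIAGNOSIS, r=0.31), model=model)
        assert e.action is Action.CORRECTED_REPORT
        assert e.corrected_nse is not None and e.corrected_nse < e.original_nse

    def test_diagnosis_without_ratio_flagged(self, model):
        e = decide(make_record(60.9, 36, Purpose.DIAGNOSIS), model=model)
        assert e.action is Action.NEEDS_RATIO

    def test_small_trend_change_not_corrected(self, model):
        e = decide(make_record(20.0, 15, Purpose.TREND, prior=18.0), model=model)
        assert e.action is Action.RELEASE_WITH_HI_NOTE  # 11% < 25% threshold

    def test_large_trend_change_corrected(self, model):
        e = decide(make_record(30.0, 15, Purpose.TREND, prior=18.0, r=0.3), model=model)
        assert e.action is Action.CORRECTED_REPORT  # 67% > 25%

    def test_trend_without_prior_warns(self, model):
        e = decide(make_record(30.0, 15, Purpose.TREND), model=model)
        assert e.action is Action.RELEASE_WITH_HI_NOTE
        assert "warning" in e.rationale

    def test_boundaries_are_strict(self, model):
        # NSE exactly at the reference limit is not "above" it
        e = decide(make_record(16.3, 36, Purpose.DIAGNOSIS, r=0.3), model=model)
        assert e.action is Action.RELEASE_WITH_HI_NOTE
        # trend change of exactly 25% is not "more than" 25%
        e = decide(make_record(25.0, 36, Purpose.TREND, prior=20.0, r=0.3), model=model)
        assert e.action is Action.RELEASE_WITH_HI_NOTE

    @given(
        nse=st.floats(0.05, 370),
        hi=st.integers(0, 1000),
        purpose=st.sampled_from(list(Purpose)),
        prior=st.one_of(st.none(), st.floats(0.05, 370)),
        r=st.one_of(st.none(), st.floats(0.0, 0.5)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_totality_exclusivity_and_rule_trace(self, model, nse, hi, purpose, prior, r):
        config = DecisionConfig()
        record = make_record(nse, hi, purpose, prior, r)
        entry = decide(record, config, model)
        assert entry.action in list(Action)
        assert entry.rationale
        # brute-force predicate evaluation must agree with the cascade
        hemolyzed = record.hi.value > config.hi_cutoff
        if not hemolyzed:
            expected = Action.RELEASE
        elif nse <= config.nse_cutoff:
            expected = Action.RELEASE_WITH_HI_NOTE
        else:
            need = purpose is Purpose.DIAGNOSIS or (
                purpose is Purpose.TREND
                and prior is not None
                and abs(nse - prior) / prior * 100 > config.trend_delta_pct
            )
            if need:
                expected = Action.NEEDS_RATIO if r is None else Action.CORRECTED_REPORT
            else:
                expected = Action.RELEASE_WITH_HI_NOTE
        assert entry.action is expected
        # never correct clean specimens
        if not hemolyzed:
            assert entry.corrected_nse is None


def replayed_prevalence_records():
    """503 specimens reproducing the published per-stratum hemolysis counts."""
    strata = [
        (10.0, 217, 47),   # NSE <= 16.3
        (30.0, 211, 95),   # 16.3 < NSE <= 50
        (75.0, 43, 11),    # 50 < NSE <= 100
        (200.0, 32, 11),   # 100 < NSE <= 370
    ]
    records = []
    i = 0
    for nse, n, n_hem in strata:
        for j in range(n):
            hi = 6 if j < n_hem else 2
            records.append(make_record(nse, hi, sid=f"s{i}"))
            i += 1
    return records


class TestRunPipeline:
    def test_replayed_prevalence(self, model):
        _, summary = run_pipeline(replayed_prevalence_records(), model=model)
        assert summary.n_total == 503
        assert summary.n_hemolyzed == 164
        assert round(100 * summary.overall_rate, 1) == 32.6
        rates = [round(100 * s["rate"], 1) for s in summary.strata]
        assert rates == [21.7, 45.0, 25.6, 34.4]

    def test_empty_stratum_reports_none(self, model):
        records = [make_record(10.0, 2, sid="a"), make_record(10.0, 8, sid="b")]
        _, summary = run_pipeline(records, model=model)
        assert summary.strata[0]["n"] == 2
        assert summary.strata[2]["rate"] is None

    def test_all_clean_released(self, model):
        records = [make_record(10.0, 0, sid=f"s{i}") for i in range(5)]
        entries, summary = run_pipeline(records, model=model)
        assert summary.n_hemolyzed == 0
        assert all(e.action is Action.RELEASE for e in entries)

    def test_empty_input_rejected(self, model):
        with pytest.raises(ValueError):
            run_pipeline([], model=model)

    @pytest.mark.parametrize("seed", range(5))
    def test_summary_matches_counting_oracle(self, model, seed):
        rng = np.random.default_rng(seed)
        records = [
            make_record(float(rng.uniform(0.1, 369)), int(rng.integers(0, 200)),
                        sid=f"s{i}")
            for i in range(100)
        ]
        _, summary = run_pipeline(records, model=model)
        hand_total = sum(1 for r in records if r.hi.value > 5)
        assert summary.n_hemolyzed == hand_total
        edges = [(0, 16.3), (16.3, 50), (50, 100), (100, 370)]
        for (lo, hi_e), s in zip(edges, summary.strata):
            members = [r for r in records if lo < r.nse_meas <= hi_e]
            assert s["n"] == len(members)
            assert s["n_hemolyzed"] == sum(1 for r in members if r.hi.value > 5)


class TestSpecimenCsv:
    def test_round_trip(self, tmp_path):
        records = [
            make_record(50.0, 10, Purpose.DIAGNOSIS, r=0.31, sid="a"),
            make_record(8.0, 0, sid="b"),
            make_record(20.0, 15, Purpose.TREND, prior=18.0, sid="c"),
        ]
        p = tmp_path / "specimens.csv"
        write_specimens(records, p)
        back, errors = read_specimens(p)
        assert errors == []
        assert back == records

    def test_bad_row_collected_not_dropped_silently(self, tmp_path):
        p = tmp_path / "specimens.csv"
        p.write_text(
            "specimen_id,patient_id,nse_meas,hi,purpose,prior_nse,r,timestamp\n"
            "a,p1,50.0,10,diagnosis,,0.31,\n"
            "b,p2,999.0,10,diagnosis,,,\n"  # NSE above assay range
            "c,p3,8.0,2,other,,,\n"
        )
        records, errors = read_specimens(p)
        assert [r.specimen_id for r in records] == ["a", "c"]
        assert len(errors) == 1 and "line 3" in errors[0]

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("specimen_id,nse_meas\na,50\n")
        with pytest.raises(ValidationError):
            read_specimens(p)

    def test_report_writer(self, tmp_path, model):
        entries, _ = run_pipeline(
            [make_record(60.9, 36, Purpose.DIAGNOSIS, r=0.31, sid="a")], model=model
        )
        p = tmp_path / "report.csv"
        write_report(entries, p)
        text = p.read_text()
        assert "corrected_report" in text and "a" in text
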