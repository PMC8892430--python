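import numpy as np
import pytest

import tracerscreen as ts
from tracerscreen.cli import ProcessingParams, build_demo_truth, run_pipeline


@pytest.fixture(scope="module")
def three_sample_study():
    """One 4-compound truth planted into 3 runs with rt/mz jitter."""
    truth = build_demo_truth("standard", 4, 0, seed=3)
    rng = np.random.default_rng(17)
    runs = {}
    for i in range(3):
        runs[f"s{i}"] = ts.generate_run(
            truth,
            sample_id=f"s{i}",
            rt_shift=float(rng.uniform(-2.0, 2.0)),
            mz_shift_ppm=float(rng.uniform(-2.0, 2.0)),
            seed=100 + i,
        )
    params = ProcessingParams(rt_window=(0.0, 1e6))
    result = run_pipeline([], "standard", params, runs=runs, report_attrition=False)
    return truth, runs, result


class TestBracket:
    def test_jittered_samples_merge_into_one_bracket_each(self, three_sample_study):
        truth, _, result = three_sample_study
        assert len(result.brackets) == len(truth.expected_hits)
        for b in result.brackets:
            assert len(b.detected_samples) == 3

    def test_far_separated_isomers_stay_apart(self):
        def feature(sample, mz, rt):
            peak = ts.ChromPeak(rt, (rt - 6, rt + 6), 1e6, 1e5, 100.0, 0, (0, 24))
            return ts.Feature(mz, rt, {0: peak}, 1.0, ts.Verdict(True))

        # 0.2 min apart > the 0.1 min bracketing tolerance
        by_sample = {
            "a": [feature("a", 300.0, 600.0)],
            "b": [feature("b", 300.0, 612.0)],
        }
        assert len(ts.bracket(by_sample, rt_tol=6.0, mz_ppm=5.0)) == 2

    def test_single_sample_brackets_are_its_features(self, std_ruleset):
        truth = build_demo_truth("standard", 3, 0, seed=5)
        run = ts.generate_run(truth, sample_id="only")
        params = ProcessingParams(rt_window=(0.0, 1e6))
        result = run_pipeline([], "standard", params, runs={"only": run},
                              report_attrition=False)
        assert len(result.brackets) == len(result.features_by_sample["only"]) == 3

    def test_no_bracket_mixes_features_from_one_sample(self, three_sample_study):
        _, _, result = three_sample_study
        for b in result.brackets:
            assert len(b.per_sample) == len(set(b.per_sample))

    def test_idempotence_of_bracketing(self, three_sample_study):
        _, _, result = three_sample_study
        consensus = {"x": [  # re-bracketing the consensus features changes nothing
            member.feature
            for b in result.brackets
            for member in [next(e for e in b.per_sample.values() if e.feature)]
        ]}
        again = ts.bracket(consensus)
        assert len(again) == len(result.brackets)


class TestConvolute:
    def test_coeluting_companion_ion_groups_with_its_parent(self, std_ruleset):
        model = ts.IncorporationModel(n_units=9, q=0.12, n_carbons=18)
        parent = ts.PlantedCompound(x_mz=350.0, rt_apex=60.0, model=model, height=2e6)
        adduct = ts.PlantedCompound(x_mz=372.0, rt_apex=60.0, model=model, height=1e6)
        truth = ts.SyntheticTruth([parent, adduct], seed=4, rt_span=(0.0, 120.0))
        run = ts.generate_run(truth, sample_id="s")
        params = ProcessingParams(rt_window=(0.0, 1e6))
        result = run_pipeline([], "standard", params, runs={"s": run},
                              report_attrition=False)
        assert len(result.brackets) == 2
        assert len(result.groups) == 1
        assert len(result.groups[0].members) == 2

    def test_unrelated_compounds_stay_in_separate_groups(self, three_sample_study):
        truth, _, result = three_sample_study
        # compounds elute 13 s apart: separate groups
        assert len(result.groups) == len(truth.expected_hits)

    def test_anticorrelated_traces_are_not_grouped(self):
        rt = np.arange(0.0, 60.5, 0.5)
        rising = 1e6 * np.exp(-((rt - 40.0) ** 2) / 18.0)
        falling = 1e6 * np.exp(-((rt - 20.0) ** 2) / 18.0)
        scans = []
        for i, t in enumerate(rt):
            mz = np.array([300.0, 310.0])
            inten = np.array([falling[i], rising[i]])
            keep = inten > 0.5
            scans.append(ts.MassSpectrum(i, float(t), "+", 1, mz[keep], inten[keep]))
        run = ts.Run("s", scans, "+")

        def feature(mz, rt_apex):
            peak = ts.ChromPeak(rt_apex, (rt_apex - 9, rt_apex + 9), 1e6, 1e6, 100.0, 0, (0, 1))
            return ts.Feature(mz, rt_apex, {0: peak}, 1.0, ts.Verdict(True))

        brackets = ts.bracket({"s": [feature(300.0, 20.0), feature(310.0, 40.0)]})
        groups = ts.convolute(brackets, {"s": run}, r_min=0.85, rt_tol=30.0)
        assert len(groups) == 2


class TestReintegrate:
    def test_blank_sample_gets_near_zero_flagged_area(self, std_ruleset):
        model = ts.IncorporationModel(n_units=9, q=0.12, n_carbons=18)
        compound = ts.PlantedCompound(x_mz=350.0, rt_apex=60.0, model=model, height=2e6)
        truth = ts.SyntheticTruth([compound], seed=4, rt_span=(0.0, 120.0))
        run_a = ts.generate_run(truth, sample_id="A")
        blank = ts.generate_run(
            ts.SyntheticTruth([], seed=4, rt_span=(0.0, 120.0)), sample_id="B"
        )
        params = ProcessingParams(rt_window=(0.0, 1e6))
        result = run_pipeline([], "standard", params, runs={"A": run_a, "B": blank},
                              report_attrition=False)
        (bracket_,) = result.brackets
        entry = bracket_.per_sample["B"]
        assert entry.flag == "reintegrated"
        assert entry.areas[0] == pytest.approx(0.0, abs=1.0)
        detected_area = bracket_.per_sample["A"].areas[0]
        assert detected_area > 1e6

    def test_subthreshold_compound_area_recovered_within_ten_percent(self, std_ruleset):
        model = ts.IncorporationModel(n_units=9, q=0.12, n_carbons=18)
        strong = ts.PlantedCompound(x_mz=350.0, rt_apex=60.0, model=model, height=2e6)
        weak = ts.PlantedCompound(x_mz=350.0, rt_apex=60.0, model=model, height=4e4)
        run_a = ts.generate_run(
            ts.SyntheticTruth([strong], seed=4, rt_span=(0.0, 120.0)), sample_id="A"
        )
        run_b = ts.generate_run(
            ts.SyntheticTruth([weak], seed=4, rt_span=(0.0, 120.0)), sample_id="B"
        )
        params = ProcessingParams(rt_window=(0.0, 1e6))
        result = run_pipeline([], "standard", params, runs={"A": run_a, "B": run_b},
                              report_attrition=False)
        (bracket_,) = result.brackets
        entry = bracket_.per_sample["B"]
        assert entry.flag == "reintegrated"
        pattern = ts.theoretical_pattern(model)
        planted_area = 4e4 * pattern[0] * 3.0 * np.sqrt(2 * np.pi)
        assert entry.areas[0] == pytest.approx(planted_area, rel=0.10)

    def test_detected_members_are_never_altered(self, three_sample_study):
        _, runs, result = three_sample_study
        before = {
            (i, s): dict(e.areas)
            for i, b in enumerate(result.brackets)
            for s, e in b.per_sample.items()
            if e.flag == "detected"
        }
        for b in result.brackets:
            ts.reintegrate(b, runs)
        after = {
            (i, s): dict(e.areas)
            for i, b in enumerate(result.brackets)
            for s, e in b.per_sample.items()
            if e.flag == "detected"
        }
        assert before == after


class TestResultsTsv:
    def test_written_matrix_round_trips(self, three_sample_study, tmp_path):
        _, _, result = three_sample_study
        path = tmp_path / "results.tsv"
        frame = ts.write_results_tsv(result.groups, str(path))
        again = ts.read_results_tsv(str(path))
        assert list(again.columns) == list(frame.columns)
        assert len(again) == len(frame) == len(result.brackets)
        assert {"group_id", "mz", "rt_min", "charge"}.issubset(again.columns)
        # rt reported in minutes
        assert (again["rt_min"] < 10).all()

    def test_empty_results_give_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        ts.write_results_tsv([], str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("group_id\tmz\trt_min\tcharge")
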