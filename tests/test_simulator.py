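import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from metacombine import (
    SCENARIOS,
    SimulationScenario,
    ValidationError,
    assign_truth,
    build_universe,
    draw_protein_params,
    read_study,
    run_scenario,
    simulate_study,
    welch_test,
    write_example_inputs,
)
from metacombine.simulator import _welch_arrays, study_result
from oracles import welch_reference


class TestScenarioPresets:
    def test_ten_presets_match_study_conditions(self):
        assert set(SCENARIOS) == set(range(1, 11))
        assert [SCENARIOS[i].n for i in (1, 2, 3)] == [6, 9, 12]
        assert [SCENARIOS[i].K for i in (4, 5, 6)] == [3, 4, 5]
        assert [SCENARIOS[i].alpha_scale for i in (7, 8)] == [1.5, 2.0]
        assert [SCENARIOS[i].rho for i in (9, 10)] == [0.50, 0.25]
        for sc in SCENARIOS.values():
            assert (sc.n_proteins, sc.diff_fraction) == (2000, 0.30)
            assert sc.fold_changes == (1.5, 2.0, 4.0)
            assert (sc.mu, sc.sigma, sc.alpha, sc.beta, sc.eta) == (
                2.42, 0.30, 1.63, -0.90, 0.50,
            )

    @pytest.mark.parametrize(
        "kwargs", [{"n": 1}, {"n": 6, "K": 1}, {"n": 6, "rho": 0.0}, {"n": 6, "rho": 1.2}]
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationScenario(**kwargs)


class TestUniverse:
    def test_two_study_overlap_arithmetic(self):
        lists = build_universe(SCENARIOS[1])  # K=2, rho=0.75
        assert [len(ids) for ids in lists] == [2000, 2000]
        shared = set(lists[0]) & set(lists[1])
        assert len(shared) == 1500
        assert len(set(lists[0]) | set(lists[1])) == 2500

    def test_full_overlap_gives_identical_lists(self):
        sc = dataclasses.replace(SCENARIOS[1], rho=1.0)
        lists = build_universe(sc)
        assert lists[0] == lists[1]
        assert len(lists[0]) == 2000

    def test_three_study_core_scheme(self):
        lists = build_universe(SCENARIOS[4])  # K=3, rho=0.75
        union = set().union(*map(set, lists))
        core = set(lists[0]) & set(lists[1]) & set(lists[2])
        assert len(union) == 1500 + 3 * 500
        assert len(core) == 1500


class TestTruth:
    def test_thirty_percent_differential(self, rng):
        universe = [f"P{i}" for i in range(2500)]
        truth = assign_truth(universe, SCENARIOS[1], rng)
        diff = truth.differential_set()
        assert len(diff) == 750
        assert set(truth.fold_change[p] for p in diff) <= {1.5, 2.0, 4.0}
        assert all(truth.true_sign[p] in (-1, 1) for p in diff)
        assert all(truth.true_sign[p] == 0 for p in universe if p not in diff)

    def test_fold_changes_roughly_uniform(self, rng):
        universe = [f"P{i}" for i in range(30_000)]
        truth = assign_truth(universe, SCENARIOS[1], rng)
        diff = truth.differential_set()
        counts = {fc: 0 for fc in (1.5, 2.0, 4.0)}
        for p in diff:
            counts[truth.fold_change[p]] += 1
        for fc, c in counts.items():
            assert c / len(diff) == pytest.approx(1 / 3, abs=0.03)


class TestProteinParams:
    def test_degenerate_closed_form(self, rng):
        sc = dataclasses.replace(SCENARIOS[1], sigma=0.0, eta=0.0)
        params = draw_protein_params(10, sc, rng)
        for gamma, lam in params:
            assert gamma == pytest.approx(math.exp(2.42), rel=1e-12)
            assert lam == pytest.approx(math.exp(1.63 - 0.90 * 2.42), rel=1e-12)

    def test_hierarchical_moments_and_slope(self, rng):
        n = 100_000
        params = np.array(draw_protein_params(n, SCENARIOS[1], rng))
        log_gamma = np.log(params[:, 0])
        log_lam = np.log(params[:, 1])
        assert log_gamma.mean() == pytest.approx(2.42, abs=4 * 0.30 / math.sqrt(n))
        assert log_gamma.std() == pytest.approx(0.30, rel=0.02)
        # least-squares regression of log(lambda) on log(gamma)
        design = np.column_stack([np.ones(n), log_gamma])
        (intercept, slope), *_ = np.linalg.lstsq(design, log_lam, rcond=None)
        assert slope == pytest.approx(-0.90, abs=0.03)
        assert intercept == pytest.approx(1.63, abs=0.08)
        resid = log_lam - design @ [intercept, slope]
        assert resid.var() == pytest.approx(0.50, rel=0.03)  # eta is a variance

    def test_alpha_scale_inflates_spread(self, rng):
        sc = dataclasses.replace(SCENARIOS[1], alpha_scale=2.0)
        base = np.array(draw_protein_params(20_000, SCENARIOS[1], rng))
        noisy = np.array(draw_protein_params(20_000, sc, rng))
        assert np.median(noisy[:, 1]) > 2 * np.median(base[:, 1])


class TestWelch:
    def test_identical_groups_give_p_one(self):
        p, s = _welch_arrays(np.tile([1.0, 2.0, 3.0], (2, 1)), np.tile([1.0, 2.0, 3.0], (2, 1)))
        assert np.all(p == 1.0) and np.all(s == 0)

    def test_constant_equal_groups_degenerate(self):
        g = np.full((1, 4), 5.0)
        p, s = _welch_arrays(g, g)
        assert p[0] == 1.0 and s[0] == 0

    def test_separated_groups_match_reference(self):
        g1 = [10.0, 11.0, 12.0, 13.0, 14.0, 15.0]
        g2 = [20.0, 21.0, 22.0, 23.0, 24.0, 25.0]
        p, s = _welch_arrays(np.array([g1]), np.array([g2]))
        ref_p, ref_sign = welch_reference(g1, g2)
        assert s[0] == ref_sign == -1
        assert p[0] == pytest.approx(ref_p, rel=1e-6)
        assert p[0] < 1e-5

    def test_null_pvalues_uniform(self, rng):
        g1 = rng.normal(size=(4000, 6))
        g2 = rng.normal(size=(4000, 6))
        p, _ = _welch_arrays(g1, g2)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestSimulateStudy:
    def test_matrix_shape_and_group_shift(self, rng):
        sc = SCENARIOS[1]
        ids = [f"P{i}" for i in range(50)]
        truth = assign_truth(ids, sc, rng)
        study = simulate_study(sc, ids, truth, rng)
        assert study.abundance.shape == (50, 12)
        assert len(welch_test(study)) == 50
        # with vanishing measurement noise the group means differ by ln(FC)
        quiet = dataclasses.replace(sc, eta=0.0, alpha=-20.0)
        gamma = np.full(4, 10.0)
        lam = np.full(4, 1e-9)
        truth2 = assign_truth(["A", "B", "C", "D"], quiet, np.random.default_rng(5))
        study2 = simulate_study(quiet, ["A", "B", "C", "D"], truth2, rng,
                                gamma=gamma, lam=lam)
        for i, pid in enumerate(["A", "B", "C", "D"]):
            observed = study2.group1[i].mean() - study2.group2[i].mean()
            expected = truth2.true_sign[pid] * math.log(truth2.fold_change[pid])
            assert observed == pytest.approx(expected, abs=1e-8)

    def test_study_result_feeds_io_types(self, rng):
        sc = SCENARIOS[1]
        ids = [f"P{i}" for i in range(30)]
        truth = assign_truth(ids, sc, rng)
        res = study_result(simulate_study(sc, ids, truth, rng, study_name="sim"))
        assert res.study_name == "sim"
        assert len(res) == 30


class TestRunScenario:
    def test_seed_determinism(self):
        small = dataclasses.replace(SCENARIOS[1], n_proteins=400)
        a = run_scenario(small, reps=3, seed=11)
        b = run_scenario(small, reps=3, seed=11)
        for m in a.methods:
            assert np.array_equal(a.methods[m].detections, b.methods[m].detections)
            assert np.array_equal(a.methods[m].tidr, b.methods[m].tidr)
        c = run_scenario(small, reps=3, seed=12)
        assert not np.array_equal(
            a.methods["stouffer"].detections, c.methods["stouffer"].detections
        )

    def test_null_universe_has_no_detections(self):
        null = dataclasses.replace(SCENARIOS[1], n_proteins=600, diff_fraction=0.0)
        res = run_scenario(null, method="stouffer", reps=4, seed=3)
        perf = res.methods["stouffer"]
        assert perf.mean_detections < 2.0
        # nothing is truly differential, so the truth-aware IDR/IRR vanish
        assert perf.mean("tidr") == 0.0 and perf.mean("tirr") == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            run_scenario(SCENARIOS[1], reps=0)
        with pytest.raises(ValidationError):
            run_scenario(SCENARIOS[1], method="fisher", reps=1)

    def test_report_fields_populated(self):
        small = dataclasses.replace(SCENARIOS[1], n_proteins=500)
        res = run_scenario(small, reps=2, seed=7)
        for perf in res.methods.values():
            assert perf.reps == 2
            assert perf.single_detections.shape == (2, 2)
            assert perf.best_single <= perf.mean_single.max() + 1e-12
            assert 0 <= perf.mean("tfdr") <= 100
            assert perf.se("detections") >= 0


def test_example_inputs_roundtrip(tmp_path):
    sc = SCENARIOS[1]
    paths = write_example_inputs(sc, tmp_path, seed=4)
    studies = [read_study(p) for p in paths]
    assert [len(s) for s in studies] == [2000, 2000]
    shared = set(studies[0].protein_ids()) & set(studies[1].protein_ids())
    assert len(shared) == 1500
    # deterministic regeneration
    paths2 = write_example_inputs(sc, tmp_path / "again", seed=4)
    assert paths[0].read_text() == paths2[0].read_text()
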