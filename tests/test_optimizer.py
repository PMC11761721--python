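"""Capped-improvement optimizer: caps, gains, feasibility, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import premopt as po
from premopt.errors import DomainError

logistic = lambda t: 1.0 / (1.0 + np.exp(-t))

PUBLISHED_KAPPA = (7.842, 10.83, 14.71, 19.44)


def make_problem(toy_fit_factory, b, baseline, target=1.0, kappa=PUBLISHED_KAPPA, **kw):
    fit = toy_fit_factory(b, kappa)
    return po.ImprovementProblem(fit=fit, baseline=np.asarray(baseline, float),
                                 target=target, **kw)


@pytest.fixture
def three_item_problem(toy_fit_factory):
    return make_problem(
        toy_fit_factory, [0.2, 0.5, 1.0], [4.0, 4.5, 3.5], target=2.0
    )


class TestBaselineScore:
    def test_symmetric_null_model_scores_3(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.0], [3.0], kappa=(-2.0, -1.0, 1.0, 2.0))
        assert po.baseline_score(p) == pytest.approx(3.0)

    def test_all_baselines_at_ceiling_match_all5_evaluation(self, surgical_fit):
        x = np.full(len(surgical_fit.item_ids), 5.0)
        p = po.ImprovementProblem(fit=surgical_fit, baseline=x, target=1.0)
        assert po.baseline_score(p) == pytest.approx(po.expected_satisfaction(surgical_fit, x))

    def test_matches_probability_vector_evaluation(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        p = po.ImprovementProblem(fit=surgical_fit, baseline=baseline, target=1.0)
        probs = po.predict_category_probs(surgical_fit, baseline)
        assert po.baseline_score(p) == pytest.approx(float(probs @ np.arange(1, 6)))

    def test_top_box_metric_is_p5(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        p = po.ImprovementProblem(fit=surgical_fit, baseline=baseline, target=1.0,
                                  metric="top_box")
        probs = po.predict_category_probs(surgical_fit, baseline)
        assert po.baseline_score(p) == pytest.approx(probs[4])


class TestEffectiveCap:
    @pytest.mark.parametrize(
        "baseline,expected",
        [(5.0, 0.0), (4.0, 15.0), (4.5, 100.0 * 0.5 / 4.5)],
    )
    def test_cap_vs_scale_ceiling(self, toy_fit_factory, baseline, expected):
        p = make_problem(toy_fit_factory, [0.5], [baseline])
        assert po.effective_cap(p, "item0") == pytest.approx(expected)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(1.0, 5.0), st.floats(0.0, 40.0))
    def test_cap_bounds(self, baseline, cap):
        fit = po.OrdinalFit(item_ids=("a",), b=np.array([0.4]),
                            kappa=np.array(PUBLISHED_KAPPA))
        p = po.ImprovementProblem(fit=fit, baseline=np.array([baseline]), target=0.0, cap=cap)
        eff = po.effective_cap(p, "a")
        assert 0.0 <= eff <= cap + 1e-12
        if baseline == 5.0:
            assert eff == 0.0


class TestPredictedImprovement:
    def test_zero_delta_zero_gain(self, three_item_problem):
        assert po.predicted_improvement(three_item_problem, [0.0, 0.0, 0.0]) == 0.0

    def test_single_item_positive_delta_positive_gain(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.8], [4.0])
        assert po.predicted_improvement(p, [5.0]) > 0.0

    def test_two_item_gain_matches_hand_computation(self, toy_fit_factory):
        b = np.array([0.6, 1.2])
        baseline = np.array([4.0, 4.2])
        p = make_problem(toy_fit_factory, b, baseline)
        delta = np.array([10.0, 0.0])
        # independent evaluation through the logistic CDF
        kap = np.asarray(PUBLISHED_KAPPA)

        def escore(eta):
            cum = logistic(kap - eta)
            probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
            return probs @ np.arange(1, 6)

        s0 = escore(b @ baseline)
        s1 = escore(b @ (baseline * np.array([1.10, 1.0])))
        assert po.predicted_improvement(p, delta) == pytest.approx(
            100.0 * (s1 - s0) / s0, rel=1e-10
        )

    def test_cap_violation_rejected(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.5], [4.5])  # effective cap 11.1
        with pytest.raises(DomainError):
            po.predicted_improvement(p, [12.0])


class TestFeasibilityBound:
    def test_zero_cap_zero_bound(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.5, 0.7], [4.0, 4.2], cap=0.0)
        assert po.feasibility_bound(p) == pytest.approx(0.0)

    def test_all_ceiling_baselines_zero_bound(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.5, 0.7], [5.0, 5.0], cap=15.0)
        assert po.feasibility_bound(p) == pytest.approx(0.0)

    def test_bound_never_exceeds_scale_headroom(self, toy_fit_factory):
        rng = np.random.default_rng(3)
        for _ in range(20):
            J = int(rng.integers(1, 5))
            b = rng.uniform(0.05, 1.5, J)
            baseline = rng.uniform(3.0, 4.9, J)
            p = make_problem(toy_fit_factory, b, baseline, cap=float(rng.uniform(5, 30)))
            s0 = po.baseline_score(p)
            assert po.feasibility_bound(p) <= 100.0 * (5.0 - s0) / s0 + 1e-9

    def test_bound_nondecreasing_in_cap(self, toy_fit_factory):
        bounds = [
            po.feasibility_bound(make_problem(toy_fit_factory, [0.4, 0.9], [4.2, 4.4], cap=c))
            for c in (0.0, 5.0, 10.0, 15.0, 25.0)
        ]
        assert all(x <= y + 1e-12 for x, y in zip(bounds, bounds[1:]))


class TestSolve:
    def test_target_zero_gives_zero_vector(self, three_item_problem):
        import dataclasses

        p = dataclasses.replace(three_item_problem, target=0.0)
        sol = po.solve_improvement(p)
        assert sol.status == "feasible"
        assert sol.objective == 0.0
        assert not sol.selected

    def test_single_item_solution_is_the_bisection_root(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.9], [4.0], target=1.5,
                         kappa=(0.0, 1.0, 2.0, 3.0))
        sol = po.solve_improvement(p)
        assert sol.status == "feasible"
        # independent bisection on the monotone 1-D gain
        lo, hi = 0.0, po.effective_cap(p, "item0")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if po.predicted_improvement(p, [mid]) < p.target:
                lo = mid
            else:
                hi = mid
        assert sol.delta[0] == pytest.approx(hi, abs=1e-6)

    def test_single_item_infeasible_when_cap_gain_below_target(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.1], [4.8], target=4.0)
        cap_gain = po.predicted_improvement(p, [po.effective_cap(p, "item0")])
        assert cap_gain < p.target
        sol = po.solve_improvement(p)
        assert sol.status == "infeasible"
        assert sol.achieved == pytest.approx(cap_gain)

    def test_three_item_toy_matches_grid_oracle(self, three_item_problem):
        sol = po.solve_improvement(three_item_problem)
        oracle = po.brute_force_oracle(three_item_problem, grid_step=0.1)
        assert sol.status == oracle.status == "feasible"
        assert sol.objective <= oracle.objective + 1e-9
        assert oracle.objective - sol.objective <= 0.2
        assert sol.achieved >= three_item_problem.target - 1e-6

    def test_random_instances_never_beat_or_trail_oracle(self, toy_fit_factory):
        rng = np.random.default_rng(12345)
        for _ in range(10):
            b = rng.uniform(0.1, 1.2, 3)
            baseline = rng.uniform(3.5, 4.8, 3)
            target = float(rng.uniform(0.5, 3.0))
            p = make_problem(toy_fit_factory, b, baseline, target=target)
            sol = po.solve_improvement(p)
            oracle = po.brute_force_oracle(p, grid_step=0.1)
            assert sol.status == oracle.status
            if sol.status == "feasible":
                assert sol.objective <= oracle.objective + 1e-9
                assert oracle.objective - sol.objective <= 0.2
                assert sol.achieved >= target - 1e-6

    def test_infeasible_above_bound_with_diagnostic_caps(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [0.3, 0.4], [4.6, 4.7], target=50.0)
        sol = po.solve_improvement(p)
        assert sol.status == "infeasible"
        assert sol.achieved == pytest.approx(po.feasibility_bound(p))

    def test_empty_eligible_set_with_positive_target_infeasible(self, toy_fit_factory):
        p = make_problem(toy_fit_factory, [-0.2, -0.5], [4.0, 4.0], target=1.0)
        assert po.solve_improvement(p).status == "infeasible"

    def test_constraint_binds_for_feasible_targets(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        for target in (0.5, 1.0, 2.0):
            p = po.ImprovementProblem(fit=surgical_fit, baseline=baseline, target=target)
            sol = po.solve_improvement(p)
            assert sol.status == "feasible"
            assert sol.achieved - target < 0.1

    def test_local_exchange_optimality(self, surgical_fit, surgical_data):
        # shifting 0.1pp of effort from a selected to an unselected eligible
        # item never increases the achieved gain
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        p = po.ImprovementProblem(fit=surgical_fit, baseline=baseline, target=1.5)
        sol = po.solve_improvement(p)
        caps = np.array([po.effective_cap(p, i) for i in items])
        eligible = set(p.eligible_items)
        for j, item_j in enumerate(items):
            if sol.delta[j] < 0.1:
                continue
            for k, item_k in enumerate(items):
                if item_k in eligible and sol.delta[k] <= caps[k] - 0.1 and k != j:
                    moved = sol.delta.copy()
                    moved[j] -= 0.1
                    moved[k] += 0.1
                    assert po.predicted_improvement(p, moved) <= sol.achieved + 1e-9

    def test_monotone_in_target(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        prev_obj, prev_count = -1.0, -1
        for target in (0.5, 1.0, 1.5, 2.0, 2.5):
            p = po.ImprovementProblem(fit=surgical_fit, baseline=baseline, target=target)
            sol = po.solve_improvement(p)
            if sol.status != "feasible":
                break
            assert sol.objective >= prev_obj - 1e-9
            assert len(sol.selected) >= prev_count
            prev_obj, prev_count = sol.objective, len(sol.selected)


class TestOracle:
    def test_refuses_more_than_four_items(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        p = po.ImprovementProblem(fit=surgical_fit, baseline=baseline, target=1.0)
        with pytest.raises(DomainError, match="oracle"):
            po.brute_force_oracle(p)

    def test_target_zero_returns_zero_vector(self, three_item_problem):
        import dataclasses

        sol = po.brute_force_oracle(dataclasses.replace(three_item_problem, target=0.0))
        assert sol.objective == 0.0


class TestPriorityTable:
    def test_target_zero_column_empty_with_count_zero(self, toy_fit_factory):
        fit = toy_fit_factory([0.4, 0.8], PUBLISHED_KAPPA[:4])
        table = po.build_priority_table(fit, [4.2, 4.3], targets=[0.0])
        frame = table.to_frame()
        assert (frame.iloc[:-1]["0%"] == "").all()
        assert table.counts[0] == 0

    def test_counts_equal_nonempty_cells(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        table = po.build_priority_table(surgical_fit, baseline, targets=[1.0, 2.0, 3.0])
        nonempty = np.sum(~np.isnan(table.delta), axis=0)
        assert np.array_equal(nonempty, table.counts)

    def test_counts_nondecreasing_and_infeasible_flagged(self, surgical_fit, surgical_data):
        items = list(surgical_fit.item_ids)
        baseline = surgical_data.frame[items].mean().to_numpy(float)
        table = po.build_priority_table(surgical_fit, baseline,
                                        targets=[1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        feas_counts = table.counts[table.feasible]
        assert all(x <= y for x, y in zip(feas_counts, feas_counts[1:]))
        assert not table.feasible[-1]  # 9% exceeds the scale headroom
        assert "Unfeasible" in table.to_frame().iloc[-1].tolist()

    def test_unsorted_targets_rejected(self, toy_fit_factory):
        fit = toy_fit_factory([0.4], PUBLISHED_KAPPA[:4])
        with pytest.raises(DomainError):
            po.build_priority_table(fit, [4.0], targets=[2.0, 1.0])

    def test_json_round_trip(self, toy_fit_factory, tmp_path):
        import json

        fit = toy_fit_factory([0.4, 0.8], PUBLISHED_KAPPA[:4])
        table = po.build_priority_table(fit, [4.2, 4.3], targets=[1.0, 2.0])
        path = tmp_path / "pt.json"
        table.to_json(path)
        back = po.PriorityTable.from_dict(json.loads(path.read_text()))
        assert back.to_frame().equals(table.to_frame())
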