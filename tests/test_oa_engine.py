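import math

import numpy as np
import pytest

from dynoa import (
    Dataset,
    OaConfig,
    build_master,
    initial_hyperplanes,
    make_fixture,
    obbt_contract,
    refine,
    reformulate,
    run_oa,
    solve_master,
    solve_slave,
    temporal_cuts,
    transcribe,
)
from dynoa.oa_engine import optimality_gap
from dynoa.reformulation import CanonicalForm
from dynoa.relaxation import HyperplaneSet, MasterMilp, PiecewiseConfig
from dynoa.synthetic_data import PINENE_TRUTH

INF = math.inf


def _toy_bilinear_canon():
    return CanonicalForm(
        var_names=["x", "y", "w"], lb=[0, 0, 0], ub=[1, 1, 1],
        var_kind=["theta", "theta", "aux"], rows=[],
        T_bt=[(0, 1, 2)], T_lft=[], T_et=[], T_uft=[],
        objective_residuals=[], aux_defs=[(2, "bilinear", (0, 1))],
        objective_linear={2: -1.0},
    )


class TestSolveMaster:
    def test_toy_corner_exactness(self, contract):
        master = build_master(_toy_bilinear_canon(), PiecewiseConfig(1), HyperplaneSet({}))
        lb, point = solve_master(master, contract)
        assert lb == pytest.approx(-1.0)
        assert (point["x"], point["y"]) == pytest.approx((1.0, 1.0))

    def test_contradictory_cut_infeasible(self, contract):
        canon = _toy_bilinear_canon()
        master = build_master(canon, PiecewiseConfig(1), HyperplaneSet({}))
        # w >= 0 by box; force w <= -1
        master.rows.append(({2: 1.0}, -INF, -1.0))
        assert solve_master(master, contract) is None

    def test_dual_bound_below_feasible_points(self, contract, pinene_clean, rng):
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 3, 2, obs=obs)
        canon = reformulate(nlp)
        master = build_master(canon, PiecewiseConfig(2), initial_hyperplanes(canon, 4))
        lb, _ = solve_master(master, contract)
        for _ in range(3):
            p = {nm: rng.uniform(0, 4e-4) for nm in model.params}
            res = solve_slave(nlp, p, contract)
            assert res.status == "feasible"
            assert lb <= res.sse + 1e-9


class TestSolveSlave:
    def test_zero_noise_truth_start(self, contract, pinene_clean):
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 12, 7, obs=obs)
        res = solve_slave(nlp, dict(PINENE_TRUTH), contract)
        assert res.status == "feasible"
        assert res.sse <= 1e-8

    def test_midpoint_matches_multistart_on_toy(self, contract):
        model, obs, ds, _ = make_fixture("toy_bilinear")
        nlp = transcribe(model, ds, 2, 2, obs=obs)
        mid = solve_slave(nlp, {}, contract)
        rng = np.random.default_rng(0)
        best = min(
            solve_slave(nlp, {"a": rng.uniform(0, 10), "b": rng.uniform(0, 10)}, contract).sse
            for _ in range(10)
        )
        assert mid.status == "feasible"
        assert mid.sse <= best + 1e-6

    def test_unsolvable_dynamics_reported_infeasible(self, contract):
        from dynoa import OdeModel, validate_model, ObservationMap
        import pandas as pd
        from dynoa.synthetic_data import _COLUMNS

        # sqrt of a negative state value makes the stage system unsolvable
        model = validate_model(OdeModel(
            name="bad", states=("x",), observed=("x",),
            params={"k": (0.0, 1.0)}, rhs={"x": "sqrt(x - 10)"},
            z0={"x": 0.0}, horizon=(0.0, 1.0), state_bounds={"x": (0.0, 1.0)},
        ))
        ds = Dataset(pd.DataFrame([("exp1", 1.0, "x", 0.5)], columns=_COLUMNS))
        nlp = transcribe(model, ds, 2, 2)
        res = solve_slave(nlp, {"k": 0.5}, contract)
        assert res.status == "infeasible"
        assert res.sse is None


class TestObbt:
    def _master(self, var_boxes, rows):
        names = list(var_boxes)
        lb = np.array([var_boxes[n][0] for n in names], dtype=float)
        ub = np.array([var_boxes[n][1] for n in names], dtype=float)
        idx = {n: i for i, n in enumerate(names)}
        rows_i = [({idx[n]: c for n, c in coefs.items()}, lo, hi) for coefs, lo, hi in rows]
        return MasterMilp(
            var_names=names, lb=lb, ub=ub, integrality=np.zeros(len(names), dtype=int),
            rows=rows_i, objective={}, alpha_index={}, zprime_index={},
            partition_edges={}, lambda_index={}, canon=None, n_source=len(names),
        )

    def test_two_lp_solves_by_hand(self):
        m = self._master(
            {"x": (0, 1), "y": (0, 0.6)}, [({"x": 1.0, "y": 1.0}, 1.0, 1.0)]
        )
        out = obbt_contract(m, ["x"], rounds=1)
        assert out["x"] == pytest.approx((0.4, 1.0), abs=1e-6)

    def test_vacuous_contraction(self):
        m = self._master({"x": (0, 1), "y": (0, 1)}, [({"y": 1.0}, 0.0, 1.0)])
        out = obbt_contract(m, ["x"], rounds=1)
        assert out["x"] == pytest.approx((0.0, 1.0))

    def test_chain_propagation_two_rounds(self):
        m = self._master(
            {"x": (0, 1), "y": (0, 1), "w": (0.2, 0.3)},
            [({"x": 1.0, "y": -1.0}, 0.0, 0.0), ({"y": 1.0, "w": -1.0}, 0.0, 0.0)],
        )
        out = obbt_contract(m, ["x", "y"], rounds=2)
        assert out["x"] == pytest.approx((0.2, 0.3), abs=1e-6)

    def test_rounds_validated(self):
        m = self._master({"x": (0, 1)}, [])
        with pytest.raises(ValueError):
            obbt_contract(m, ["x"], rounds=0)


class TestTemporalCuts:
    def test_zero_noise_cuts_inactive(self, contract, pinene_clean):
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 5, 3, obs=obs)
        cuts = temporal_cuts(
            nlp, [(1, 2, 3, 4), (2, 3, 4, 5)], contract, PiecewiseConfig(1), anchors_init=4
        )
        assert len(cuts) == 2
        for coefs, lo, hi in cuts:
            assert lo >= 0.0  # nonnegative right-hand side
            assert lo <= 1e-8  # truth attains zero partial SSE
            assert hi == INF
            assert all(nm.startswith("alpha_") for nm in coefs)

    def test_full_window_matches_full_bound(self, contract):
        import pandas as pd

        from dynoa.synthetic_data import _COLUMNS, _toy_linear

        model, obs = _toy_linear()
        frame = pd.DataFrame(
            [("exp1", 1.0, "z", 0.0), ("exp1", 2.0, "z", 10.0)], columns=_COLUMNS
        )
        nlp = transcribe(model, Dataset(frame), 2, 2, obs=obs)
        canon = reformulate(nlp)
        master = build_master(canon, PiecewiseConfig(1), initial_hyperplanes(canon, 8))
        lb_full, _ = solve_master(master, contract)
        (coefs, lo, _hi), = temporal_cuts(
            nlp, [(1, 2)], contract, PiecewiseConfig(1), anchors_init=8
        )
        assert lo == pytest.approx(lb_full, rel=1e-6, abs=1e-9)

    def test_noncontiguous_window_rejected(self, contract, pinene_clean):
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 5, 3, obs=obs)
        with pytest.raises(ValueError, match="contiguous"):
            temporal_cuts(nlp, [(1, 3)], contract)


class TestRefine:
    def test_bisect_active_segment(self, contract):
        canon = _toy_bilinear_canon()
        pw = PiecewiseConfig(np_init=2)
        master = build_master(canon, pw, HyperplaneSet({}))
        pw, _hp, actions = refine(
            pw, HyperplaneSet({}), master, {"x": 0.3, "y": 1.0, "w": 0.3}, "bisect"
        )
        assert actions
        assert pw.edges["x"] == pytest.approx([0.0, 0.25, 0.5, 1.0])

    def test_duplicate_anchor_is_noop(self, contract):
        model, obs, ds, _ = make_fixture("toy_linear")
        nlp = transcribe(model, ds, 2, 2, obs=obs)
        canon = reformulate(nlp)
        hp = initial_hyperplanes(canon, 3)
        master = build_master(canon, PiecewiseConfig(1), hp)
        point = {master.var_names[kz]: hp.anchors[master.var_names[kz]][0]
                 for kz in master.zprime_index.values()}
        _pw, _hp, actions = refine(PiecewiseConfig(1), hp, master, point, "add-anchor")
        assert actions == []

    def test_anchor_add_never_decreases_lb(self, contract):
        import pandas as pd

        from dynoa.synthetic_data import _COLUMNS, _toy_linear

        model, obs = _toy_linear()
        frame = pd.DataFrame(
            [("exp1", 1.0, "z", 0.0), ("exp1", 2.0, "z", 10.0)], columns=_COLUMNS
        )
        nlp = transcribe(model, Dataset(frame), 2, 2, obs=obs)
        canon = reformulate(nlp)
        pw = PiecewiseConfig(1)
        hp = initial_hyperplanes(canon, 2)
        lb_prev = -INF
        for _ in range(4):
            master = build_master(canon, pw, hp)
            lb, point = solve_master(master, contract)
            assert lb >= lb_prev - 1e-9
            lb_prev = lb
            pw, hp, _ = refine(pw, hp, master, point, "add-anchor")


class TestRunOa:
    def test_toy_linear_one_iteration(self, contract):
        model, obs, ds, truth = make_fixture("toy_linear")
        cfg = OaConfig(ne=2, nk=2, np_init=1, anchors_init=3, obbt_rounds=0,
                       multistart=2, seed=0, max_iterations=5)
        best, ledger, status = run_oa(model, ds, cfg, contract, obs=obs)
        assert status == "converged"
        assert len(ledger.rows) == 1
        assert best["theta"] == pytest.approx(2.0, abs=1e-9)
        assert ledger.UB <= 1e-12
        assert abs(ledger.LB) <= 1e-9

    def test_giant_tolerance_stops_first_pair(self, contract, pinene_noisy):
        model, obs, ds, _ = pinene_noisy
        cfg = OaConfig(ne=3, nk=2, np_init=1, anchors_init=2, obbt_rounds=0,
                       multistart=2, seed=0, max_iterations=9, tol=1e6)
        _best, ledger, status = run_oa(model, ds, cfg, contract, obs=obs)
        assert status == "converged"
        assert len(ledger.rows) == 1

    def test_ledger_monotone_and_sandwich(self, contract, pinene_noisy):
        model, obs, ds, _ = pinene_noisy
        cfg = OaConfig(ne=3, nk=2, np_init=2, anchors_init=3, obbt_rounds=0,
                       multistart=3, seed=1, max_iterations=3, tol=1e-9,
                       fixed_np=False, refinement="both")
        _best, ledger, status = run_oa(model, ds, cfg, contract, obs=obs)
        assert status == "iteration_cap"
        lbs = [r["LB"] for r in ledger.rows]
        ubs = [r["UB"] for r in ledger.rows]
        assert all(b >= a - 1e-12 for a, b in zip(lbs, lbs[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(ubs, ubs[1:]))
        assert all(lb <= ub + 1e-9 for lb, ub in zip(lbs, ubs))

    def test_determinism(self, contract):
        model, obs, ds, _ = make_fixture("toy_bilinear")
        cfg = OaConfig(ne=2, nk=2, np_init=2, anchors_init=3, obbt_rounds=0,
                       multistart=3, seed=11, max_iterations=2, tol=1e-12,
                       fixed_np=False, refinement="both")
        out1 = run_oa(model, ds, cfg, contract, obs=obs)
        out2 = run_oa(model, ds, cfg, contract, obs=obs)
        assert out1[2] == out2[2]
        assert out1[1].rows == out2[1].rows


class TestGap:
    def test_relative_and_guarded(self):
        assert optimality_gap(19.26, 19.87) == pytest.approx(0.0307, abs=1e-4)
        assert optimality_gap(0.0, 5e-13) == pytest.approx(5e-13)
        assert optimality_gap(0.0, INF) == INF
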