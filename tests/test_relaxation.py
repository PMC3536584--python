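import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynoa import (
    build_master,
    hyperplane_rows,
    initial_hyperplanes,
    mccormick_rows,
    piecewise_mccormick_rows,
    reformulate,
    secant_rows,
    transcribe,
    write_lp,
)
from dynoa.relaxation import HyperplaneSet, PiecewiseConfig

INF = math.inf


def _row_holds(coefs, lo, hi, values, tol=1e-9):
    lhs = sum(v * values[k] for k, v in coefs.items())
    return lo - tol <= lhs <= hi + tol


def _z_range(xbox, ybox, xv, yv, rows):
    """Feasible range of z at fixed (x, y) under envelope rows (LP in z)."""
    zmin, zmax = -INF, INF
    for coefs, lo, hi in rows:
        cz = coefs.get("z", 0.0)
        rest = sum(v * {"x": xv, "y": yv}.get(k, 0.0) for k, v in coefs.items() if k != "z")
        if cz == 0:
            continue
        # lo <= cz*z + rest <= hi
        a, b = (lo - rest) / cz, (hi - rest) / cz
        a, b = min(a, b), max(a, b)
        zmin, zmax = max(zmin, a), min(zmax, b)
    return zmin, zmax


class TestMcCormick:
    def test_center_gap_is_quarter_box_area(self):
        rows = mccormick_rows((0, 1), (0, 1))
        zmin, zmax = _z_range((0, 1), (0, 1), 0.5, 0.5, rows)
        assert (zmin, zmax) == pytest.approx((0.0, 0.5))
        # worst-case gap over the box is (xU-xL)(yU-yL)/4 at the center
        assert zmax - 0.25 == pytest.approx(0.25)

    @pytest.mark.parametrize("corner", [(0, 0), (0, 1), (1, 0), (1, 1)])
    def test_exact_at_corners(self, corner):
        rows = mccormick_rows((0, 1), (0, 1))
        xv, yv = corner
        zmin, zmax = _z_range((0, 1), (0, 1), xv, yv, rows)
        assert zmin == pytest.approx(xv * yv, abs=1e-12)
        assert zmax == pytest.approx(xv * yv, abs=1e-12)

    def test_degenerate_box_is_exact(self):
        rows = mccormick_rows((2, 2), (0, 1))
        assert rows == [({"z": 1.0, "y": -2.0}, 0.0, 0.0)]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        xl=st.floats(-10, 10), yl=st.floats(-10, 10),
        wx=st.floats(1e-3, 10), wy=st.floats(1e-3, 10),
        fx=st.floats(0, 1), fy=st.floats(0, 1), npseg=st.integers(1, 6),
    )
    def test_envelopes_never_cut_true_points(self, xl, yl, wx, wy, fx, fy, npseg):
        """Property: for any box and any point with z = x*y, the plain and
        piecewise envelopes (with the witness binaries) are satisfied."""
        xu, yu = xl + wx, yl + wy
        xv = xl + fx * wx
        yv = yl + fy * wy
        values = {"x": xv, "y": yv, "z": xv * yv}
        tol = 1e-9 * max(1.0, abs(xv * yv), xu * xu, yu * yu)
        for coefs, lo, hi in mccormick_rows((xl, xu), (yl, yu)):
            assert _row_holds(coefs, lo, hi, values, tol)
        rows, edges = piecewise_mccormick_rows((xl, xu), (yl, yu), npseg)
        values.update(_pw_point(edges, yl, yu, xv, yv))
        for coefs, lo, hi in rows:
            assert _row_holds(coefs, lo, hi, values, tol)

    def test_validity_at_random_points(self, rng):
        """Core safety property: envelopes never cut off a true z = x*y."""
        for _ in range(1000):
            xl, yl = rng.uniform(-5, 5, 2)
            xu = xl + rng.uniform(0.01, 5)
            yu = yl + rng.uniform(0.01, 5)
            xv = rng.uniform(xl, xu)
            yv = rng.uniform(yl, yu)
            values = {"x": xv, "y": yv, "z": xv * yv}
            for coefs, lo, hi in mccormick_rows((xl, xu), (yl, yu)):
                assert _row_holds(coefs, lo, hi, values)


def _pw_point(edges, yl, yu, xv, yv):
    """Construct the (lambda, dy) witness for a true point x, y."""
    NP = len(edges) - 1
    n = min(max(np.searchsorted(edges, xv, side="right") - 1, 0), NP - 1)
    values = {}
    for m in range(NP):
        values[("lam", m)] = 1.0 if m == n else 0.0
        values[("dy", m)] = (yv - yl) if m == n else 0.0
    return values


class TestPiecewise:
    def test_np1_equals_plain_mccormick(self):
        rows, edges = piecewise_mccormick_rows((0, 1), (0, 1), 1)
        for xv in (0.0, 0.3, 1.0):
            for yv in (0.0, 0.7, 1.0):
                vals = {"x": xv, "y": yv, **_pw_point(edges, 0, 1, xv, yv)}
                plain = _z_range((0, 1), (0, 1), xv, yv, mccormick_rows((0, 1), (0, 1)))
                sub = [(
                    {k: v for k, v in coefs.items() if k in ("x", "y", "z")},
                    lo - sum(v * vals[k] for k, v in coefs.items()
                             if k not in ("x", "y", "z")) if lo != -INF else -INF,
                    hi - sum(v * vals[k] for k, v in coefs.items()
                             if k not in ("x", "y", "z")) if hi != INF else INF,
                ) for coefs, lo, hi in rows if "z" in coefs]
                pw = _z_range((0, 1), (0, 1), xv, yv, sub)
                assert pw == pytest.approx(plain, abs=1e-9)

    def test_np2_halves_worst_gap(self):
        rows, edges = piecewise_mccormick_rows((0, 1), (0, 1), 2)
        worst = 0.0
        for xv in np.linspace(0, 1, 9):
            for yv in np.linspace(0, 1, 9):
                vals = {"x": xv, "y": yv, **_pw_point(edges, 0, 1, xv, yv)}
                sub = [(
                    {k: v for k, v in coefs.items() if k in ("x", "y", "z")},
                    lo if lo == -INF else lo - sum(
                        v * vals[k] for k, v in coefs.items() if k not in ("x", "y", "z")),
                    hi if hi == INF else hi - sum(
                        v * vals[k] for k, v in coefs.items() if k not in ("x", "y", "z")),
                ) for coefs, lo, hi in rows if "z" in coefs]
                zmin, zmax = _z_range((0, 1), (0, 1), xv, yv, sub)
                worst = max(worst, zmax - xv * yv, xv * yv - zmin)
        assert worst == pytest.approx(0.125, abs=1e-9)

    @pytest.mark.parametrize("NP", [1, 2, 3, 5])
    def test_true_points_admit_witness(self, rng, NP):
        """Any feasible (x, y, z = xy) extends to a feasible (lambda, dy)."""
        for _ in range(200):
            xl, yl = rng.uniform(-3, 3, 2)
            xu = xl + rng.uniform(0.05, 4)
            yu = yl + rng.uniform(0.05, 4)
            rows, edges = piecewise_mccormick_rows((xl, xu), (yl, yu), NP)
            xv = rng.uniform(xl, xu)
            yv = rng.uniform(yl, yu)
            values = {"x": xv, "y": yv, "z": xv * yv}
            values.update(_pw_point(edges, yl, yu, xv, yv))
            for coefs, lo, hi in rows:
                assert _row_holds(coefs, lo, hi, values)

    def test_explicit_edges_validated(self):
        with pytest.raises(ValueError):
            piecewise_mccormick_rows((0, 1), (0, 1), [0.0, 0.7, 0.5, 1.0])
        with pytest.raises(ValueError):
            piecewise_mccormick_rows((0, 1), (0, 1), 0)


class TestSecant:
    def test_exp_convex_pair(self):
        rows = secant_rows("exp", (0.0, 1.0))
        for xv in np.linspace(0, 1, 11):
            zv = math.exp(xv)
            for coefs, lo, hi in rows:
                assert _row_holds(coefs, lo, hi, {"x": xv, "z": zv})
        # secant over-estimates strictly inside, tight at the endpoints
        sec = rows[0]
        for xv, strict in ((0.0, False), (0.5, True), (1.0, False)):
            bound = sec[2] + sum(-v * xv for k, v in sec[0].items() if k == "x")
            gap = bound - math.exp(xv)
            assert gap >= -1e-12
            assert (gap > 1e-3) == strict

    def test_log_concave_pair(self):
        rows = secant_rows("log", (1.0, math.e))
        for xv in np.linspace(1.0, math.e, 11):
            zv = math.log(xv)
            for coefs, lo, hi in rows:
                assert _row_holds(coefs, lo, hi, {"x": xv, "z": zv})

    def test_odd_power_through_zero_rejected(self):
        with pytest.raises(ValueError, match="curvature"):
            secant_rows("pow", (-1.0, 1.0), 3)


class TestHyperplanes:
    def test_tangency(self):
        rows = hyperplane_rows([2.0])
        (coefs, lo, _hi), = rows
        # alpha >= 4 + 4 (z' - 2): at z' = 2 the bound equals the square
        assert coefs["alpha"] * 4.0 + coefs["zp"] * 2.0 >= lo - 1e-12
        assert 4.0 + coefs["zp"] * 2.0 == pytest.approx(lo)

    def test_three_anchor_bound(self):
        rows = hyperplane_rows([-1.0, 0.0, 1.0])
        zp = 0.5
        bound = max((lo - coefs["zp"] * zp) for coefs, lo, _ in rows)
        assert bound == pytest.approx(0.0)
        assert bound <= zp ** 2

    def test_underestimates_square_everywhere(self, rng):
        anchors = rng.uniform(-5, 5, 7)
        rows = hyperplane_rows(anchors)
        for zp in rng.uniform(-6, 6, 200):
            bound = max((lo - coefs["zp"] * zp) for coefs, lo, _ in rows)
            assert bound <= zp ** 2 + 1e-9


class TestBuildMaster:
    def test_np1_master_is_pure_lp(self, pinene_clean):
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 5, 3, obs=obs)
        canon = reformulate(nlp)
        m = build_master(canon, PiecewiseConfig(np_init=1), initial_hyperplanes(canon, 1))
        assert int(m.integrality.sum()) == 0

    def test_case1_binary_count(self, pinene_clean):
        """With the five rate constants partitioned into 4 segments each the
        master carries 5*4 = 20 binaries, independent of the atom count."""
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 5, 3, obs=obs)
        canon = reformulate(nlp)
        m = build_master(canon, PiecewiseConfig(np_init=4), initial_hyperplanes(canon, 6))
        assert int(m.integrality.sum()) == 20
        assert len(m.alpha_index) == 40

    def test_lp_export(self, pinene_clean):
        model, obs, ds, _ = pinene_clean
        nlp = transcribe(model, ds, 2, 2, obs=obs)
        canon = reformulate(nlp)
        m = build_master(canon, PiecewiseConfig(np_init=2), initial_hyperplanes(canon, 2))
        text = write_lp(m)
        assert text.startswith("\\ master relaxation")
        assert "Binary" in text and "Bounds" in text and "End" in text


class TestMonotoneTightening:
    def _lb(self, master, contract):
        from dynoa.oa_engine import solve_master

        lb, _ = solve_master(master, contract)
        return lb

    def test_lb_nondecreasing_in_np(self, contract):
        # max xy s.t. x + y = 1 over [0,1]^2 (as min -z): the single-segment
        # envelope gives -0.5; partitioning x tightens towards -0.25
        from dynoa.reformulation import CanonicalForm

        canon = CanonicalForm(
            var_names=["x", "y", "w"], lb=[0, 0, 0], ub=[1, 1, 1],
            var_kind=["theta", "theta", "aux"],
            rows=[({0: 1.0, 1: 1.0}, 1.0)],
            T_bt=[(0, 1, 2)], T_lft=[], T_et=[], T_uft=[],
            objective_residuals=[], aux_defs=[(2, "bilinear", (0, 1))],
            objective_linear={2: -1.0},
        )
        lbs = [
            self._lb(build_master(canon, PiecewiseConfig(np_init=np_), HyperplaneSet({})), contract)
            for np_ in (1, 2, 4, 8)
        ]
        assert lbs[0] == pytest.approx(-0.5)
        for a, b in zip(lbs, lbs[1:]):
            assert b >= a - 1e-9
        # segment width 1/8 bounds the envelope error by width/4 = 1/32
        assert lbs[-1] >= -0.25 - 1.0 / 32 - 1e-9
        # all remain valid lower bounds on min -xy = -0.25
        assert all(lb <= -0.25 + 1e-9 for lb in lbs)

    def test_lb_nondecreasing_in_anchors(self, contract):
        # fit dz/dt = theta to inconsistent data: optimal SSE is 20; the
        # hyper-plane relaxation approaches it from below as anchors grow
        import pandas as pd

        from dynoa import Dataset
        from dynoa.synthetic_data import _COLUMNS, _toy_linear

        model, obs = _toy_linear()
        frame = pd.DataFrame(
            [("exp1", 1.0, "z", 0.0), ("exp1", 2.0, "z", 10.0)], columns=_COLUMNS
        )
        nlp = transcribe(model, Dataset(frame), 2, 2, obs=obs)
        canon = reformulate(nlp)
        lbs = []
        for n_anchor in (2, 6, 20):
            m = build_master(
                canon, PiecewiseConfig(np_init=1), initial_hyperplanes(canon, n_anchor)
            )
            lbs.append(self._lb(m, contract))
        for a, b in zip(lbs, lbs[1:]):
            assert b >= a - 1e-9
        assert all(lb <= 20.0 + 1e-6 for lb in lbs)
        assert lbs[-1] >= 15.0  # 20 anchors already come close
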