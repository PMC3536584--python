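"""Outer-approximation engine.

The loop alternates a master MILP relaxation (rigorous lower bound: the
solver's *proven dual bound*, never the incumbent objective, so early
termination cannot break rigor) with a local solve of the original
transcription (upper bound), refining the relaxation — extra objective
hyper-planes and/or bisection of active piecewise segments — until the
optimality gap |UB - LB| / |UB| falls below tolerance.  Optional
optimality-based bound tightening (OBBT) contracts the collocation-coefficient
boxes before the loop, and temporal strengthening cuts bound the partial
fitting error of element windows from below by window-restricted sub-master
bounds.

Solver backends sit behind :class:`SolverContract`.  The defaults use HiGHS
through :func:`scipy.optimize.milp`/``linprog`` for the master, and a reduced
local method for the slave: the square collocation system is eliminated by
element marching, and the remaining degrees of freedom (parameters, free
initial conditions, offsets) are fitted with a bounded trust-region
least-squares solve.  Any point the slave returns satisfies the transcription
equations to Newton tolerance, so its SSE is a valid upper bound.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, least_squares, linprog, milp
from scipy.sparse import csr_matrix

from .collocation import (
    TranscribedNlp,
    evaluate_trajectory,
    lagrange_values,
    locate_measurement,
    simulate_collocation,
    transcribe,
)
from .model_core import FreeInitial, ObservationMap, OdeModel
from .reformulation import CanonicalForm, reformulate
from .relaxation import (
    HyperplaneSet,
    MasterMilp,
    PiecewiseConfig,
    build_master,
    initial_hyperplanes,
)
from .synthetic_data import Dataset

__all__ = [
    "OaConfig",
    "MilpResult",
    "NlpResult",
    "ScipyMilpBackend",
    "ReducedNlpBackend",
    "SolverContract",
    "BoundsLedger",
    "solve_master",
    "solve_slave",
    "obbt_contract",
    "temporal_cuts",
    "refine",
    "run_oa",
]

_INF = math.inf

#: below this magnitude of UB the optimality gap is measured absolutely
GAP_GUARD = 1e-12


@dataclass
class OaConfig:
    """Run configuration with the benchmark defaults (NE=5, NK=3, 4 piecewise
    intervals, 6 initial hyper-planes, 5% tolerance, 3 OBBT rounds)."""

    ne: int = 5
    nk: int = 3
    np_init: int = 4
    anchors_init: int = 6
    tol: float = 0.05
    refinement: str = "add-anchor"  # "add-anchor" | "bisect" | "both"
    fixed_np: bool = True  # keep the piecewise count constant (anchors only)
    obbt_rounds: int = 3
    obbt_targets: str = "xi"  # "xi" | "all" | "none"
    multistart: int = 8
    seed: int = 0
    max_iterations: int = 25
    time_limit: float | None = None
    milp_time_limit: float | None = None
    share_common: bool = True
    edges: tuple[float, ...] | None = None  # explicit element edges
    temporal_windows: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("iteration cap must be positive")
        if self.ne < 1 or self.nk < 1:
            raise ValueError("discretization sizes must be positive")
        if self.np_init < 1 or self.anchors_init < 1:
            raise ValueError("piecewise/hyper-plane counts must be positive")
        if self.refinement not in ("add-anchor", "bisect", "both"):
            raise ValueError(f"unknown refinement policy {self.refinement!r}")
        if self.time_limit is not None and self.time_limit <= 0:
            raise ValueError("time limit must be positive")


@dataclass
class MilpResult:
    status: str  # "optimal" | "limit" | "infeasible" | "failure"
    x: np.ndarray | None
    objective: float | None
    dual_bound: float


@dataclass
class NlpResult:
    status: str  # "feasible" | "infeasible" | "failure"
    point: dict[str, float] | None
    sse: float | None


class ScipyMilpBackend:
    """Master solver on HiGHS via scipy; returns the proven dual bound."""

    def __init__(self, time_limit: float | None = None, mip_rel_gap: float = 1e-9):
        self.time_limit = time_limit
        self.mip_rel_gap = mip_rel_gap

    def solve(self, master: MasterMilp) -> MilpResult:
        n = len(master.var_names)
        c = np.zeros(n)
        for i, v in master.objective.items():
            c[i] = v
        rows_i, cols, vals, cl, cu = [], [], [], [], []
        for r, (coefs, rlo, rhi) in enumerate(master.rows):
            for i, v in coefs.items():
                rows_i.append(r)
                cols.append(i)
                vals.append(v)
            cl.append(rlo)
            cu.append(rhi)
        A = csr_matrix((vals, (rows_i, cols)), shape=(len(master.rows), n))
        options = {}
        if self.time_limit is not None:
            options["time_limit"] = self.time_limit
        if master.integrality.any():
            options["mip_rel_gap"] = self.mip_rel_gap
        res = milp(
            c,
            constraints=LinearConstraint(A, np.array(cl), np.array(cu)),
            integrality=master.integrality,
            bounds=Bounds(master.lb, master.ub),
            options=options,
        )
        if res.status == 2:
            return MilpResult("infeasible", None, None, _INF)
        if res.x is None:
            return MilpResult("failure", None, None, -_INF)
        dual = getattr(res, "mip_dual_bound", None)
        if dual is None or not np.isfinite(dual):
            # continuous problem (or solver without a reported bound): the
            # optimum itself is the proven bound only at optimal status
            dual = res.fun if res.status == 0 else -_INF
        status = "optimal" if res.status == 0 else "limit"
        return MilpResult(status, np.asarray(res.x), float(res.fun), float(dual))


class ReducedNlpBackend:
    """Local solver for the transcription via variable elimination.

    Decision variables are the parameters and extra degrees of freedom; the
    collocation coefficients are recovered by element marching for each trial
    point, and a bounded trust-region least-squares iteration minimizes the
    measurement residual vector.
    """

    def __init__(self, ftol: float = 1e-14, xtol: float = 1e-14, max_nfev: int | None = None):
        self.ftol = ftol
        self.xtol = xtol
        self.max_nfev = max_nfev

    # -- reduced parameterization ------------------------------------------
    @staticmethod
    def free_names(nlp: TranscribedNlp) -> list[str]:
        return [v.name for v in nlp.variables if v.kind in ("theta", "extra")]

    @staticmethod
    def _point_from(nlp: TranscribedNlp, pvec: np.ndarray, names: Sequence[str]):
        """Full transcription point (xi, zhat, theta, extras) from the reduced
        vector; raises RuntimeError if the collocation solve fails."""
        model, obs, scheme = nlp.model, nlp.obs, nlp.scheme
        vals = dict(zip(names, map(float, pvec)))
        theta = [vals[p] for p in model.params]
        point = dict(vals)
        residual_vec = []
        for u in nlp.dataset.experiments:
            extra = []
            for d, dof in model.extra_dof.items():
                extra.append(vals[f"{d}_{u}"] if dof.per_experiment else vals[d])
            z0 = []
            for s in model.states:
                iv = model.initial_value(s, u)
                z0.append(vals[f"{s}0_{u}"] if isinstance(iv, FreeInitial) else float(iv))
            xi = simulate_collocation(model, scheme, theta, z0, extra)
            for e in range(scheme.ne):
                for k in range(scheme.nk + 1):
                    for sj, s in enumerate(model.states):
                        point[f"xi_{u}_e{e + 1}_k{k}_{s}"] = float(xi[e, k, sj])
            extra_by_name = dict(zip(model.extra_dof, extra))
            for nm, zbar, (uu, t_u, j) in nlp.residuals:
                if uu != u:
                    continue
                zj = evaluate_trajectory(xi, scheme, t_u)[model.states.index(j)]
                sc = obs.scale_of(j)
                off = obs.offset_of(j)
                sc = extra_by_name[sc] if isinstance(sc, str) else float(sc)
                off = extra_by_name[off] if isinstance(off, str) else float(off)
                zhat = sc * zj + off
                point[nm] = float(zhat)
                residual_vec.append(zhat - zbar)
        return point, np.asarray(residual_vec)

    def solve(self, nlp: TranscribedNlp, start: Mapping[str, float]) -> NlpResult:
        names = self.free_names(nlp)
        boxes = nlp.boxes()
        lo = np.array([boxes[nm][0] for nm in names])
        hi = np.array([boxes[nm][1] for nm in names])
        x0 = np.array([
            float(start.get(nm, 0.5 * (boxes[nm][0] + boxes[nm][1]))) for nm in names
        ])
        x0 = np.clip(x0, lo, hi)

        def fun(p):
            _, r = self._point_from(nlp, p, names)
            return r

        try:
            res = least_squares(
                fun, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                ftol=self.ftol, xtol=self.xtol, gtol=1e-14, max_nfev=self.max_nfev,
            )
            point, r = self._point_from(nlp, res.x, names)
        except RuntimeError:
            return NlpResult("infeasible", None, None)
        except Exception:  # pragma: no cover - backend failure is retryable
            return NlpResult("failure", None, None)
        return NlpResult("feasible", point, float(np.dot(r, r)))


@dataclass
class SolverContract:
    """Abstract MILP + local-NLP backend pair used by the engine."""

    milp: ScipyMilpBackend = field(default_factory=ScipyMilpBackend)
    nlp: ReducedNlpBackend = field(default_factory=ReducedNlpBackend)


def default_contract(config: OaConfig | None = None) -> SolverContract:
    milp_tl = config.milp_time_limit if config else None
    return SolverContract(milp=ScipyMilpBackend(time_limit=milp_tl))


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

@dataclass
class BoundsLedger:
    """Append-only per-iteration trace with monotone running bounds."""

    rows: list[dict] = field(default_factory=list)

    @property
    def LB(self) -> float:
        return self.rows[-1]["LB"] if self.rows else -_INF

    @property
    def UB(self) -> float:
        return self.rows[-1]["UB"] if self.rows else _INF

    def append(self, it: int, lb_it: float, ub_it: float | None, action: str) -> dict:
        LB = max(self.LB, lb_it)
        UB = min(self.UB, ub_it) if ub_it is not None else self.UB
        row = {
            "iteration": it, "lb_it": lb_it,
            "ub_it": ub_it if ub_it is not None else _INF,
            "LB": LB, "UB": UB, "gap": optimality_gap(LB, UB), "action": action,
        }
        self.rows.append(row)
        return row


def optimality_gap(lb: float, ub: float) -> float:
    """|UB - LB| / |UB|, measured absolutely when UB is numerically zero."""
    if not math.isfinite(ub):
        return _INF
    if abs(ub) < GAP_GUARD:
        return abs(ub - lb)
    return abs(ub - lb) / abs(ub)


# ---------------------------------------------------------------------------
# Engine operations
# ---------------------------------------------------------------------------

def solve_master(master: MasterMilp, contract: SolverContract):
    """Solve the relaxation; returns ``(lb, point-by-name)`` or raises on
    backend failure; proven infeasibility is reported as status."""
    res = contract.milp.solve(master)
    if res.status == "infeasible":
        return None
    if res.x is None:
        raise RuntimeError("master solver failure (no incumbent, no proof)")
    point = {nm: float(res.x[i]) for i, nm in enumerate(master.var_names)}
    return res.dual_bound, point


def solve_slave(nlp: TranscribedNlp, start: Mapping[str, float], contract: SolverContract):
    """Local solve of the transcription from ``start`` (missing entries are
    filled from box midpoints inside the backend)."""
    return contract.nlp.solve(nlp, start)


def _lp_arrays(master: MasterMilp):
    n = len(master.var_names)
    rows_i, cols, vals, cl, cu = [], [], [], [], []
    for r, (coefs, rlo, rhi) in enumerate(master.rows):
        for i, v in coefs.items():
            rows_i.append(r)
            cols.append(i)
            vals.append(v)
        cl.append(rlo)
        cu.append(rhi)
    A = csr_matrix((vals, (rows_i, cols)), shape=(len(master.rows), n))
    return A, np.array(cl), np.array(cu)


def obbt_contract(
    master: MasterMilp, targets: Sequence[str], rounds: int = 1
) -> dict[str, tuple[float, float]]:
    """Optimality-based bound tightening over the master's LP relaxation.

    Minimizes and maximizes each target variable subject to the master rows
    (binaries relaxed to [0, 1], which keeps every bound valid), replacing its
    box by the optima; repeated ``rounds`` times so contractions propagate.
    Boxes never widen.  Raises RuntimeError if a box empties (master
    infeasible).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    lb = master.lb.astype(float).copy()
    ub = master.ub.astype(float).copy()
    idxs = [master.index(nm) for nm in targets]
    A, cl, cu = _lp_arrays(master)
    ineq_mask = cl != cu
    for _ in range(rounds):
        for i in idxs:
            for sense in (1.0, -1.0):
                c = np.zeros(len(lb))
                c[i] = sense
                res = linprog(
                    c,
                    A_ub=None if not ineq_mask.any() else _stack_ub(A, cl, cu, ineq_mask),
                    b_ub=None if not ineq_mask.any() else _stack_ub_rhs(cl, cu, ineq_mask),
                    A_eq=A[~ineq_mask] if (~ineq_mask).any() else None,
                    b_eq=cl[~ineq_mask] if (~ineq_mask).any() else None,
                    bounds=np.column_stack([lb, ub]),
                    method="highs",
                )
                if res.status == 2:
                    raise RuntimeError("OBBT proved the master infeasible")
                if res.status != 0:
                    continue  # keep the old bound on numerical trouble
                if sense > 0:
                    lb[i] = max(lb[i], res.fun - 1e-12 * max(1.0, abs(res.fun)))
                else:
                    ub[i] = min(ub[i], -res.fun + 1e-12 * max(1.0, abs(res.fun)))
    return {master.var_names[i]: (float(lb[i]), float(ub[i])) for i in idxs}


def _stack_ub(A, cl, cu, mask):
    from scipy.sparse import vstack

    Am = A[mask]
    blocks = []
    if np.isfinite(cu[mask]).any():
        blocks.append(Am[np.isfinite(cu[mask])])
    if np.isfinite(cl[mask]).any():
        blocks.append(-Am[np.isfinite(cl[mask])])
    return vstack(blocks)


def _stack_ub_rhs(cl, cu, mask):
    out = []
    cum = cu[mask]
    clm = cl[mask]
    if np.isfinite(cum).any():
        out.append(cum[np.isfinite(cum)])
    if np.isfinite(clm).any():
        out.append(-clm[np.isfinite(clm)])
    return np.concatenate(out)


def temporal_cuts(
    nlp: TranscribedNlp,
    windows: Sequence[Sequence[int]],
    contract: SolverContract,
    pw: PiecewiseConfig | None = None,
    anchors_init: int = 6,
    share_common: bool = True,
):
    """Strengthening cuts from temporally decomposed sub-relaxations.

    For each contiguous element window, a sub-master keeps only that window's
    residual equations, the continuity rows interior to the window (the rows
    entering the window's first element are removed; the initial condition is
    kept only when element 1 belongs to the window), and the measurements
    falling inside.  Its proven dual bound is a valid lower bound on the
    partial SSE of those measurements, emitted as a row for the full master.
    """
    cuts = []
    for window in windows:
        w = sorted(window)
        if w != list(range(w[0], w[-1] + 1)):
            raise ValueError(f"window {window} is not a contiguous element range")
        e1, e2 = w[0], w[-1]
        eqs = []
        for eq in nlp.equations:
            if eq.family == "residual" and e1 <= eq.meta[1] <= e2:
                eqs.append(eq)
            elif eq.family == "continuity" and e1 + 1 <= eq.meta[1] <= e2:
                eqs.append(eq)
            elif eq.family == "initial" and e1 == 1:
                eqs.append(eq)
        keys = []
        residuals = []
        for nm, zbar, key in nlp.residuals:
            e_u, _ = locate_measurement(key[1], nlp.scheme)
            if e1 <= e_u <= e2:
                residuals.append((nm, zbar, key))
                keys.append((nm, key))
        meas_eqs = [
            eq for eq in nlp.equations
            if eq.family == "measurement" and any(eq.meta == key for _, key in keys)
        ]
        sub = TranscribedNlp(
            model=nlp.model, obs=nlp.obs, dataset=nlp.dataset, scheme=nlp.scheme,
            variables=list(nlp.variables), equations=eqs + meas_eqs, residuals=residuals,
        )
        canon = reformulate(sub, share_common=share_common)
        hp = initial_hyperplanes(canon, anchors_init)
        master = build_master(canon, pw, hp)
        res = contract.milp.solve(master)
        if res.status == "infeasible":
            raise RuntimeError(f"temporal sub-master for window {window} infeasible")
        bound = max(res.dual_bound, 0.0)
        coefs = {f"alpha_zp_{nm}": 1.0 for nm, _key in keys}
        cuts.append((coefs, bound, _INF))
    return cuts


def refine(
    pw: PiecewiseConfig,
    hp: HyperplaneSet,
    master: MasterMilp,
    relax_point: Mapping[str, float],
    policy: str = "add-anchor",
    tol: float = 1e-9,
):
    """Refinement step 4b: add a hyper-plane at the master's residual values
    and/or bisect the active segment of each partitioned variable.

    Returns ``(pw, hp, actions)``; ``actions`` is empty when every proposed
    refinement duplicated an existing one (the caller should widen its
    action).
    """
    actions: list[str] = []
    if policy in ("add-anchor", "both"):
        for key, kz in master.zprime_index.items():
            nm = master.var_names[kz]
            val = float(relax_point[nm])
            existing = hp.anchors.setdefault(nm, [0.0])
            if all(abs(val - a) > tol for a in existing):
                existing.append(val)
                existing.sort()
                actions.append(f"anchor:{nm}@{val:.6g}")
    if policy in ("bisect", "both"):
        for nm, edges in master.partition_edges.items():
            x = float(relax_point[nm])
            edges = list(pw.edges.get(nm, edges))
            n = min(
                max(int(np.searchsorted(edges, x, side="right")) - 1, 0), len(edges) - 2
            )
            mid = 0.5 * (edges[n] + edges[n + 1])
            if edges[n + 1] - edges[n] > tol and all(abs(mid - e) > tol for e in edges):
                edges.insert(n + 1, mid)
                pw.edges[nm] = edges
                actions.append(f"bisect:{nm}@{mid:.6g}")
    return pw, hp, actions


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _sample_start(rng: np.random.Generator, names, boxes) -> dict[str, float]:
    """Random start; rate-constant-like boxes (nonnegative, spanning many
    decades) are sampled log-uniformly, everything else uniformly."""
    out = {}
    for nm in names:
        lo, hi = boxes[nm]
        if lo >= 0.0 and hi > 0.0 and hi > 1e3 * max(lo, hi * 1e-9):
            lo_eff = max(lo, hi * 1e-9)
            out[nm] = float(np.exp(rng.uniform(np.log(lo_eff), np.log(hi))))
        else:
            out[nm] = float(rng.uniform(lo, hi))
    return out


def run_oa(
    model: OdeModel,
    dataset: Dataset,
    config: OaConfig,
    contract: SolverContract | None = None,
    obs: ObservationMap | None = None,
):
    """Run the outer-approximation algorithm; returns
    ``(best point, ledger, status)`` with status in
    {"converged", "iteration_cap", "time_cap", "infeasible"}.
    """
    t_start = time.monotonic()
    contract = contract or default_contract(config)
    nlp = transcribe(model, dataset, config.ne, config.nk, obs=obs, edges=config.edges)
    rng = np.random.default_rng(config.seed)
    ledger = BoundsLedger()

    # step 1: initial upper bound from a seeded multistart local solve
    boxes = nlp.boxes()
    free = ReducedNlpBackend.free_names(nlp)
    best: NlpResult | None = None
    starts: list[dict[str, float]] = [{}]  # box midpoints
    starts += [_sample_start(rng, free, boxes) for _ in range(max(config.multistart - 1, 0))]
    for s in starts:
        cand = solve_slave(nlp, s, contract)
        if cand.status == "feasible" and (best is None or cand.sse < best.sse):
            best = cand
    ub0 = best.sse if best is not None else None

    canon = reformulate(nlp, share_common=config.share_common)
    pw = PiecewiseConfig(np_init=config.np_init)
    hp = initial_hyperplanes(canon, config.anchors_init)
    cuts = []

    # optional bound contraction before the loop
    if config.obbt_rounds > 0 and config.obbt_targets != "none":
        master0 = build_master(canon, pw, hp, objective_cut=ub0)
        if config.obbt_targets == "xi":
            targets = [v.name for v in nlp.variables if v.kind == "xi"]
        else:
            targets = [v.name for v in nlp.variables]
        try:
            tightened = obbt_contract(master0, targets, rounds=config.obbt_rounds)
        except RuntimeError:
            return best.point if best else None, ledger, "infeasible"
        for nm, (lo, hi) in tightened.items():
            nlp.set_box(nm, lo, hi)
        canon = reformulate(nlp, share_common=config.share_common)
        hp = initial_hyperplanes(canon, config.anchors_init)

    if config.temporal_windows:
        cuts = temporal_cuts(
            nlp, config.temporal_windows, contract, pw,
            anchors_init=config.anchors_init, share_common=config.share_common,
        )

    status = "iteration_cap"
    for it in range(1, config.max_iterations + 1):
        master = build_master(
            canon, pw, hp, cuts=cuts,
            objective_cut=(None if best is None else best.sse),
        )
        solved = solve_master(master, contract)
        if solved is None:
            status = "infeasible"
            ledger.append(it, _INF, None, "master-infeasible")
            break
        lb_it, relax_point = solved

        start = {nm: relax_point[nm] for nm in free}
        cand = solve_slave(nlp, start, contract)
        action = "slave-" + cand.status
        ub_it = None
        if cand.status == "feasible":
            ub_it = cand.sse
            if best is None or cand.sse < best.sse:
                best = cand
        row = ledger.append(it, lb_it, ub_it, action)
        if row["gap"] <= config.tol:
            status = "converged"
            break
        if config.time_limit is not None and time.monotonic() - t_start > config.time_limit:
            status = "time_cap"
            break
        policy = "add-anchor" if config.fixed_np else config.refinement
        pw, hp, actions = refine(pw, hp, master, relax_point, policy)
        if not actions and policy != "both":
            # widen the action before giving up (step-3a retry discipline)
            pw, hp, actions = refine(pw, hp, master, relax_point, "both")
        n_anchor = sum(a.startswith("anchor") for a in actions)
        n_bisect = sum(a.startswith("bisect") for a in actions)
        summary = []
        if n_anchor:
            summary.append(f"anchors+{n_anchor}")
        if n_bisect:
            summary.append(f"bisect+{n_bisect}")
        row["action"] += ";" + (",".join(summary) if summary else "noop")

    return (best.point if best is not None else None), ledger, status
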