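"""Master MILP relaxation of the canonical form.

Bilinear atoms are replaced by McCormick envelopes; partitioning one factor's
box into segments selected by binary switches tightens the envelope
(piecewise McCormick).  Registered powers are relaxed through the bilinear
route (x**2 -> x*x) or, for purely convex/concave atoms, by function-secant
pairs, as are the univariate atoms.  The least-squares objective is
underestimated by supporting hyper-planes: each residual square contributes an
epigraph variable alpha bounded below by first-order Taylor cuts at a set of
anchor points, and the master minimizes the sum of the alphas.

Every feasible point of the source NLP extends to a feasible master point
with objective value no larger than its SSE, so the master optimum (or any
proven dual bound on it) is a rigorous lower bound on the global optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reformulation import CanonicalForm

__all__ = [
    "PiecewiseConfig",
    "HyperplaneSet",
    "MasterMilp",
    "mccormick_rows",
    "piecewise_mccormick_rows",
    "secant_rows",
    "hyperplane_rows",
    "build_master",
    "initial_hyperplanes",
    "write_lp",
]

_INF = math.inf


@dataclass
class PiecewiseConfig:
    """Segment layout for partitioned bilinear factors.

    ``np_init`` is the uniform segment count; ``edges`` may pin explicit
    per-variable segment edges (used by bisection refinement).  Which factor
    of each atom is partitioned: a parameter factor when present, otherwise
    the alphabetically-first factor; all atoms sharing a partitioned variable
    share one segment grid and one set of binaries.
    """

    np_init: int = 1
    edges: dict[str, list[float]] = field(default_factory=dict)

    def edges_for(self, name: str, lo: float, hi: float) -> list[float]:
        if name in self.edges:
            return list(self.edges[name])
        return list(np.linspace(lo, hi, self.np_init + 1))


@dataclass
class HyperplaneSet:
    """Tangency anchors of the objective hyper-planes, per residual variable."""

    anchors: dict[str, list[float]] = field(default_factory=dict)

    def anchors_for(self, name: str) -> list[float]:
        return self.anchors[name]


def initial_hyperplanes(canon: CanonicalForm, count: int) -> HyperplaneSet:
    """``count`` anchors uniformly spaced over each residual's box, plus the
    anchor at zero that makes alpha >= 0 explicit."""
    anchors: dict[str, list[float]] = {}
    for k, _key in canon.objective_residuals:
        lo, hi = canon.box(k)
        pts = list(np.linspace(lo, hi, max(count, 1)))
        pts.append(0.0)
        anchors[canon.var_names[k]] = _dedupe(pts)
    return HyperplaneSet(anchors=anchors)


def _dedupe(pts, tol: float = 1e-9) -> list[float]:
    out: list[float] = []
    for p in sorted(pts):
        if not out or abs(p - out[-1]) > tol:
            out.append(float(p))
    return out


# ---------------------------------------------------------------------------
# Envelope row generators (rows are dicts over symbolic keys)
# ---------------------------------------------------------------------------

def mccormick_rows(xbox, ybox):
    """The four McCormick inequalities for z = x*y over a box, as
    ``(coeffs, lb, ub)`` rows over keys 'x', 'y', 'z'.

    A degenerate (point) box collapses the envelope to the exact equality.
    """
    xl, xu = map(float, xbox)
    yl, yu = map(float, ybox)
    if xl == xu:
        return [({"z": 1.0, "y": -xl}, 0.0, 0.0)]
    if yl == yu:
        return [({"z": 1.0, "x": -yl}, 0.0, 0.0)]
    return [
        ({"z": 1.0, "x": -yl, "y": -xl}, -xl * yl, _INF),   # z >= x yL + xL y - xL yL
        ({"z": 1.0, "x": -yu, "y": -xu}, -xu * yu, _INF),   # z >= x yU + xU y - xU yU
        ({"z": 1.0, "x": -yl, "y": -xu}, -_INF, -xu * yl),  # z <= x yL + xU y - xU yL
        ({"z": 1.0, "x": -yu, "y": -xl}, -_INF, -xl * yu),  # z <= x yU + xL y - xL yU
    ]


def piecewise_mccormick_rows(xbox, ybox, np_or_edges):
    """Piecewise McCormick rows for z = x*y with x partitioned into segments.

    Keys: 'x', 'y', 'z', ('lam', n), ('dy', n) for n = 0..NP-1.  Emits the
    one-active-segment row, the y disaggregation, the four segment-wise
    under/over-estimators, and the rows linking x to its active segment
    (the binary semantics the piecewise construction relies on).
    """
    xl, xu = map(float, xbox)
    yl, yu = map(float, ybox)
    if isinstance(np_or_edges, int):
        if np_or_edges < 1:
            raise ValueError("segment count must be >= 1")
        edges = list(np.linspace(xl, xu, np_or_edges + 1))
    else:
        edges = [float(v) for v in np_or_edges]
        if len(edges) < 2 or not all(b > a for a, b in zip(edges, edges[1:])):
            raise ValueError("segment edges must be strictly increasing")
        if not (math.isclose(edges[0], xl) and math.isclose(edges[-1], xu)):
            raise ValueError("segment edges must span the x box")
    NP = len(edges) - 1
    dy_span = yu - yl
    rows = []
    # sum lambda = 1
    rows.append(({("lam", n): 1.0 for n in range(NP)}, 1.0, 1.0))
    # y = yL + sum dy
    r = {("dy", n): 1.0 for n in range(NP)}
    r["y"] = -1.0
    rows.append((r, -yl, -yl))
    # 0 <= dy(n) <= (yU - yL) lam(n)
    for n in range(NP):
        rows.append(({("dy", n): 1.0}, 0.0, _INF))
        rows.append(({("dy", n): 1.0, ("lam", n): -dy_span}, -_INF, 0.0))
    eL = edges[:-1]
    eR = edges[1:]
    # z >= x yL + sum eL(n) dy(n)
    r = {"z": 1.0, "x": -yl}
    for n in range(NP):
        r[("dy", n)] = -eL[n]
    rows.append((r, 0.0, _INF))
    # z >= x yU + sum eR(n) [dy(n) - (yU-yL) lam(n)]
    r = {"z": 1.0, "x": -yu}
    for n in range(NP):
        r[("dy", n)] = -eR[n]
        r[("lam", n)] = eR[n] * dy_span
    rows.append((r, 0.0, _INF))
    # z <= x yL + sum eR(n) dy(n)
    r = {"z": 1.0, "x": -yl}
    for n in range(NP):
        r[("dy", n)] = -eR[n]
    rows.append((r, -_INF, 0.0))
    # z <= x yU + sum eL(n) [dy(n) - (yU-yL) lam(n)]
    r = {"z": 1.0, "x": -yu}
    for n in range(NP):
        r[("dy", n)] = -eL[n]
        r[("lam", n)] = eL[n] * dy_span
    rows.append((r, -_INF, 0.0))
    # active-segment linking: sum eL lam <= x <= sum eR lam
    r = {"x": 1.0}
    for n in range(NP):
        r[("lam", n)] = -eL[n]
    rows.append((r, 0.0, _INF))
    r = {"x": 1.0}
    for n in range(NP):
        r[("lam", n)] = -eR[n]
    rows.append((r, -_INF, 0.0))
    return rows, edges


_FUNCS = {
    "exp": (math.exp, math.exp, "convex"),
    "log": (math.log, lambda x: 1.0 / x, "concave"),
    "sqrt": (math.sqrt, lambda x: 0.5 / math.sqrt(x), "concave"),
}


def secant_rows(fname: str, box, n: int | None = None):
    """Function-secant pair for a purely convex or concave univariate atom
    z = f(x): tangent cuts at the box ends and midpoint on the function side,
    the secant on the other side.  Keys 'x', 'z'."""
    lo, hi = map(float, box)
    if fname == "pow":
        if n is None or n < 2:
            raise ValueError("power atoms need an exponent n >= 2")
        f = lambda x: x ** n
        fp = lambda x: n * x ** (n - 1)
        if n % 2 == 0:
            curvature = "convex"
        elif lo >= 0.0:
            curvature = "convex"
        elif hi <= 0.0:
            curvature = "concave"
        else:
            raise ValueError(
                f"odd power x**{n} changes curvature on [{lo}, {hi}]; split the box"
            )
    else:
        f, fp, curvature = _FUNCS[fname]
    rows = []
    if hi > lo:
        slope = (f(hi) - f(lo)) / (hi - lo)
    else:
        slope = fp(lo)
    # secant: z vs f(lo) + slope (x - lo)
    sec = ({"z": 1.0, "x": -slope}, f(lo) - slope * lo)
    tangents = []
    for a in (lo, 0.5 * (lo + hi), hi):
        tangents.append(({"z": 1.0, "x": -fp(a)}, f(a) - fp(a) * a))
    out = []
    if curvature == "convex":
        out.append((sec[0], -_INF, sec[1]))  # z <= secant
        for coefs, rhs in tangents:
            out.append((coefs, rhs, _INF))  # z >= tangent
    else:
        out.append((sec[0], sec[1], _INF))  # z >= secant
        for coefs, rhs in tangents:
            out.append((coefs, -_INF, rhs))  # z <= tangent
    return out


def hyperplane_rows(anchors, zprime_box=None):
    """Epigraph rows alpha >= z0^2 + 2 z0 (z' - z0), one per anchor.
    Keys 'zp', 'alpha'."""
    rows = []
    for z0 in anchors:
        z0 = float(z0)
        rows.append(({"alpha": 1.0, "zp": -2.0 * z0}, -z0 * z0, _INF))
    return rows


# ---------------------------------------------------------------------------
# Master assembly
# ---------------------------------------------------------------------------

@dataclass
class MasterMilp:
    """Linear rows, boxes and integrality of the relaxation, plus bookkeeping
    linking alpha/lambda variables back to residuals and partitioned factors."""

    var_names: list[str]
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray  # 1 for binaries
    rows: list[tuple[dict[int, float], float, float]]  # (coeffs, lb, ub)
    objective: dict[int, float]  # minimize
    alpha_index: dict[tuple, int]  # measurement key -> alpha var index
    zprime_index: dict[tuple, int]  # measurement key -> z' var index
    partition_edges: dict[str, list[float]]  # partitioned var name -> edges
    lambda_index: dict[str, list[int]]  # partitioned var name -> lambda indices
    canon: CanonicalForm
    n_source: int  # leading variables shared with the canonical form

    def index(self, name: str) -> int:
        idx = getattr(self, "_index", None)
        if idx is None:
            idx = {n: i for i, n in enumerate(self.var_names)}
            self._index = idx
        return idx[name]


def _product_atoms(canon: CanonicalForm):
    """All atoms the master must relax as products: T_bt entries (i, j, k)
    meaning w_k = w_i w_j; T_lft entries recast through the bilinear
    transform (w_k w_j = w_i); T_et squares as w_i w_i."""
    atoms = []
    for i, j, k in canon.T_bt:
        atoms.append((i, j, k))
    for i, j, k in canon.T_lft:
        atoms.append((k, j, i))  # product of quotient and denominator
    for i, k, n in canon.T_et:
        if n == 2:
            atoms.append((i, i, k))
    return atoms


def _partitioned_factor(canon: CanonicalForm, i: int, j: int) -> tuple[int, int]:
    """(x, y) with x the factor carrying the partition: parameters first,
    otherwise the alphabetically-first name."""
    ki, kj = canon.var_kind[i], canon.var_kind[j]
    if ki == "theta" and kj != "theta":
        return i, j
    if kj == "theta" and ki != "theta":
        return j, i
    return (i, j) if canon.var_names[i] <= canon.var_names[j] else (j, i)


def build_master(
    canon: CanonicalForm,
    pw: PiecewiseConfig | None = None,
    hp: HyperplaneSet | None = None,
    cuts=None,
    objective_cut: float | None = None,
) -> MasterMilp:
    """Assemble the master MILP from the canonical form.

    ``cuts`` is a list of extra ``(coeffs-by-master-name, lb, ub)`` rows (e.g.
    temporal strengthening cuts); ``objective_cut`` bounds the sum of the
    epigraph variables by a known upper bound on the SSE.
    """
    pw = pw or PiecewiseConfig()
    hp = hp or initial_hyperplanes(canon, 1)

    names = list(canon.var_names)
    lb = list(canon.lb)
    ub = list(canon.ub)
    integ = [0] * len(names)
    rows: list[tuple[dict[int, float], float, float]] = []
    for coefs, rhs in canon.rows:
        rows.append((dict(coefs), rhs, rhs))

    def add_var(nm, lo, hi, binary=False):
        names.append(nm)
        lb.append(lo)
        ub.append(hi)
        integ.append(1 if binary else 0)
        return len(names) - 1

    # shared binaries per partitioned variable
    atoms = _product_atoms(canon)
    lambda_index: dict[str, list[int]] = {}
    partition_edges: dict[str, list[float]] = {}
    seen_partitioned: set[int] = set()

    def lambdas_for(x: int) -> tuple[list[int], list[float]]:
        nm = canon.var_names[x]
        if nm not in lambda_index:
            edges = pw.edges_for(nm, canon.lb[x], canon.ub[x])
            if len(edges) - 1 <= 1:
                lambda_index[nm] = []
                partition_edges[nm] = edges
            else:
                idxs = [
                    add_var(f"lam_{nm}_{n}", 0.0, 1.0, binary=True)
                    for n in range(len(edges) - 1)
                ]
                lambda_index[nm] = idxs
                partition_edges[nm] = edges
        return lambda_index[nm], partition_edges[nm]

    for a_no, (i, j, k) in enumerate(atoms):
        if canon.lb[i] == canon.ub[i] or canon.lb[j] == canon.ub[j]:
            for coefs, rlo, rhi in mccormick_rows(canon.box(i), canon.box(j)):
                rows.append((_map_keys(coefs, {"x": i, "y": j, "z": k}), rlo, rhi))
            continue
        x, y = _partitioned_factor(canon, i, j)
        lam, edges = lambdas_for(x)
        if len(lam) == 0:
            for coefs, rlo, rhi in mccormick_rows(canon.box(x), canon.box(y)):
                rows.append((_map_keys(coefs, {"x": x, "y": y, "z": k}), rlo, rhi))
        else:
            NP = len(edges) - 1
            pw_rows, _ = piecewise_mccormick_rows(canon.box(x), canon.box(y), edges)
            dy = [
                add_var(f"dy_a{a_no}_{n}", 0.0, canon.ub[y] - canon.lb[y])
                for n in range(NP)
            ]
            keymap: dict = {"x": x, "y": y, "z": k}
            for n in range(NP):
                keymap[("lam", n)] = lam[n]
                keymap[("dy", n)] = dy[n]
            # the sum-lambda and x-linking rows are per partitioned variable,
            # shared across its atoms: emit them once
            first_atom_of_x = x not in seen_partitioned
            seen_partitioned.add(x)
            for coefs, rlo, rhi in pw_rows:
                per_var = ("z" not in coefs) and not any(
                    isinstance(kk, tuple) and kk[0] == "dy" for kk in coefs
                ) and "y" not in coefs
                if per_var and not first_atom_of_x:
                    continue
                rows.append((_map_keys(coefs, keymap), rlo, rhi))

    # higher powers and univariate atoms: function-secant pairs
    for i, k, n in canon.T_et:
        if n != 2:
            for coefs, rlo, rhi in secant_rows("pow", canon.box(i), n):
                rows.append((_map_keys(coefs, {"x": i, "z": k}), rlo, rhi))
    for i, k, fname in canon.T_uft:
        for coefs, rlo, rhi in secant_rows(fname, canon.box(i)):
            rows.append((_map_keys(coefs, {"x": i, "z": k}), rlo, rhi))

    # objective epigraph
    alpha_index: dict[tuple, int] = {}
    zprime_index: dict[tuple, int] = {}
    objective: dict[int, float] = dict(canon.objective_linear)
    for kz, key in canon.objective_residuals:
        lo, hi = canon.box(kz)
        amax = max(lo * lo, hi * hi)
        a = add_var(f"alpha_{canon.var_names[kz]}", 0.0, amax)
        alpha_index[key] = a
        zprime_index[key] = kz
        objective[a] = 1.0
        anchors = hp.anchors_for(canon.var_names[kz])
        for coefs, rlo, rhi in hyperplane_rows(anchors):
            rows.append((_map_keys(coefs, {"zp": kz, "alpha": a}), rlo, rhi))

    if objective_cut is not None:
        rows.append((dict.fromkeys(alpha_index.values(), 1.0), -_INF, float(objective_cut)))

    master = MasterMilp(
        var_names=names, lb=np.array(lb), ub=np.array(ub),
        integrality=np.array(integ), rows=rows, objective=objective,
        alpha_index=alpha_index, zprime_index=zprime_index,
        partition_edges=partition_edges, lambda_index=lambda_index,
        canon=canon, n_source=len(canon.var_names),
    )
    for coefs_by_name, rlo, rhi in (cuts or []):
        master.rows.append((
            {master.index(nm): v for nm, v in coefs_by_name.items()}, rlo, rhi
        ))
    return master


def _map_keys(coefs, keymap):
    # accumulate: a square atom maps 'x' and 'y' to the same variable
    out: dict[int, float] = {}
    for k, v in coefs.items():
        i = keymap[k]
        out[i] = out.get(i, 0.0) + v
    return out


def write_lp(master: MasterMilp) -> str:
    """Serialize the master to CPLEX LP text (solver-independent regression
    artifact)."""
    def vname(i):
        # LP format is picky about leading characters and symbols
        return "v%d" % i

    out = ["\\ master relaxation", "Minimize", " obj: " + " + ".join(
        f"{v} {vname(i)}" for i, v in sorted(master.objective.items())
    )]
    out.append("Subject To")
    cno = 0
    for coefs, rlo, rhi in master.rows:
        terms = " ".join(
            ("+ " if v >= 0 else "- ") + f"{abs(v)!r} {vname(i)}"
            for i, v in sorted(coefs.items())
        )
        if rlo == rhi:
            out.append(f" c{cno}: {terms} = {rlo!r}")
            cno += 1
        else:
            if rlo != -_INF:
                out.append(f" c{cno}: {terms} >= {rlo!r}")
                cno += 1
            if rhi != _INF:
                out.append(f" c{cno}: {terms} <= {rhi!r}")
                cno += 1
    out.append("Bounds")
    for i in range(len(master.var_names)):
        out.append(f" {master.lb[i]!r} <= {vname(i)} <= {master.ub[i]!r}")
    bins = [vname(i) for i in range(len(master.var_names)) if master.integrality[i]]
    if bins:
        out.append("Binary")
        out.append(" " + " ".join(bins))
    out.append("End")
    return "\n".join(out) + "\n"
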