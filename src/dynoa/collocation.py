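"""Orthogonal collocation on finite elements.

The horizon is split into ``NE`` elements; inside each element the state is a
degree-``NK`` Lagrange polynomial supported on the element start (tau = 0) and
the ``NK`` shifted Gauss-Legendre roots.  Enforcing the ODE at the interior
nodes, continuity across elements and the initial condition turns the dynamic
model into a square algebraic system in the collocation coefficients
``xi[e, k, j]``; adding measurement interpolation rows and the least-squares
objective yields the transcribed NLP that the rest of the package relaxes and
solves.

Because each coefficient is the state value at a known time, physically
motivated state bounds translate directly into variable boxes — the property
the global-optimization relaxation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .model_core import FreeInitial, ObservationMap, OdeModel
from .synthetic_data import Dataset

__all__ = [
    "legendre_nodes",
    "basis_matrices",
    "CollocationScheme",
    "make_scheme",
    "locate_measurement",
    "Equation",
    "VarInfo",
    "TranscribedNlp",
    "transcribe",
    "evaluate_trajectory",
    "simulate_collocation",
]


def legendre_nodes(nk: int) -> np.ndarray:
    """tau_0 = 0 followed by the NK Gauss-Legendre roots shifted to (0, 1)."""
    if not 1 <= nk <= 10:
        raise ValueError(f"collocation degree must be in [1, 10], got {nk}")
    roots, _ = np.polynomial.legendre.leggauss(nk)
    return np.concatenate([[0.0], np.sort(roots + 1.0) / 2.0])


def _bary_weights(tau: np.ndarray) -> np.ndarray:
    n = len(tau)
    w = np.ones(n)
    for k in range(n):
        for m in range(n):
            if m != k:
                w[k] /= tau[k] - tau[m]
    return w


def lagrange_values(tau: np.ndarray, tloc: float) -> np.ndarray:
    """phi_k(tloc) for the Lagrange basis on nodes ``tau``."""
    tau = np.asarray(tau, dtype=float)
    out = np.ones(len(tau))
    for k in range(len(tau)):
        for m in range(len(tau)):
            if m != k:
                out[k] *= (tloc - tau[m]) / (tau[k] - tau[m])
    return out


def basis_matrices(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact Lagrange-basis derivatives at the interior nodes, and phi(1).

    Returns ``Dmat`` with ``Dmat[k, q] = d phi_k/d tau at tau_{q+1}`` for
    q = 0..NK-1 (the collocated nodes), and ``phi_end[k] = phi_k(1)``.
    Derivatives come from the barycentric form analytically, not from finite
    differences, so transcription residuals are bit-stable.
    """
    tau = np.asarray(tau, dtype=float)
    if len(np.unique(tau)) != len(tau):
        raise ValueError("duplicate collocation nodes")
    n = len(tau)
    w = _bary_weights(tau)
    D = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if k != j:
                D[k, j] = (w[k] / w[j]) / (tau[j] - tau[k])
        D[j, j] = -np.sum(D[:, j]) + D[j, j]  # columns of l_k' sum to zero
    return D[:, 1:], lagrange_values(tau, 1.0)


@dataclass(frozen=True)
class CollocationScheme:
    """Element mesh plus basis tables shared by every state and experiment."""

    ne: int
    nk: int
    edges: np.ndarray  # element boundaries eta_1 .. eta_{NE+1}, length NE+1
    tau: np.ndarray
    Dmat: np.ndarray  # (NK+1, NK)
    phi_end: np.ndarray  # (NK+1,)

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.edges)

    def node_time(self, e: int, k: int) -> float:
        """Absolute time of node k of element e (both 1-based)."""
        return float(self.edges[e - 1] + self.lengths[e - 1] * self.tau[k])


def make_scheme(
    horizon: tuple[float, float], ne: int, nk: int, edges: Sequence[float] | None = None
) -> CollocationScheme:
    t0, tf = horizon
    if edges is None:
        edges = np.linspace(t0, tf, ne + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        if len(edges) != ne + 1 or edges[0] != t0 or edges[-1] != tf:
            raise ValueError("element edges must span the horizon with NE+1 points")
        if not (np.diff(edges) > 0).all():
            raise ValueError("element edges must be strictly increasing")
    tau = legendre_nodes(nk)
    Dmat, phi_end = basis_matrices(tau)
    return CollocationScheme(ne=ne, nk=nk, edges=np.asarray(edges, dtype=float),
                             tau=tau, Dmat=Dmat, phi_end=phi_end)


def locate_measurement(t_u: float, scheme: CollocationScheme) -> tuple[int, float]:
    """Map an absolute time to (1-based element index, local tau in [0, 1]).

    Elements own their left edge; the right horizon endpoint maps to
    ``(NE, 1)`` so every admissible time has a home.
    """
    edges = scheme.edges
    if t_u < edges[0] or t_u > edges[-1]:
        raise ValueError(f"measurement time {t_u} outside horizon [{edges[0]}, {edges[-1]}]")
    e = int(np.searchsorted(edges, t_u, side="right")) - 1
    e = min(e, scheme.ne - 1)
    tau_u = (t_u - edges[e]) / (edges[e + 1] - edges[e])
    return e + 1, float(tau_u)


# ---------------------------------------------------------------------------
# Transcription
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarInfo:
    name: str
    lo: float
    hi: float
    kind: str  # "xi" | "theta" | "zhat" | "extra"


@dataclass(frozen=True)
class Equation:
    family: str  # "residual" | "continuity" | "initial" | "measurement"
    expr: sp.Expr  # == 0
    meta: tuple  # residual: (u, e, k', j); continuity: (u, e, j);
    #              initial: (u, j); measurement: (u, t_u, j)


@dataclass
class TranscribedNlp:
    """Algebraic transcription: variables with boxes, four equation families,
    and the measurement residual pairs defining the SSE objective."""

    model: OdeModel
    obs: ObservationMap
    dataset: Dataset
    scheme: CollocationScheme
    variables: list[VarInfo]
    equations: list[Equation]
    #: (zhat variable name, observed value, (experiment, time, state))
    residuals: list[tuple[str, float, tuple[str, float, str]]]

    @property
    def var_index(self) -> dict[str, int]:
        idx = getattr(self, "_var_index", None)
        if idx is None:
            idx = {v.name: i for i, v in enumerate(self.variables)}
            self._var_index = idx
        return idx

    def boxes(self) -> dict[str, tuple[float, float]]:
        return {v.name: (v.lo, v.hi) for v in self.variables}

    def set_box(self, name: str, lo: float, hi: float) -> None:
        i = self.var_index[name]
        v = self.variables[i]
        self.variables[i] = VarInfo(v.name, lo, hi, v.kind)

    def sse(self, point: Mapping[str, float]) -> float:
        return sum((point[nm] - val) ** 2 for nm, val, _ in self.residuals)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for eq in self.equations:
            out[eq.family] = out.get(eq.family, 0) + 1
        return out


def xi_name(u: str, e: int, k: int, state: str) -> str:
    return f"xi_{u}_e{e}_k{k}_{state}"


def zhat_name(u: str, iu: int, state: str) -> str:
    return f"zhat_{u}_m{iu}_{state}"


def _per_exp_name(base: str, u: str) -> str:
    return f"{base}_{u}"


def transcribe(
    model: OdeModel,
    dataset: Dataset,
    ne: int,
    nk: int,
    state_boxes: Mapping[str, tuple[float, float]] | None = None,
    obs: ObservationMap | None = None,
    edges: Sequence[float] | None = None,
) -> TranscribedNlp:
    """Build the transcribed NLP for every experiment in the dataset.

    Experiments replicate the collocation coefficients and measurement rows
    and share the global parameter vector; free initial conditions and
    per-experiment extra degrees of freedom get one variable per experiment.
    """
    obs = obs or ObservationMap()
    scheme = make_scheme(model.horizon, ne, nk, edges)
    experiments = dataset.experiments
    if not experiments:
        raise ValueError("empty dataset")
    for row in dataset.frame.itertuples(index=False):
        if row.state_name not in model.observed:
            raise ValueError(f"measurement of unobserved state {row.state_name!r}")

    variables: list[VarInfo] = []
    equations: list[Equation] = []
    residuals: list[tuple[str, float, tuple[str, float, str]]] = []

    theta_syms = {p: sp.Symbol(p) for p in model.params}
    for p, (lo, hi) in model.params.items():
        variables.append(VarInfo(p, lo, hi, "theta"))

    # extra degrees of freedom (global or replicated per experiment)
    extra_map: dict[tuple[str, str], sp.Symbol] = {}
    for d, dof in model.extra_dof.items():
        if dof.per_experiment:
            for u in experiments:
                nm = _per_exp_name(d, u)
                variables.append(VarInfo(nm, dof.lo, dof.hi, "extra"))
                extra_map[(d, u)] = sp.Symbol(nm)
        else:
            variables.append(VarInfo(d, dof.lo, dof.hi, "extra"))
            for u in experiments:
                extra_map[(d, u)] = sp.Symbol(d)

    default_box = (0.0, 100.0)
    boxes = {
        s: (state_boxes or {}).get(s, model.state_bounds.get(s, default_box))
        for s in model.states
    }

    for u in experiments:
        xi: dict[tuple[int, int, str], sp.Symbol] = {}
        for e in range(1, ne + 1):
            for k in range(0, nk + 1):
                for s in model.states:
                    nm = xi_name(u, e, k, s)
                    lo, hi = boxes[s]
                    variables.append(VarInfo(nm, lo, hi, "xi"))
                    xi[(e, k, s)] = sp.Symbol(nm)

        subs_extra = {sp.Symbol(d): extra_map[(d, u)] for d in model.extra_dof}

        # residual family: collocated ODE at interior nodes
        for e in range(1, ne + 1):
            h = scheme.lengths[e - 1]
            for kp in range(1, nk + 1):
                t_node = scheme.node_time(e, kp)
                state_subs = {sp.Symbol(s): xi[(e, kp, s)] for s in model.states}
                state_subs[sp.Symbol("t")] = sp.Float(t_node)
                for j in model.states:
                    g = model.rhs[j].xreplace(subs_extra).xreplace(state_subs)
                    deriv = sp.Add(*[
                        sp.Float(scheme.Dmat[k, kp - 1]) * xi[(e, k, j)]
                        for k in range(0, nk + 1)
                    ])
                    equations.append(Equation(
                        "residual", deriv - sp.Float(h) * g, (u, e, kp, j)
                    ))

        # continuity family
        for e in range(2, ne + 1):
            for j in model.states:
                extrap = sp.Add(*[
                    sp.Float(scheme.phi_end[k]) * xi[(e - 1, k, j)]
                    for k in range(0, nk + 1)
                ])
                equations.append(Equation("continuity", xi[(e, 0, j)] - extrap, (u, e, j)))

        # initial family (free initial conditions become per-experiment vars)
        for j in model.states:
            iv = model.initial_value(j, u)
            if isinstance(iv, FreeInitial):
                nm = _per_exp_name(f"{j}0", u)
                variables.append(VarInfo(nm, iv.lo, iv.hi, "extra"))
                rhs0: sp.Expr = sp.Symbol(nm)
            else:
                rhs0 = sp.Float(iv)
            equations.append(Equation("initial", xi[(1, 0, j)] - rhs0, (u, j)))

        # measurement family and objective residual pairs
        meas = dataset.measurements(u)
        for iu, t_u in enumerate(dict.fromkeys(meas["time"])):
            e_u, tau_u = locate_measurement(float(t_u), scheme)
            phis = lagrange_values(scheme.tau, tau_u)
            here = meas[meas["time"] == t_u]
            for row in here.itertuples(index=False):
                j = row.state_name
                nm = zhat_name(u, iu, j)
                interp = sp.Add(*[
                    sp.Float(phis[k]) * xi[(e_u, k, j)] for k in range(0, nk + 1)
                ])
                scale = obs.scale_of(j)
                offset = obs.offset_of(j)
                sc_expr = extra_map[(scale, u)] if isinstance(scale, str) else sp.Float(scale)
                off_expr = extra_map[(offset, u)] if isinstance(offset, str) else sp.Float(offset)
                signal = sc_expr * interp + off_expr
                lo, hi = _signal_box(signal, boxes, model, u, ne, nk)
                variables.append(VarInfo(nm, lo, hi, "zhat"))
                equations.append(Equation(
                    "measurement", -sp.Symbol(nm) + signal, (u, float(t_u), j)
                ))
                residuals.append((nm, float(row.value), (u, float(t_u), j)))

    return TranscribedNlp(
        model=model, obs=obs, dataset=dataset, scheme=scheme,
        variables=variables, equations=equations, residuals=residuals,
    )


def _signal_box(signal: sp.Expr, state_boxes, model: OdeModel, u: str, ne, nk):
    """Interval enclosure of a measurement signal from the variable boxes."""
    from .reformulation import interval_bound

    boxes = {}
    for sym in signal.free_symbols:
        nm = str(sym)
        matched = False
        for s in model.states:
            if nm.endswith(f"_{s}") and nm.startswith("xi_"):
                boxes[nm] = state_boxes[s]
                matched = True
                break
        if not matched:
            for d, dof in model.extra_dof.items():
                if nm == d or nm.startswith(f"{d}_"):
                    boxes[nm] = (dof.lo, dof.hi)
                    matched = True
                    break
        if not matched:  # pragma: no cover - defensive
            boxes[nm] = (-np.inf, np.inf)
    return interval_bound(signal, boxes)


# ---------------------------------------------------------------------------
# Simulation through the transcription (element marching)
# ---------------------------------------------------------------------------

def _stage_lambdas(model: OdeModel):
    """Lambdified rhs and its state Jacobian, cached on the model."""
    cached = getattr(model, "_stage_fns", None)
    if cached is None:
        zs = [sp.Symbol(s) for s in model.states]
        ps = [sp.Symbol(p) for p in model.params]
        ds = [sp.Symbol(d) for d in model.extra_dof]
        t = sp.Symbol("t")
        g = sp.Matrix(model.rhs_exprs())
        J = g.jacobian(zs)
        f = sp.lambdify([zs, ps, ds, t], list(g), modules="numpy")
        jf = sp.lambdify([zs, ps, ds, t], J, modules="numpy")
        cached = (f, jf)
        model._stage_fns = cached  # type: ignore[attr-defined]
    return cached


def simulate_collocation(
    model: OdeModel,
    scheme: CollocationScheme,
    param_values: Sequence[float],
    z0: Sequence[float],
    extra_values: Sequence[float] = (),
    newton_tol: float = 1e-12,
    max_newton: int = 50,
) -> np.ndarray:
    """Solve the square residual/continuity/initial system with parameters
    fixed, marching element by element with a damped Newton iteration.

    Returns ``xi`` of shape (NE, NK+1, |J|).  The collocation system is
    block-sequential: inside element ``e`` only the interior-node values are
    unknown once the entering state is known, so each element needs one small
    Newton solve (a single step for models linear in the states).
    """
    f, jf = _stage_lambdas(model)
    ns = len(model.states)
    nk = scheme.nk
    D = scheme.Dmat  # (nk+1, nk)
    p = np.asarray(param_values, dtype=float)
    ev = np.asarray(extra_values, dtype=float)
    xi = np.zeros((scheme.ne, nk + 1, ns))
    z_in = np.asarray(z0, dtype=float).copy()
    scale = max(1.0, float(np.max(np.abs(z_in))))

    for e in range(scheme.ne):
        h = scheme.lengths[e]
        tnodes = scheme.edges[e] + h * scheme.tau[1:]
        xi[e, 0] = z_in
        x = np.tile(z_in, (nk, 1))  # initial guess: constant state

        def residual(xmat):
            F = np.empty((nk, ns))
            for q in range(nk):
                acc = D[0, q] * z_in + sum(D[k + 1, q] * xmat[k] for k in range(nk))
                F[q] = acc - h * np.asarray(f(xmat[q], p, ev, tnodes[q]), dtype=float)
            return F

        converged = False
        for _ in range(max_newton):
            F = residual(x)
            if not np.isfinite(F).all():
                raise RuntimeError(
                    f"collocation residual not finite in element {e + 1}"
                )
            nrm = float(np.max(np.abs(F)))
            if nrm < newton_tol * scale:
                converged = True
                break
            # assemble the (nk*ns) x (nk*ns) stage Jacobian
            J = np.zeros((nk * ns, nk * ns))
            for q in range(nk):
                Jg = np.asarray(jf(x[q], p, ev, tnodes[q]), dtype=float)
                for k in range(nk):
                    blk = np.eye(ns) * D[k + 1, q]
                    if k == q:
                        blk = blk - h * Jg
                    J[q * ns:(q + 1) * ns, k * ns:(k + 1) * ns] = blk
            try:
                dx = np.linalg.solve(J, -F.ravel())
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(f"singular collocation Jacobian in element {e + 1}") from exc
            step = 1.0
            for _damp in range(30):
                xn = x + step * dx.reshape(nk, ns)
                if float(np.max(np.abs(residual(xn)))) < nrm or step < 1e-6:
                    break
                step *= 0.5
            x = x + step * dx.reshape(nk, ns)
        else:  # pragma: no cover - exhausted iterations
            pass
        if not converged:
            F = residual(x)
            if not (float(np.max(np.abs(F))) <= 1e-6 * scale):
                raise RuntimeError(
                    f"collocation Newton failed in element {e + 1}"
                )
        xi[e, 1:] = x
        z_in = scheme.phi_end @ xi[e]
        scale = max(scale, float(np.max(np.abs(z_in))))
    return xi


def evaluate_trajectory(coeffs: np.ndarray, scheme: CollocationScheme, t: float) -> np.ndarray:
    """Evaluate the element-local Lagrange interpolant at absolute time t."""
    e, tau_u = locate_measurement(t, scheme)
    phis = lagrange_values(scheme.tau, tau_u)
    return phis @ coeffs[e - 1]
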