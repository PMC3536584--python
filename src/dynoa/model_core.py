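"""Symbolic ODE kinetic models over a restricted expression grammar.

A model is a set of states ``z`` with right-hand sides ``dz/dt = g(z, theta, t)``
written in a grammar closed under +, -, *, /, integer powers, ``exp``, ``log``
and ``sqrt`` — the term classes the downstream bilinear reformulation supports.
Parameters carry box bounds; initial conditions may be fixed numbers or free
(estimated) values with their own boxes; non-dynamic fitted quantities such as
an instrument offset are *extra degrees of freedom*.

Two benchmark kinetic models ship with the package: the thermal isomerisation
of alpha-Pinene (5 states, 5 first-order rate constants) and the irreversible
inhibition of HIV-1 proteinase (9 states, 5 free rate constants, free initial
enzyme/substrate concentrations and a free fluorimeter offset per experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

__all__ = [
    "FreeInitial",
    "ExtraDof",
    "ObservationMap",
    "OdeModel",
    "ModelValidationError",
    "validate_model",
    "eval_rhs",
    "builtin_model",
    "read_model",
    "write_model",
]

#: functions admitted by the expression grammar
_ALLOWED_FUNCS = (sp.exp, sp.log)

_TIME = sp.Symbol("t")


class ModelValidationError(ValueError):
    """Raised when a model violates the grammar or its declared structure."""


@dataclass(frozen=True)
class FreeInitial:
    """An estimated initial condition with box bounds (one copy per experiment)."""

    lo: float
    hi: float


@dataclass(frozen=True)
class ExtraDof:
    """A non-dynamic fitted quantity (e.g. signal offset) with box bounds.

    ``per_experiment`` replicates the degree of freedom for every experiment
    in the dataset, as needed for per-assay instrument baselines.
    """

    lo: float
    hi: float
    per_experiment: bool = False


@dataclass(frozen=True)
class ObservationMap:
    """Linear output map from states to measured signals.

    For each observed state ``j`` the measured signal is
    ``scale * z_j + offset``.  ``scale``/``offset`` entries are either numbers
    or names of declared extra degrees of freedom.  Defaults to the identity.
    """

    scale: Mapping[str, float | str] = field(default_factory=dict)
    offset: Mapping[str, float | str] = field(default_factory=dict)

    def scale_of(self, state: str) -> float | str:
        return self.scale.get(state, 1.0)

    def offset_of(self, state: str) -> float | str:
        return self.offset.get(state, 0.0)


@dataclass
class OdeModel:
    """An ODE kinetic model ``dz/dt = g(z, theta, t)`` with parameter boxes."""

    name: str
    states: tuple[str, ...]
    observed: tuple[str, ...]
    params: dict[str, tuple[float, float]]
    rhs: dict[str, sp.Expr]
    z0: dict[str, float | FreeInitial]
    horizon: tuple[float, float]
    extra_dof: dict[str, ExtraDof] = field(default_factory=dict)
    state_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: fixed per-experiment initial-condition overrides, e.g. inhibitor doses
    experiment_init: dict[str, dict[str, float]] = field(default_factory=dict)

    def rhs_exprs(self) -> list[sp.Expr]:
        return [self.rhs[s] for s in self.states]

    def state_box(self, state: str, default: tuple[float, float] = (0.0, 100.0)):
        return self.state_bounds.get(state, default)

    def initial_value(self, state: str, experiment: str | None = None):
        """Initial condition of ``state``, honouring per-experiment overrides."""
        if experiment is not None:
            over = self.experiment_init.get(experiment, {})
            if state in over:
                return over[state]
        return self.z0[state]


def _parse_rhs(text: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    local = dict(symbols)
    local.update({"exp": sp.exp, "log": sp.log, "sqrt": sp.sqrt, "t": _TIME})
    try:
        expr = parse_expr(text, local_dict=local, transformations=standard_transformations)
    except Exception as exc:  # pragma: no cover - sympy error text varies
        raise ModelValidationError(f"cannot parse expression {text!r}: {exc}") from exc
    return expr


def check_grammar(expr: sp.Expr, allowed: set[sp.Symbol]) -> None:
    """Verify ``expr`` stays inside the supported grammar closure.

    Admitted nodes: numbers, allowed symbols, Add, Mul, integer powers,
    half-integer powers (sqrt), exp and log.  Anything richer is rejected so
    that every model admits an exact bilinear reformulation downstream.
    """
    for node in sp.preorder_traversal(expr):
        if node.is_Number or node.is_Add or node.is_Mul:
            continue
        if node.is_Symbol:
            if node not in allowed and node != _TIME:
                raise ModelValidationError(f"unknown symbol '{node}' in expression {expr}")
            continue
        if node.is_Pow:
            e = node.exp
            if e.is_Integer:
                continue
            if e == sp.Rational(1, 2) or e == sp.Rational(-1, 2):
                continue
            raise ModelValidationError(f"unsupported exponent {e} in {expr}")
        if isinstance(node, _ALLOWED_FUNCS):
            continue
        raise ModelValidationError(f"unsupported construct {node!r} in expression {expr}")


def validate_model(model: OdeModel) -> OdeModel:
    """Resolve symbols, check the grammar and box/horizon sanity.

    Returns the model with string right-hand sides parsed to sympy
    expressions under the canonical (declared) ordering of states and
    parameters.  Raises :class:`ModelValidationError` naming the offender on
    any violation.
    """
    if len(set(model.states)) != len(model.states):
        raise ModelValidationError("duplicate state names")
    if not model.observed:
        raise ModelValidationError("empty observed set: at least one state must be measured")
    for s in model.observed:
        if s not in model.states:
            raise ModelValidationError(f"observed name {s!r} is not a state")
    t0, tf = model.horizon
    if not t0 < tf:
        raise ModelValidationError(f"inverted horizon [{t0}, {tf}]")
    for p, (lo, hi) in model.params.items():
        if lo > hi:
            raise ModelValidationError(f"inverted bound for parameter {p!r}: [{lo}, {hi}]")
    for d, dof in model.extra_dof.items():
        if dof.lo > dof.hi:
            raise ModelValidationError(f"inverted bound for extra dof {d!r}")
    for s in model.states:
        if s not in model.z0:
            raise ModelValidationError(f"missing initial condition for state {s!r}")
        iv = model.z0[s]
        if isinstance(iv, FreeInitial) and iv.lo > iv.hi:
            raise ModelValidationError(f"inverted bound for free initial condition {s!r}")
    for s, (lo, hi) in model.state_bounds.items():
        if lo > hi:
            raise ModelValidationError(f"inverted state bound for {s!r}")

    symbols = {n: sp.Symbol(n) for n in (*model.states, *model.params, *model.extra_dof)}
    allowed = set(symbols.values())
    parsed: dict[str, sp.Expr] = {}
    for s in model.states:
        if s not in model.rhs:
            raise ModelValidationError(f"missing rhs for state {s!r}")
        expr = model.rhs[s]
        if isinstance(expr, str):
            expr = _parse_rhs(expr, symbols)
        check_grammar(expr, allowed)
        extra = expr.free_symbols - allowed - {_TIME}
        if extra:
            raise ModelValidationError(
                f"unknown symbol {sorted(map(str, extra))[0]!r} in rhs of {s!r}"
            )
        parsed[s] = expr
    model.rhs = parsed
    return model


def _rhs_lambda(model: OdeModel):
    fn = getattr(model, "_rhs_fn", None)
    if fn is None:
        syms = (
            [sp.Symbol(s) for s in model.states]
            + [sp.Symbol(p) for p in model.params]
            + [sp.Symbol(d) for d in model.extra_dof]
            + [_TIME]
        )
        fn = sp.lambdify(syms, model.rhs_exprs(), modules="numpy")
        model._rhs_fn = fn  # type: ignore[attr-defined]
    return fn


def eval_rhs(model, state_values, param_values, t, extra_values=()):
    """Evaluate ``g(z, theta, t)`` componentwise in canonical state order."""
    import numpy as np

    fn = _rhs_lambda(model)
    extra_values = list(extra_values)
    # extra dof that never enter the rhs (e.g. signal offsets) may be omitted
    extra_values += [0.0] * (len(model.extra_dof) - len(extra_values))
    out = fn(*state_values, *param_values, *extra_values, t)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# Built-in benchmark models
# ---------------------------------------------------------------------------

def _alpha_pinene() -> tuple[OdeModel, ObservationMap]:
    # First-order isomerisation network: alpha-pinene -> dipentene,
    # allo-ocimene <-> dimer, allo-ocimene -> pyronene.  Mass fractions,
    # time in minutes.
    states = ("apinene", "dipentene", "alloocimene", "pyronene", "dimer")
    rhs = {
        "apinene": "-(p1 + p2)*apinene",
        "dipentene": "p1*apinene",
        "alloocimene": "p2*apinene - (p3 + p4)*alloocimene + p5*dimer",
        "pyronene": "p3*alloocimene",
        "dimer": "p4*alloocimene - p5*dimer",
    }
    model = OdeModel(
        name="alpha_pinene",
        states=states,
        observed=states,
        params={f"p{i}": (0.0, 1.0) for i in range(1, 6)},
        rhs=rhs,  # parsed by validate_model
        z0={"apinene": 100.0, "dipentene": 0.0, "alloocimene": 0.0, "pyronene": 0.0, "dimer": 0.0},
        horizon=(0.0, 36420.0),
        state_bounds={s: (0.0, 100.0) for s in states},
    )
    return validate_model(model), ObservationMap()


#: per-experiment inhibitor doses (uM) of the five HIV proteinase assays
HIV_I0 = {"exp1": 0.0, "exp2": 0.0015, "exp3": 0.003, "exp4": 0.004, "exp5": 0.004}

#: rate constants fixed by the benchmark (uM/s units where applicable)
HIV_FIXED = {"k11": 0.1, "k12": 0.001, "k21": 100.0, "k41": 100.0, "k51": 100.0}


def _hiv_proteinase() -> tuple[OdeModel, ObservationMap]:
    # Irreversible inhibition of HIV-1 proteinase: monomer M dimerises to the
    # active enzyme E, which binds substrate S, product P and inhibitor I;
    # the EI complex decays irreversibly to EJ.  Concentrations in uM,
    # time in seconds.  Fixed constants are substituted numerically; the five
    # remaining rate constants are estimated.
    k11, k12, k21, k41, k51 = (HIV_FIXED[k] for k in ("k11", "k12", "k21", "k41", "k51"))
    states = ("M", "P", "S", "I", "ES", "EP", "E", "EI", "EJ")
    rhs = {
        "M": f"-2*{k11}*M*M + 2*{k12}*E",
        "P": f"k3*ES - 2*{k41}*P*E + 2*k42*EP",
        "S": f"-{k21}*S*E + k22*ES",
        "I": f"-{k51}*I*E + k52*EI",
        "ES": f"{k21}*S*E - k22*ES - k3*ES",
        "EP": f"{k41}*P*E - k42*EP",
        "E": (
            f"{k11}*M*M - {k12}*E - {k21}*S*E + k22*ES + k3*ES"
            f" - {k41}*P*E + k42*EP - {k51}*I*E + k52*EI"
        ),
        "EI": f"{k51}*I*E - k52*EI - k6*EI",
        "EJ": "k6*EI",
    }
    bounds = {s: (0.0, 37.5) for s in states}
    bounds["E"] = (0.002, 0.006)
    bounds["S"] = (12.5, 37.5)
    model = OdeModel(
        name="hiv_proteinase",
        states=states,
        observed=("P",),
        params={k: (0.0, 1.0e6) for k in ("k3", "k22", "k42", "k52", "k6")},
        rhs=rhs,
        z0={
            "M": 0.0,
            "P": 0.0,
            "S": FreeInitial(12.5, 37.5),
            "I": 0.0,
            "ES": 0.0,
            "EP": 0.0,
            "E": FreeInitial(0.002, 0.006),
            "EI": 0.0,
            "EJ": 0.0,
        },
        horizon=(0.0, 3600.0),
        extra_dof={"offset": ExtraDof(-0.5, 0.5, per_experiment=True)},
        state_bounds=bounds,
        experiment_init={u: {"I": v} for u, v in HIV_I0.items()},
    )
    obs = ObservationMap(scale={"P": 1.0}, offset={"P": "offset"})
    return validate_model(model), obs


_BUILTINS = {"alpha_pinene": _alpha_pinene, "hiv_proteinase": _hiv_proteinase}


def builtin_model(name: str) -> tuple[OdeModel, ObservationMap]:
    """Return a fresh copy of a named benchmark model and its observation map."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown builtin model {name!r}; choose from {sorted(_BUILTINS)}")
    return factory()


# ---------------------------------------------------------------------------
# Model file round-trip (line-oriented text format)
# ---------------------------------------------------------------------------

def write_model(model: OdeModel, obs: ObservationMap | None = None) -> str:
    """Serialize a model (and optional observation map) to text."""
    lines = [f"name: {model.name}"]
    lines.append("states: " + " ".join(model.states))
    lines.append("observed: " + " ".join(model.observed))
    lines.append(f"horizon: {model.horizon[0]!r} {model.horizon[1]!r}")
    for p, (lo, hi) in model.params.items():
        lines.append(f"param: {p} {lo!r} {hi!r}")
    for d, dof in model.extra_dof.items():
        flag = " per_experiment" if dof.per_experiment else ""
        lines.append(f"extra_dof: {d} {dof.lo!r} {dof.hi!r}{flag}")
    for s in model.states:
        lines.append(f"rhs: {s} = {model.rhs[s]}")
    for s in model.states:
        iv = model.z0[s]
        if isinstance(iv, FreeInitial):
            lines.append(f"init: {s} = free {iv.lo!r} {iv.hi!r}")
        else:
            lines.append(f"init: {s} = {iv!r}")
    for s, (lo, hi) in model.state_bounds.items():
        lines.append(f"state_bound: {s} {lo!r} {hi!r}")
    for u, over in model.experiment_init.items():
        for s, v in over.items():
            lines.append(f"experiment_init: {u} {s} {v!r}")
    if obs is not None:
        for s in model.observed:
            lines.append(f"observe: {s} {obs.scale_of(s)} {obs.offset_of(s)}")
    return "\n".join(lines) + "\n"


def _num_or_name(tok: str):
    try:
        return float(tok)
    except ValueError:
        return tok


def read_model(text: str) -> tuple[OdeModel, ObservationMap]:
    """Parse the text model format written by :func:`write_model`."""
    name = "model"
    states: list[str] = []
    observed: list[str] = []
    horizon = (0.0, 1.0)
    params: dict[str, tuple[float, float]] = {}
    extra: dict[str, ExtraDof] = {}
    rhs: dict[str, str] = {}
    z0: dict[str, float | FreeInitial] = {}
    state_bounds: dict[str, tuple[float, float]] = {}
    experiment_init: dict[str, dict[str, float]] = {}
    scale: dict[str, float | str] = {}
    offset: dict[str, float | str] = {}

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        key, rest = key.strip(), rest.strip()
        if key == "name":
            name = rest
        elif key == "states":
            states = rest.split()
        elif key == "observed":
            observed = rest.split()
        elif key == "horizon":
            a, b = rest.split()
            horizon = (float(a), float(b))
        elif key == "param":
            p, lo, hi = rest.split()
            params[p] = (float(lo), float(hi))
        elif key == "extra_dof":
            toks = rest.split()
            extra[toks[0]] = ExtraDof(
                float(toks[1]), float(toks[2]), per_experiment="per_experiment" in toks[3:]
            )
        elif key == "rhs":
            s, _, expr = rest.partition("=")
            rhs[s.strip()] = expr.strip()
        elif key == "init":
            s, _, val = rest.partition("=")
            toks = val.split()
            if toks[0] == "free":
                z0[s.strip()] = FreeInitial(float(toks[1]), float(toks[2]))
            else:
                z0[s.strip()] = float(toks[0])
        elif key == "state_bound":
            s, lo, hi = rest.split()
            state_bounds[s] = (float(lo), float(hi))
        elif key == "experiment_init":
            u, s, v = rest.split()
            experiment_init.setdefault(u, {})[s] = float(v)
        elif key == "observe":
            s, sc, off = rest.split()
            scale[s] = _num_or_name(sc)
            offset[s] = _num_or_name(off)
        else:
            raise ModelValidationError(f"unknown model-file key {key!r}")

    model = OdeModel(
        name=name,
        states=tuple(states),
        observed=tuple(observed),
        params=params,
        rhs=rhs,
        z0=z0,
        horizon=horizon,
        extra_dof=extra,
        state_bounds=state_bounds,
        experiment_init=experiment_init,
    )
    obs = ObservationMap(scale=scale, offset=offset)
    return validate_model(model), obs
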