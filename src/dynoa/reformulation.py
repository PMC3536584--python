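"""Symbolic reformulation to a bilinear canonical form.

Every transcription equation is decomposed recursively: nonlinear atoms
(products, quotients, integer powers, exp/log/sqrt) are replaced by auxiliary
variables with defining identities collected in term registries, leaving a
purely linear core ``A w = b``.  Quotients are rewritten through the bilinear
transform (``w_k = w_i / w_j`` becomes the product identity
``w_k * w_j = w_i``), so the only nonconvexities the relaxation must handle
are bilinear products, registered powers and univariate convex/concave
functions.  Natural interval extension assigns a valid box to every auxiliary
variable; the relaxation tightness downstream depends directly on these boxes.

Common subexpressions are shared by default (one auxiliary per distinct atom),
which keeps the number of binaries in the piecewise relaxation proportional to
the number of *distinct* partitioned variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import sympy as sp

__all__ = ["interval_bound", "CanonicalForm", "reformulate", "dump_canonical", "extend_point"]

_INF = math.inf


class IntervalDomainError(ValueError):
    """Interval evaluation hit an invalid domain (division by an interval
    containing zero, log/sqrt touching negatives)."""


def _imul(a, b):
    c = (a[0] * b[0], a[0] * b[1], a[1] * b[0], a[1] * b[1])
    c = [0.0 if x != x else x for x in c]  # 0*inf -> treat as 0
    return min(c), max(c)


def _ipow(a, n: int):
    lo, hi = a
    if n == 0:
        return (1.0, 1.0)
    if n < 0:
        return _idiv((1.0, 1.0), _ipow(a, -n))
    if n % 2 == 1:
        return (lo ** n, hi ** n)
    m = 0.0 if lo <= 0.0 <= hi else min(abs(lo), abs(hi)) ** n
    return (m, max(abs(lo), abs(hi)) ** n)


def _idiv(a, b):
    if b[0] <= 0.0 <= b[1]:
        raise IntervalDomainError(f"division by interval containing zero: {b}")
    return _imul(a, (1.0 / b[1], 1.0 / b[0]))


def interval_bound(expr: sp.Expr, boxes: Mapping[str, tuple[float, float]]):
    """Natural interval extension of a grammar expression over variable boxes.

    The enclosure always contains the exact range but may overestimate it
    (the classic dependency effect: ``x - x`` over [0, 1] evaluates to
    [-1, 1]).  Raises :class:`IntervalDomainError` on domain violations.
    """
    if expr.is_Number:
        v = float(expr)
        return (v, v)
    if expr.is_Symbol:
        try:
            return tuple(map(float, boxes[str(expr)]))
        except KeyError:
            raise KeyError(f"no box for symbol {expr}") from None
    if expr.is_Add:
        lo = hi = 0.0
        for a in expr.args:
            l, h = interval_bound(a, boxes)
            lo, hi = lo + l, hi + h
        return (lo, hi)
    if expr.is_Mul:
        acc = (1.0, 1.0)
        for a in expr.args:
            acc = _imul(acc, interval_bound(a, boxes))
        return acc
    if expr.is_Pow:
        base = interval_bound(expr.base, boxes)
        e = expr.exp
        if e.is_Integer:
            if int(e) < 0 and base[0] <= 0.0 <= base[1]:
                raise IntervalDomainError(f"negative power of interval containing zero: {base}")
            return _ipow(base, int(e))
        if e == sp.Rational(1, 2):
            if base[0] < 0:
                raise IntervalDomainError(f"sqrt of interval touching negatives: {base}")
            return (math.sqrt(base[0]), math.sqrt(base[1]))
        if e == sp.Rational(-1, 2):
            if base[0] <= 0:
                raise IntervalDomainError(f"1/sqrt of interval touching non-positives: {base}")
            return (1.0 / math.sqrt(base[1]), 1.0 / math.sqrt(base[0]))
        raise ValueError(f"unsupported exponent {e}")
    if isinstance(expr, sp.exp):
        l, h = interval_bound(expr.args[0], boxes)
        return (math.exp(l), math.exp(h))
    if isinstance(expr, sp.log):
        l, h = interval_bound(expr.args[0], boxes)
        if l <= 0:
            raise IntervalDomainError(f"log of interval touching non-positives: ({l}, {h})")
        return (math.log(l), math.log(h))
    raise ValueError(f"unsupported construct in interval evaluation: {expr!r}")


# ---------------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------------

@dataclass
class CanonicalForm:
    """Linear core plus registered nonconvex atoms over the variable vector w."""

    var_names: list[str]
    lb: list[float]
    ub: list[float]
    var_kind: list[str]  # original kinds plus "aux"
    rows: list[tuple[dict[int, float], float]]  # sum coef*w = rhs
    T_bt: list[tuple[int, int, int]]  # w_k = w_i * w_j  as (i, j, k)
    T_lft: list[tuple[int, int, int]]  # w_k = w_i / w_j  as (i, j, k)
    T_et: list[tuple[int, int, int]]  # w_k = w_i ** n    as (i, k, n)
    T_uft: list[tuple[int, int, str]]  # w_k = f(w_i)     as (i, k, fname)
    #: (zprime index, measurement key) per objective residual; the master
    #: relaxes each square by supporting hyper-planes rather than an atom
    objective_residuals: list[tuple[int, tuple]]
    #: auxiliary definitions in creation order, for extending source points
    aux_defs: list[tuple[int, str, tuple]]
    #: optional linear objective coefficients (added to the epigraph sum)
    objective_linear: dict[int, float] = field(default_factory=dict)
    #: indices into ``rows`` of the source equations, in source order
    source_rows: list[int] = field(default_factory=list)
    source: object | None = None

    def index(self, name: str) -> int:
        idx = getattr(self, "_index", None)
        if idx is None:
            idx = {n: i for i, n in enumerate(self.var_names)}
            self._index = idx
        return idx[name]

    def box(self, i: int) -> tuple[float, float]:
        return (self.lb[i], self.ub[i])


class _Builder:
    def __init__(self, share_common: bool = True):
        self.share = share_common
        self.names: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.kind: list[str] = []
        self.rows: list[tuple[dict[int, float], float]] = []
        self.T_bt: list[tuple[int, int, int]] = []
        self.T_lft: list[tuple[int, int, int]] = []
        self.T_et: list[tuple[int, int, int]] = []
        self.T_uft: list[tuple[int, int, str]] = []
        self.aux_defs: list[tuple[int, str, tuple]] = []
        self.cache: dict = {}
        self.n_aux = 0
        self.by_name: dict[str, int] = {}

    # -- variables ---------------------------------------------------------
    def add_var(self, name: str, lo: float, hi: float, kind: str) -> int:
        i = len(self.names)
        self.names.append(name)
        self.lb.append(float(lo))
        self.ub.append(float(hi))
        self.kind.append(kind)
        self.by_name[name] = i
        return i

    def new_aux(self, lo: float, hi: float, tag: str) -> int:
        self.n_aux += 1
        return self.add_var(f"w{self.n_aux}_{tag}", lo, hi, "aux")

    def box_of(self, i: int) -> tuple[float, float]:
        return (self.lb[i], self.ub[i])

    def _check_finite(self, i: int, context: str) -> None:
        if not (math.isfinite(self.lb[i]) and math.isfinite(self.ub[i])):
            raise ValueError(
                f"unbounded variable {self.names[i]!r} reachable from nonlinear atom {context}"
            )

    # -- atoms -------------------------------------------------------------
    def bilinear(self, i: int, j: int) -> int:
        i, j = min(i, j), max(i, j)
        key = ("bt", i, j)
        if self.share and key in self.cache:
            return self.cache[key]
        self._check_finite(i, "product")
        self._check_finite(j, "product")
        lo, hi = _imul(self.box_of(i), self.box_of(j))
        k = self.new_aux(lo, hi, f"{self.names[i]}.{self.names[j]}")
        self.T_bt.append((i, j, k))
        self.aux_defs.append((k, "bilinear", (i, j)))
        self.cache[key] = k
        return k

    def fraction(self, i: int, j: int) -> int:
        key = ("lft", i, j)
        if self.share and key in self.cache:
            return self.cache[key]
        self._check_finite(i, "quotient")
        self._check_finite(j, "quotient")
        lo, hi = _idiv(self.box_of(i), self.box_of(j))
        k = self.new_aux(lo, hi, f"{self.names[i]}/{self.names[j]}")
        self.T_lft.append((i, j, k))
        self.aux_defs.append((k, "fraction", (i, j)))
        self.cache[key] = k
        return k

    def power(self, i: int, n: int) -> int:
        key = ("et", i, n)
        if self.share and key in self.cache:
            return self.cache[key]
        self._check_finite(i, "power")
        lo, hi = _ipow(self.box_of(i), n)
        k = self.new_aux(lo, hi, f"{self.names[i]}^{n}")
        self.T_et.append((i, k, n))
        self.aux_defs.append((k, "power", (i, n)))
        self.cache[key] = k
        return k

    def univariate(self, i: int, fname: str) -> int:
        key = ("uft", i, fname)
        if self.share and key in self.cache:
            return self.cache[key]
        self._check_finite(i, fname)
        fn = {"exp": sp.exp, "log": sp.log, "sqrt": sp.sqrt}[fname]
        lo, hi = interval_bound(fn(sp.Symbol("_x")), {"_x": self.box_of(i)})
        k = self.new_aux(lo, hi, f"{fname}({self.names[i]})")
        self.T_uft.append((i, k, fname))
        self.aux_defs.append((k, "univariate", (i, fname)))
        self.cache[key] = k
        return k

    # -- decomposition -----------------------------------------------------
    def to_affine(self, expr: sp.Expr) -> tuple[dict[int, float], float]:
        """Decompose ``expr`` into an affine form over (original + aux) vars."""
        if expr.is_Number:
            return {}, float(expr)
        if expr.is_Symbol:
            return {self.by_name[str(expr)]: 1.0}, 0.0
        if expr.is_Add:
            coefs: dict[int, float] = {}
            const = 0.0
            for a in expr.args:
                c, k0 = self.to_affine(a)
                const += k0
                for i, v in c.items():
                    coefs[i] = coefs.get(i, 0.0) + v
            return {i: v for i, v in coefs.items() if v != 0.0}, const
        if expr.is_Mul:
            coef = 1.0
            numer: list[int] = []
            denom: list[int] = []
            for a in expr.args:
                if a.is_Number:
                    coef *= float(a)
                elif a.is_Pow and a.exp.is_Integer and int(a.exp) < 0:
                    b = self.to_var(a.base)
                    denom.extend([b] * (-int(a.exp)))
                else:
                    numer.append(self.to_var(a))
            if not numer and not denom:
                return {}, coef
            if not numer:
                one = self._one_var()
                numer = [one]
            numer.sort()
            acc = numer[0]
            for i in numer[1:]:
                acc = self.bilinear(acc, i)
            for j in denom:
                acc = self.fraction(acc, j)
            return {acc: coef}, 0.0
        if expr.is_Pow:
            e = expr.exp
            if e.is_Integer:
                n = int(e)
                base = self.to_var(expr.base)
                if n >= 2:
                    return {self.power(base, n): 1.0}, 0.0
                if n == 1:
                    return {base: 1.0}, 0.0
                # negative powers: 1 / base**(-n)
                inner = self.power(base, -n) if n < -1 else base
                return {self.fraction(self._one_var(), inner): 1.0}, 0.0
            if e == sp.Rational(1, 2):
                return {self.univariate(self.to_var(expr.base), "sqrt"): 1.0}, 0.0
            if e == sp.Rational(-1, 2):
                root = self.univariate(self.to_var(expr.base), "sqrt")
                return {self.fraction(self._one_var(), root): 1.0}, 0.0
            raise ValueError(f"unsupported exponent {e} in {expr}")
        if isinstance(expr, sp.exp):
            return {self.univariate(self.to_var(expr.args[0]), "exp"): 1.0}, 0.0
        if isinstance(expr, sp.log):
            return {self.univariate(self.to_var(expr.args[0]), "log"): 1.0}, 0.0
        raise ValueError(f"unsupported construct {expr!r}")

    def to_var(self, expr: sp.Expr) -> int:
        """Index of a variable equal to ``expr``, adding an auxiliary if needed."""
        if expr.is_Symbol:
            return self.by_name[str(expr)]
        if self.share and expr in self.cache:
            return self.cache[expr]
        coefs, const = self.to_affine(expr)
        if const == 0.0 and len(coefs) == 1:
            (i, v), = coefs.items()
            if v == 1.0:
                if self.share:
                    self.cache[expr] = i
                return i
        lo = const
        hi = const
        for i, v in coefs.items():
            l, h = _imul((v, v), self.box_of(i))
            lo += l
            hi += h
        k = self.new_aux(lo, hi, "aff")
        self.aux_defs.append((k, "affine", (dict(coefs), const)))
        row = dict(coefs)
        row[k] = row.get(k, 0.0) - 1.0
        self.rows.append((row, -const))
        if self.share:
            self.cache[expr] = k
        return k

    def _one_var(self) -> int:
        key = ("const", 1.0)
        if key in self.cache:
            return self.cache[key]
        k = self.add_var("w_one", 1.0, 1.0, "aux")
        self.aux_defs.append((k, "affine", ({}, 1.0)))
        self.cache[key] = k
        return k


def reformulate(nlp, share_common: bool = True) -> CanonicalForm:
    """Reformulate a :class:`~dynoa.collocation.TranscribedNlp` into the
    canonical linear-core + term-registry form, including the objective split
    ``z' = zhat - zbar`` with one residual variable per measurement."""
    b = _Builder(share_common=share_common)
    for v in nlp.variables:
        if not (math.isfinite(v.lo) and math.isfinite(v.hi)):
            raise ValueError(f"variable {v.name!r} must have a finite box")
        b.add_var(v.name, v.lo, v.hi, v.kind)

    source_rows: list[int] = []
    for eq in nlp.equations:
        coefs, const = b.to_affine(sp.expand(eq.expr))
        source_rows.append(len(b.rows))
        b.rows.append((coefs, -const))

    objective_residuals: list[tuple[int, tuple]] = []
    for nm, zbar, key in nlp.residuals:
        i = b.by_name[nm]
        lo, hi = b.box_of(i)
        k = b.add_var(f"zp_{nm}", lo - zbar, hi - zbar, "zprime")
        b.aux_defs.append((k, "affine", ({i: 1.0}, -zbar)))
        b.rows.append(({i: 1.0, k: -1.0}, zbar))
        objective_residuals.append((k, key))

    return CanonicalForm(
        var_names=b.names, lb=b.lb, ub=b.ub, var_kind=b.kind, rows=b.rows,
        T_bt=b.T_bt, T_lft=b.T_lft, T_et=b.T_et, T_uft=b.T_uft,
        objective_residuals=objective_residuals, aux_defs=b.aux_defs,
        source_rows=source_rows, source=nlp,
    )


def extend_point(canon: CanonicalForm, point: Mapping[str, float]) -> list[float]:
    """Extend a point on the source variables to the full canonical vector by
    evaluating the auxiliary definitions in creation order."""
    w = [math.nan] * len(canon.var_names)
    for i, nm in enumerate(canon.var_names):
        if nm in point:
            w[i] = float(point[nm])
    for k, kind, payload in canon.aux_defs:
        if kind == "affine":
            coefs, const = payload
            w[k] = const + sum(v * w[i] for i, v in coefs.items())
        elif kind == "bilinear":
            i, j = payload
            w[k] = w[i] * w[j]
        elif kind == "fraction":
            i, j = payload
            w[k] = w[i] / w[j]
        elif kind == "power":
            i, n = payload
            w[k] = w[i] ** n
        elif kind == "univariate":
            i, fname = payload
            w[k] = {"exp": math.exp, "log": math.log, "sqrt": math.sqrt}[fname](w[i])
    return w


def dump_canonical(canon: CanonicalForm) -> str:
    """Flat text dump (variables, boxes, sparse linear core, registries)."""
    out = ["# canonical form"]
    out.append(f"variables {len(canon.var_names)}")
    for i, nm in enumerate(canon.var_names):
        out.append(f"var {i} {nm} {canon.lb[i]!r} {canon.ub[i]!r} {canon.var_kind[i]}")
    out.append(f"rows {len(canon.rows)}")
    for r, (coefs, rhs) in enumerate(canon.rows):
        terms = " ".join(f"{i}:{coefs[i]!r}" for i in sorted(coefs))
        out.append(f"row {r} {terms} = {rhs!r}")
    for label, entries in (
        ("T_bt", canon.T_bt), ("T_lft", canon.T_lft), ("T_et", canon.T_et),
        ("T_uft", canon.T_uft),
    ):
        for entry in entries:
            out.append(f"{label} " + " ".join(map(str, entry)))
    for k, key in canon.objective_residuals:
        out.append(f"objective_residual {k} {key}")
    return "\n".join(out) + "\n"
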