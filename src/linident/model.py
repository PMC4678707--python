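"""Linear state-space models with symbolic parameters, and experiment conditions.

A model is the pair of equations

    dx/dt = A x + B u,   x(0) = x0
        y = C x + D u

where the entries of A, B, C, D are expressions in named rate parameters.
An experiment condition fixes the initial state ``x0`` and the constant
control levels ``u0``; each entry may be a number, a free symbol (a designed
but unspecified level) or exactly zero.  Zero/nonzero structure of the
condition is what decides which parameter correlations are visible in the
output, so conditions are first-class objects here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "LinearModel",
    "ExperimentCondition",
    "TrueParameterSet",
    "build_model",
    "fix_params",
    "random_model",
]

#: symbol used as the Laplace variable throughout the package
s = sp.Symbol("s")


def _as_matrix(entries, nrows, ncols, name):
    m = sp.Matrix(entries) if not isinstance(entries, sp.MatrixBase) else sp.Matrix(entries)
    if m.shape == (0, 0) and (nrows == 0 or ncols == 0):
        m = sp.zeros(nrows, ncols)
    if m.shape != (nrows, ncols):
        raise ValueError(
            f"matrix {name} has shape {m.shape}, expected {(nrows, ncols)}"
        )
    return sp.ImmutableMatrix(m)


@dataclass(frozen=True)
class LinearModel:
    """A time-invariant linear state-space model with symbolic entries.

    Parameters are the free symbols of (A, B, C, D); their order is
    significant (it fixes the column order of the sensitivity matrix and
    the component order of every nullspace vector).
    """

    name: str
    state_names: tuple[str, ...]
    output_names: tuple[str, ...]
    input_names: tuple[str, ...]
    params: tuple[sp.Symbol, ...]
    A: sp.ImmutableMatrix
    B: sp.ImmutableMatrix
    C: sp.ImmutableMatrix
    D: sp.ImmutableMatrix
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        n_x, n_y, n_u = self.n_x, self.n_y, self.n_u
        object.__setattr__(self, "A", _as_matrix(self.A, n_x, n_x, "A"))
        object.__setattr__(self, "B", _as_matrix(self.B, n_x, n_u, "B"))
        object.__setattr__(self, "C", _as_matrix(self.C, n_y, n_x, "C"))
        object.__setattr__(self, "D", _as_matrix(self.D, n_y, n_u, "D"))
        if len(set(self.params)) != len(self.params):
            raise ValueError("duplicate parameter symbols")
        if len(self.params) < 1:
            raise ValueError("model must have at least one parameter")
        free = set().union(*(m.free_symbols for m in (self.A, self.B, self.C, self.D)))
        extra = free - set(self.params)
        if extra:
            raise ValueError(f"symbols {sorted(extra, key=str)} not declared as parameters")
        for names, n, what in (
            (self.state_names, n_x, "state"),
            (self.output_names, n_y, "output"),
            (self.input_names, n_u, "input"),
        ):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {what} names")

    # -- dimensions ------------------------------------------------------
    @property
    def n_x(self) -> int:
        return len(self.state_names)

    @property
    def n_y(self) -> int:
        return len(self.output_names)

    @property
    def n_u(self) -> int:
        return len(self.input_names)

    @property
    def n_p(self) -> int:
        return len(self.params)

    # -- parameter blocks ------------------------------------------------
    def params_in(self, which: str) -> tuple[sp.Symbol, ...]:
        """Parameters appearing in one of the matrices 'A', 'B', 'C', 'D'."""
        m = getattr(self, which)
        return tuple(p for p in self.params if p in m.free_symbols)

    def param_blocks(self) -> dict[str, tuple[sp.Symbol, ...]]:
        return {k: self.params_in(k) for k in "ABCD"}

    def subs_params(self, values: Mapping[sp.Symbol, float]) -> tuple[np.ndarray, ...]:
        """Numeric (A, B, C, D) for a full parameter assignment."""
        out = []
        for m in (self.A, self.B, self.C, self.D):
            out.append(np.array(sp.Matrix(m).subs(values), dtype=float))
        return tuple(out)

    def to_dict(self) -> dict:
        """Serializable description (inverse of :func:`build_model`)."""
        d = {
            "name": self.name,
            "states": list(self.state_names),
            "inputs": list(self.input_names),
            "outputs": list(self.output_names),
            "params": [str(p) for p in self.params],
            "A": [[str(e) for e in row] for row in self.A.tolist()],
            "B": [[str(e) for e in row] for row in self.B.tolist()],
            "C": [[str(e) for e in row] for row in self.C.tolist()],
            "D": [[str(e) for e in row] for row in self.D.tolist()],
        }
        if self.metadata:
            d["metadata"] = dict(self.metadata)
        return d

    def __repr__(self):  # compact; the matrices can be large
        return (
            f"<LinearModel {self.name!r}: n_x={self.n_x}, n_y={self.n_y}, "
            f"n_u={self.n_u}, n_p={self.n_p}>"
        )


def _parse_entry(e):
    if isinstance(e, sp.Expr):
        return e
    if isinstance(e, (int, float)):
        return sp.nsimplify(e, rational=True)
    return sp.parse_expr(str(e))


def build_model(
    spec: Mapping,
    *,
    name: str | None = None,
) -> LinearModel:
    """Build and validate a :class:`LinearModel` from a plain description.

    ``spec`` maps ``states``/``inputs``/``outputs`` to name lists and
    ``A``/``B``/``C``/``D`` to matrices given as lists of lists of
    expression strings (grammar: ``+ - * / ( )``, identifiers, numbers).
    The parameter list is inferred as the sorted set of free symbols unless
    an explicit ``params`` list overrides it.
    """
    states = list(spec.get("states") or [])
    inputs = list(spec.get("inputs") or [])
    outputs = list(spec.get("outputs") or [])
    if not states:
        raise ValueError("model needs at least one state")
    n_x, n_u, n_y = len(states), len(inputs), len(outputs)

    def parse_matrix(key, nrows, ncols):
        raw = spec.get(key)
        if raw is None:
            return sp.zeros(nrows, ncols)
        rows = [[_parse_entry(e) for e in row] for row in raw]
        m = sp.Matrix(rows) if rows else sp.zeros(nrows, ncols)
        if m.shape != (nrows, ncols):
            raise ValueError(f"matrix {key} has shape {m.shape}, expected {(nrows, ncols)}")
        return m

    A = parse_matrix("A", n_x, n_x)
    B = parse_matrix("B", n_x, n_u)
    C = parse_matrix("C", n_y, n_x)
    D = parse_matrix("D", n_y, n_u)

    declared = spec.get("params")
    if declared:
        params = tuple(sp.Symbol(str(p)) for p in declared)
    else:
        free = set().union(*(m.free_symbols for m in (A, B, C, D)))
        params = tuple(sorted(free, key=str))
    return LinearModel(
        name=name or spec.get("name", "model"),
        state_names=tuple(states),
        output_names=tuple(outputs),
        input_names=tuple(inputs),
        params=params,
        A=A,
        B=B,
        C=C,
        D=D,
        metadata=dict(spec.get("metadata") or {}),
    )


def fix_params(model: LinearModel, values: Mapping) -> LinearModel:
    """Return a copy of ``model`` with some parameters held at known values.

    The fixed parameters are substituted into (A, B, C, D) and removed from
    the parameter list; use this to analyze identifiability of the
    remaining parameters when part of the model is known (e.g. a measured
    volume of distribution).
    """
    subs = {
        (sp.Symbol(str(k)) if not isinstance(k, sp.Symbol) else k): sp.nsimplify(v, rational=True)
        for k, v in values.items()
    }
    unknown = set(subs) - set(model.params)
    if unknown:
        raise ValueError(f"cannot fix non-parameters {sorted(unknown, key=str)}")
    remaining = tuple(p for p in model.params if p not in subs)
    if not remaining:
        raise ValueError("fixing all parameters leaves nothing to analyze")
    return LinearModel(
        name=model.name,
        state_names=model.state_names,
        output_names=model.output_names,
        input_names=model.input_names,
        params=remaining,
        A=model.A.subs(subs),
        B=model.B.subs(subs),
        C=model.C.subs(subs),
        D=model.D.subs(subs),
        metadata=dict(model.metadata),
    )


# ---------------------------------------------------------------------------
# experiment conditions
# ---------------------------------------------------------------------------

def _cond_entry(e):
    """Normalize a condition entry to 0, a number, or a sympy Symbol."""
    if isinstance(e, sp.Symbol):
        return e
    if isinstance(e, sp.Expr):
        if e.is_number:
            return float(e) if float(e) != 0 else sp.Integer(0)
        raise ValueError(f"condition entry must be number, symbol or 0, got {e}")
    if isinstance(e, str):
        return sp.Symbol(e)
    v = float(e)
    return sp.Integer(0) if v == 0 else v


@dataclass(frozen=True)
class ExperimentCondition:
    """Initial state x0 and constant control levels u0 of one experiment.

    Entries are numbers, free symbols (generic nonzero levels) or zero.
    A *dataset* in the sense used throughout this package is the noise-free
    output time course generated by one such condition.
    """

    x0: tuple
    u0: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "x0", tuple(_cond_entry(e) for e in self.x0))
        object.__setattr__(self, "u0", tuple(_cond_entry(e) for e in self.u0))

    # -- introspection ---------------------------------------------------
    @property
    def symbols(self) -> set[sp.Symbol]:
        return {e for e in self.x0 + self.u0 if isinstance(e, sp.Symbol)}

    @property
    def is_numeric(self) -> bool:
        return not self.symbols

    @property
    def is_zero(self) -> bool:
        return all(e == 0 for e in self.x0 + self.u0)

    def validate(self, model: LinearModel) -> None:
        if len(self.x0) != model.n_x:
            raise ValueError(f"x0 has length {len(self.x0)}, expected {model.n_x}")
        if len(self.u0) != model.n_u:
            raise ValueError(f"u0 has length {len(self.u0)}, expected {model.n_u}")
        clash = self.symbols & set(model.params)
        if clash:
            raise ValueError(
                f"condition symbols {sorted(clash, key=str)} collide with model parameters"
            )

    # -- transformations -------------------------------------------------
    def generic(self, model: LinearModel) -> "ExperimentCondition":
        """Replace every nonzero entry by a canonical free symbol.

        The analysis of structural vs. practical non-identifiability is run
        on this symbolic version of the condition: zeros stay zero, every
        nonzero (numeric or symbolic) entry becomes ``x{i}0`` / ``u{j}0``.
        """
        x0 = tuple(
            sp.Integer(0) if e == 0 else sp.Symbol(f"x{i + 1}0")
            for i, e in enumerate(self.x0)
        )
        u0 = tuple(
            sp.Integer(0) if e == 0 else sp.Symbol(f"u{j + 1}0")
            for j, e in enumerate(self.u0)
        )
        cond = ExperimentCondition(x0, u0)
        cond.validate(model)
        return cond

    def randomize(self, rng: np.random.Generator, lo: float = 0.5, hi: float = 2.0):
        """Numeric condition honoring the zero/nonzero pattern.

        Symbolic entries get a fresh uniform draw on [lo, hi]; numeric
        entries (including zeros) are kept as they are.
        """
        x0 = tuple(
            float(rng.uniform(lo, hi)) if isinstance(e, sp.Symbol) else e
            for e in self.x0
        )
        u0 = tuple(
            float(rng.uniform(lo, hi)) if isinstance(e, sp.Symbol) else e
            for e in self.u0
        )
        return ExperimentCondition(x0, u0)

    def describe(self) -> str:
        xs = ", ".join(f"x{i+1}(0)={e}" for i, e in enumerate(self.x0))
        us = ", ".join(f"u{j+1}={e}" for j, e in enumerate(self.u0))
        return "; ".join(p for p in (xs, us) if p)


@dataclass(frozen=True)
class TrueParameterSet:
    """Numeric truth for simulation fixtures: parameter symbol -> value."""

    values: tuple[tuple[sp.Symbol, float], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "TrueParameterSet":
        items = tuple(
            (sp.Symbol(str(k)) if not isinstance(k, sp.Symbol) else k, float(v))
            for k, v in mapping.items()
        )
        if not all(np.isfinite(v) for _, v in items):
            raise ValueError("parameter values must be finite")
        return cls(items)

    def as_dict(self) -> dict[sp.Symbol, float]:
        return dict(self.values)

    def validate(self, model: LinearModel) -> None:
        missing = set(model.params) - {k for k, _ in self.values}
        if missing:
            raise ValueError(f"missing true values for {sorted(missing, key=str)}")

    def __len__(self):
        return len(self.values)


# ---------------------------------------------------------------------------
# random compartment-style model generator
# ---------------------------------------------------------------------------

def random_model(
    n_x: int,
    n_y: int,
    observed_states: Sequence[int] | None = None,
    seed: int = 0,
    *,
    edge_prob: float = 0.5,
    with_input: bool = True,
) -> tuple[LinearModel, TrueParameterSet]:
    """Generate a random compartment model with one rate per transfer edge.

    Compartment ``j`` loses mass at rate ``(p0j + sum_i pij)`` (leak plus
    transfers) and compartment ``i`` gains ``pij * xj``; C selects
    ``observed_states``.  Reproducible for a fixed ``seed``.
    """
    if not (1 <= n_y <= n_x <= 6):
        raise ValueError("need 1 <= n_y <= n_x <= 6")
    rng = np.random.default_rng(seed)
    if observed_states is None:
        observed_states = list(range(n_y))
    observed_states = list(observed_states)
    if len(observed_states) != n_y or any(not 0 <= i < n_x for i in observed_states):
        raise ValueError("observed_states must list n_y valid state indices")

    A = sp.zeros(n_x, n_x)
    params: list[sp.Symbol] = []
    values: dict[sp.Symbol, float] = {}

    def add_param(name):
        p = sp.Symbol(name)
        params.append(p)
        values[p] = float(rng.uniform(0.5, 2.0))
        return p

    for j in range(n_x):
        outflow = sp.Integer(0)
        for i in range(n_x):
            if i == j:
                continue
            if rng.uniform() < edge_prob:
                pij = add_param(f"p{i + 1}{j + 1}")
                A[i, j] += pij
                outflow += pij
        leak = add_param(f"p0{j + 1}")
        A[j, j] = -(outflow + leak)

    n_u = 1 if with_input else 0
    B = sp.zeros(n_x, n_u)
    if with_input:
        B[0, 0] = 1
    C = sp.zeros(n_y, n_x)
    for r, i in enumerate(observed_states):
        C[r, i] = 1
    D = sp.zeros(n_y, n_u)

    model = LinearModel(
        name=f"random-{n_x}x{n_y}-seed{seed}",
        state_names=tuple(f"x{i + 1}" for i in range(n_x)),
        output_names=tuple(f"y{r + 1}" for r in range(n_y)),
        input_names=tuple(f"u{j + 1}" for j in range(n_u)),
        params=tuple(params),
        A=A,
        B=B,
        C=C,
        D=D,
    )
    return model, TrueParameterSet.from_mapping(values)
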