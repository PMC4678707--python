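"""Noise-free simulation, least-squares refitting, and correlation scans.

The symbolic verdicts are validated numerically: the model is simulated
exactly (matrix-exponential propagation of the augmented constant-input
system), noise-free datasets are fitted with bounded trust-region least
squares, and repeating the fit with one correlated parameter fixed at a
grid of values traces out the correlation manifold -- along which any
identifiable combination stays constant while the individual parameters
drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.linalg import expm
from scipy.optimize import least_squares

from .correlation import DEFAULT_SEED, numeric_rank
from .model import ExperimentCondition, LinearModel, TrueParameterSet

__all__ = [
    "Dataset",
    "FitResult",
    "ScanTable",
    "simulate",
    "fit",
    "correlation_scan",
    "finite_difference_sensitivity_rank",
]

#: solver defaults: positive-parameter bounds and tight tolerances --
#: noise-free data should be fitted essentially to machine precision
BOUNDS = (1e-6, 1e3)
FIT_TOL = 1e-12
N_STARTS = 5

#: relative step for central-difference output sensitivities
FD_REL_STEP = 1e-6
#: rank threshold for finite-difference matrices (looser than the exact
#: 1e-10 used on symbolically evaluated matrices: the differencing itself
#: carries O(step**2) error)
FD_RANK_RTOL = 1e-8


@dataclass(frozen=True)
class Dataset:
    """Noise-free output time courses from one experiment condition."""

    time_points: np.ndarray
    outputs: np.ndarray  # n_y x n_t
    condition: ExperimentCondition

    def __post_init__(self):
        t = np.asarray(self.time_points, dtype=float)
        y = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if y.shape[1] != t.size:
            raise ValueError("outputs and time points disagree in length")
        if not np.all(np.isfinite(y)):
            raise ValueError("outputs contain non-finite values")
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "outputs", y)


def _as_value_dict(values) -> dict:
    if isinstance(values, TrueParameterSet):
        return values.as_dict()
    return {
        (sp.Symbol(str(k)) if not isinstance(k, sp.Symbol) else k): float(v)
        for k, v in values.items()
    }


def _numeric_condition(cond: ExperimentCondition):
    if not cond.is_numeric:
        raise ValueError("simulation needs a fully numeric condition")
    return (
        np.array([float(e) for e in cond.x0]),
        np.array([float(e) for e in cond.u0]),
    )


def _propagate(A, Bu, x0, ts):
    """States at ts for dx/dt = A x + Bu (constant drive), exactly.

    Uses the augmented homogeneous system [[A, Bu], [0, 0]] so a singular
    A needs no special casing; one matrix exponential per distinct step.
    """
    n = A.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = Bu
    z = np.concatenate([x0, [1.0]])
    out = np.empty((len(ts), n))
    steps = np.diff(np.concatenate([[0.0], ts]))
    cache: dict[float, np.ndarray] = {}
    for i, dt in enumerate(steps):
        key = round(float(dt), 15)
        if key not in cache:
            cache[key] = expm(aug * dt)
        z = cache[key] @ z
        out[i] = z[:n]
    return out


def simulate(
    model: LinearModel,
    values,
    cond: ExperimentCondition,
    time_points: Sequence[float],
) -> Dataset:
    """Exact noise-free dataset y(t) = C x(t) + D u0 at the given times."""
    cond.validate(model)
    vals = _as_value_dict(values)
    missing = set(model.params) - set(vals)
    if missing:
        raise ValueError(f"missing values for {sorted(missing, key=str)}")
    A, B, C, D = model.subs_params(vals)
    x0, u0 = _numeric_condition(cond)
    ts = np.asarray(time_points, dtype=float)
    Bu = B @ u0 if model.n_u else np.zeros(model.n_x)
    X = _propagate(A, Bu, x0, ts)
    Y = (C @ X.T) + (D @ u0)[:, None] if model.n_u else C @ X.T
    return Dataset(time_points=ts, outputs=Y, condition=cond)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit."""

    estimates: dict
    fixed: dict
    residual_norm: float
    converged: bool

    def all_values(self) -> dict:
        return {**self.estimates, **self.fixed}


@dataclass(frozen=True)
class ScanTable:
    """Rows of (fixed sweep value, FitResult) for a swept parameter."""

    sweep_param: sp.Symbol
    rows: tuple

    def values(self, expr) -> np.ndarray:
        """Evaluate an expression of the parameters on every scan row."""
        expr = sp.sympify(expr)
        syms = sorted(expr.free_symbols, key=str)
        f = sp.lambdify(syms, expr, "numpy")
        out = []
        for _, res in self.rows:
            allv = {str(k): v for k, v in res.all_values().items()}
            out.append(float(f(*(allv[str(sy)] for sy in syms))))
        return np.array(out)

    def estimates_frame(self):
        """Scan results as a pandas DataFrame (one row per sweep value)."""
        import pandas as pd

        recs = []
        for sval, res in self.rows:
            rec = {str(self.sweep_param): sval}
            rec.update({str(k): v for k, v in res.all_values().items()})
            rec["residual_norm"] = res.residual_norm
            rec["converged"] = res.converged
            recs.append(rec)
        return pd.DataFrame(recs)


def _residual_fn(model: LinearModel, datasets, free_params, fixed_vals):
    """Vectorized residual over all datasets for the free parameters."""
    sims = []
    for ds in datasets:
        x0, u0 = _numeric_condition(ds.condition)
        sims.append((ds, x0, u0))
    A_f, B_f, C_f, D_f = (
        sp.lambdify([list(model.params)], sp.Matrix(m), "numpy")
        for m in (model.A, model.B, model.C, model.D)
    )
    order = list(model.params)
    fixed_idx = {order.index(p): v for p, v in fixed_vals.items()}
    free_idx = [order.index(p) for p in free_params]

    def fun(theta):
        full = np.empty(len(order))
        for i, v in fixed_idx.items():
            full[i] = v
        full[free_idx] = theta
        A = np.asarray(A_f(full), dtype=float)
        B = np.asarray(B_f(full), dtype=float)
        C = np.asarray(C_f(full), dtype=float)
        D = np.asarray(D_f(full), dtype=float)
        res = []
        for ds, x0, u0 in sims:
            Bu = B @ u0 if u0.size else np.zeros(model.n_x)
            X = _propagate(A, Bu, x0, ds.time_points)
            Y = C @ X.T + ((D @ u0)[:, None] if u0.size else 0.0)
            res.append((Y - ds.outputs).ravel())
        return np.concatenate(res)

    return fun


def fit(
    model: LinearModel,
    datasets: Sequence[Dataset],
    fixed: Mapping | None = None,
    start: Mapping | None = None,
    *,
    n_starts: int = N_STARTS,
    seed: int = DEFAULT_SEED,
    bounds: tuple = BOUNDS,
) -> FitResult:
    """Bounded nonlinear least squares over the stacked datasets.

    All parameters not in ``fixed`` are estimated.  The first start is
    ``start`` (default: all ones); the remaining ``n_starts - 1`` starts
    are drawn log-uniform on [0.1, 10] (seeded).  The best residual wins.
    Non-convergence of every start is reported via ``converged``, not
    raised.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    fixed = _as_value_dict(fixed or {})
    free = [p for p in model.params if p not in fixed]
    if not free:
        raise ValueError("no free parameters to fit")
    start = _as_value_dict(start or {})
    theta0 = np.array([start.get(p, 1.0) for p in free])
    fun = _residual_fn(model, datasets, free, fixed)
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=len(free)))
        for _ in range(max(0, n_starts - 1))
    ]
    best = None
    for th0 in starts:
        th0 = np.clip(th0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                fun, th0, bounds=bounds, method="trf",
                xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best is not None and np.sqrt(2 * best.cost) < 1e-10:
            break
    if best is None:
        return FitResult(
            estimates={p: float("nan") for p in free},
            fixed=fixed, residual_norm=float("inf"), converged=False,
        )
    return FitResult(
        estimates=dict(zip(free, map(float, best.x))),
        fixed=fixed,
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )


def correlation_scan(
    model: LinearModel,
    datasets: Sequence[Dataset],
    sweep_param,
    sweep_values: Sequence[float],
    start: Mapping | None = None,
    *,
    fixed: Mapping | None = None,
    seed: int = DEFAULT_SEED,
    n_starts: int = N_STARTS,
) -> ScanTable:
    """Repeat the fit with ``sweep_param`` fixed at each value in turn.

    Each fit is warm-started from the previous solution (the correlation
    manifold is continuous), so only the first fit pays the multi-start
    price.
    """
    sweep_param = (
        sp.Symbol(str(sweep_param))
        if not isinstance(sweep_param, sp.Symbol)
        else sweep_param
    )
    if sweep_param not in model.params:
        raise ValueError(f"{sweep_param} is not a model parameter")
    fixed = _as_value_dict(fixed or {})
    rows = []
    warm = _as_value_dict(start or {})
    for i, v in enumerate(sweep_values):
        res = fit(
            model, datasets,
            fixed={**fixed, sweep_param: float(v)},
            start=warm,
            seed=seed,
            n_starts=n_starts if i == 0 else 1,
        )
        rows.append((float(v), res))
        if res.converged:
            warm = res.estimates
    return ScanTable(sweep_param=sweep_param, rows=tuple(rows))


def finite_difference_sensitivity_rank(
    model: LinearModel,
    values,
    cond: ExperimentCondition,
    time_points: Sequence[float],
    *,
    rel_step: float = FD_REL_STEP,
    rtol: float = FD_RANK_RTOL,
) -> int:
    """Numeric rank of the stacked central-difference output sensitivities.

    This is the package's fully independent, Laplace-free identifiability
    oracle: the column count minus this rank equals the correlation
    nullspace dimension under the same condition.
    """
    vals = _as_value_dict(values)
    cols = []
    for p in model.params:
        h = rel_step * max(abs(vals[p]), 1e-3)
        up = dict(vals)
        dn = dict(vals)
        up[p] = vals[p] + h
        dn[p] = vals[p] - h
        yu = simulate(model, up, cond, time_points).outputs
        yd = simulate(model, dn, cond, time_points).outputs
        cols.append(((yu - yd) / (2 * h)).ravel())
    J = np.array(cols).T
    return numeric_rank(J, rtol=rtol)
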