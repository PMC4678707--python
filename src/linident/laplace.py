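"""Laplace-domain state solutions and polynomial output-sensitivity columns.

For dx/dt = A x + B u with x(0) = x0 and constant controls, the transform
of the state is X(s) = (sI - A)^-1 (B U(s) + x0) with U_i(s) = u0_i / s
(step inputs).  The output sensitivity dY/dp_j is a vector of rational
functions of s; putting all n_p of them over one common denominator and
cancelling any polynomial factor shared by *every* entry leaves polynomial
columns q_j(s).  Linear dependence of those columns over the field of
rational functions in the parameters (and condition symbols) is exactly
linear dependence of the output sensitivities, which is what the
correlation analysis consumes.

The inverse is computed as adjugate / det so all intermediate entries stay
polynomial; the characteristic polynomial Delta = det(sI - A) is the
common denominator of the state solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

from .model import ExperimentCondition, LinearModel, s

__all__ = [
    "AllColumnsZeroError",
    "LaplaceState",
    "SensitivityColumns",
    "characteristic_polynomial",
    "state_laplace",
    "derivative_matrices",
    "sensitivity_columns",
]


class AllColumnsZeroError(ValueError):
    """Raised when every sensitivity column vanishes (x0 = 0 and u0 = 0):
    the output carries no information about any parameter and the
    correlation analysis is meaningless."""


def characteristic_polynomial(model: LinearModel) -> sp.Expr:
    """det(sI - A), monic of degree n_x."""
    n = model.n_x
    return sp.expand((s * sp.eye(n) - sp.Matrix(model.A)).det(method="berkowitz"))


@dataclass(frozen=True)
class LaplaceState:
    """X(s) in cleared-numerator form: X = X_num / den, den = s^m * Delta."""

    Delta: sp.Expr
    X_num: sp.ImmutableMatrix
    den: sp.Expr
    input_power: int  # m: power of s clearing the step-input denominators

    @property
    def X(self) -> sp.ImmutableMatrix:
        return sp.ImmutableMatrix([sp.cancel(e / self.den) for e in self.X_num])


def _input_vector(model: LinearModel, cond: ExperimentCondition, input_mode: str):
    """(U_num, m): transform of the controls as U = U_num / s^m."""
    if model.n_u == 0:
        return sp.Matrix(model.n_u, 1, []), 0
    u0 = sp.Matrix([list(cond.u0)]).T
    if input_mode == "generic":
        # constant free symbols standing for U_i(s); dependence on s dropped
        return u0, 0
    if input_mode == "step":
        if all(e == 0 for e in cond.u0):
            return u0, 0
        return u0, 1  # U_i(s) = u0_i / s
    raise ValueError(f"input_mode must be 'step' or 'generic', got {input_mode!r}")


def state_laplace(
    model: LinearModel,
    cond: ExperimentCondition,
    input_mode: str = "step",
) -> LaplaceState:
    """Solve the state equation in the Laplace domain.

    Returns X(s) = adj(sI - A) (B U_num + s^m x0) / (s^m Delta), where
    m = 1 when any step input is active and 0 otherwise.
    """
    cond.validate(model)
    n = model.n_x
    sI_A = s * sp.eye(n) - sp.Matrix(model.A)
    Delta = sp.expand(sI_A.det(method="berkowitz"))
    adj = sI_A.adjugate()
    U_num, m = _input_vector(model, cond, input_mode)
    x0 = sp.Matrix([list(cond.x0)]).T
    drive = (sp.Matrix(model.B) * U_num if model.n_u else sp.zeros(n, 1)) + s**m * x0
    X_num = sp.ImmutableMatrix([sp.expand(e) for e in adj * drive])
    return LaplaceState(Delta=Delta, X_num=X_num, den=sp.expand(s**m * Delta), input_power=m)


# formal placeholders used by derivative_matrices for readability
def _formal_states(model):
    return sp.Matrix([sp.Symbol(f"X{i + 1}") for i in range(model.n_x)])


def _formal_inputs(model):
    return sp.Matrix([sp.Symbol(f"U{j + 1}") for j in range(model.n_u)])


def derivative_matrices(model: LinearModel, X=None, cond=None):
    """Block derivative matrices (M_A, M_B, M_C, M_D).

    M_A has one column per A-parameter, namely d(A X)/dp evaluated on the
    formal state vector (X1, ..., Xn); likewise M_B = d(B U)/dp on formal
    inputs, M_C = d(C X)/dp and M_D = d(D U)/dp.  Matrices for
    parameter-free blocks have width 0.  The formal symbols keep the result
    readable; :func:`sensitivity_columns` substitutes the actual rational
    X(s) itself.
    """
    Xf = _formal_states(model)
    Uf = _formal_inputs(model)
    blocks = {}
    for key, mat, vec in (
        ("A", sp.Matrix(model.A), Xf),
        ("B", sp.Matrix(model.B), Uf),
        ("C", sp.Matrix(model.C), Xf),
        ("D", sp.Matrix(model.D), Uf),
    ):
        ps = model.params_in(key)
        prod = mat * vec if vec.rows else sp.zeros(mat.rows, 1)
        cols = [prod.diff(p) for p in ps]
        blocks[key] = (
            sp.Matrix.hstack(*cols) if cols else sp.zeros(prod.rows, 0)
        )
    return blocks["A"], blocks["B"], blocks["C"], blocks["D"]


@dataclass(frozen=True)
class SensitivityColumns:
    """Polynomial sensitivity columns q_j(s), one per parameter.

    ``columns[j]`` is a length-n_y vector of polynomials in s (coefficients
    rational in parameters and condition symbols); the full sensitivity is
    columns[j] * removed_factor / denom, where ``removed_factor`` is the
    polynomial factor common to every entry that was cancelled before
    analysis (linear dependence is invariant under common nonzero scaling).
    """

    columns: tuple
    denom: sp.Expr
    param_order: tuple
    degree_bound: int
    removed_factor: sp.Expr
    condition_symbols: frozenset

    @property
    def n_p(self) -> int:
        return len(self.columns)

    @property
    def n_y(self) -> int:
        return len(self.columns[0]) if self.columns else 0

    def scaled(self, factor: sp.Expr) -> "SensitivityColumns":
        """Multiply every column by the same nonzero polynomial (testing aid)."""
        cols = tuple(
            tuple(sp.expand(e * factor) for e in col) for col in self.columns
        )
        deg = max(
            (sp.degree(e, s) for col in cols for e in col if e != 0), default=0
        )
        return SensitivityColumns(
            columns=cols,
            denom=sp.expand(self.denom * factor),
            param_order=self.param_order,
            degree_bound=int(deg),
            removed_factor=self.removed_factor,
            condition_symbols=self.condition_symbols,
        )


def _common_numerator_form(entries):
    """Clear parameter denominators (e.g. a 1/V**2 from a scaled output):
    rewrite entries over one common denominator, return expanded numerators
    and that denominator."""
    fracs = [sp.fraction(sp.together(e)) for e in entries]
    dens = [d for _, d in fracs]
    common = sp.Integer(1)
    for d in dens:
        common = sp.lcm(common, d)
    if common == 1:
        return [sp.expand(n) for n, _ in fracs], common
    nums = [sp.expand(n * sp.cancel(common / d)) for (n, d) in fracs]
    return nums, common


def sensitivity_columns(
    model: LinearModel,
    cond: ExperimentCondition,
    input_mode: str = "step",
) -> SensitivityColumns:
    """Assemble the polynomial output-sensitivity columns q_j(s).

    For each parameter p the sensitivity vector is

        dY/dp = C (sI-A)^-1 [(dA/dp) X + (dB/dp) U] + (dC/dp) X + (dD/dp) U

    (the general form; blocks without parameters contribute nothing).  All
    n_p vectors are put over the common denominator s^m * Delta**2 by
    construction, and any polynomial factor dividing every entry of every
    column is removed afterwards.
    """
    cond.validate(model)
    if cond.is_zero:
        raise AllColumnsZeroError(
            "x0 = 0 and u0 = 0: no excitation, all sensitivity columns vanish"
        )
    lap = state_laplace(model, cond, input_mode)
    n = model.n_x
    sI_A = s * sp.eye(n) - sp.Matrix(model.A)
    adj = sI_A.adjugate()
    C = sp.Matrix(model.C)
    D = sp.Matrix(model.D)
    A = sp.Matrix(model.A)
    B = sp.Matrix(model.B)
    CAdj = C * adj
    X_num = sp.Matrix(lap.X_num)
    m = lap.input_power
    if model.n_u:
        U_num, m_u = _input_vector(model, cond, input_mode)
    else:
        U_num, m_u = sp.zeros(0, 1), 0
    # structural denominators: A-term s^m * Delta^2, B-term s^m_u * Delta,
    # C-term s^m * Delta, D-term s^m_u; everything is lifted to s^m * Delta^2
    lift_B = s ** (m - m_u) * lap.Delta
    lift_C = lap.Delta
    lift_D = s ** (m - m_u) * lap.Delta**2

    raw_cols = []
    for p in model.params:
        vec = CAdj * (A.diff(p) * X_num)
        if model.n_u:
            dB = B.diff(p)
            if any(e != 0 for e in dB):
                vec = vec + (CAdj * (dB * U_num)) * lift_B
            dD = D.diff(p)
            if any(e != 0 for e in dD):
                vec = vec + (dD * U_num) * lift_D
        dC = C.diff(p)
        if any(e != 0 for e in dC):
            vec = vec + (dC * X_num) * lift_C
        raw_cols.append([sp.expand(e) for e in vec])

    flat = [e for col in raw_cols for e in col]
    nums, param_den = _common_numerator_form(flat)
    denom = sp.expand(s**m * lap.Delta**2) * param_den
    if all(e == 0 for e in nums):
        raise AllColumnsZeroError("all sensitivity columns are identically zero")

    nonzero = [e for e in nums if e != 0]
    g = nonzero[0]
    for e in nonzero[1:]:
        g = sp.gcd(g, e)
        if g == 1:
            break
    if g != 1 and g != 0:
        nums = [sp.expand(sp.cancel(e / g)) for e in nums]
    removed = g if g != 1 else sp.Integer(1)

    n_y = model.n_y
    cols = tuple(
        tuple(nums[j * n_y + i] for i in range(n_y)) for j in range(model.n_p)
    )
    deg = max((sp.degree(e, s) for col in cols for e in col if e != 0), default=0)
    return SensitivityColumns(
        columns=cols,
        denom=sp.expand(denom),
        param_order=tuple(model.params),
        degree_bound=int(deg),
        removed_factor=removed,
        condition_symbols=frozenset(cond.symbols),
    )
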