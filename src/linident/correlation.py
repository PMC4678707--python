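"""Parameter-correlation detection from the polynomial sensitivity columns.

A linear combination sum_j alpha_j q_j(s) = 0 must hold coefficient-by-
coefficient in s, which turns column dependence into a homogeneous linear
system beta * alpha = 0 whose entries are functions of the parameters and
of the experiment-condition symbols.  The right nullspace of beta over the
field of rational functions gives the correlated parameter groups; whether
the basis vectors involve condition symbols separates structural from
practical (condition-removable) non-identifiability, and the ratio of the
largest group to the per-dataset equation count gives the minimal number
of noise-free datasets needed to remedy a practical correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import sympy as sp

from .laplace import SensitivityColumns, sensitivity_columns
from .model import ExperimentCondition, LinearModel, s

__all__ = [
    "CoefficientSystem",
    "NullspaceVector",
    "IdentifiabilityReport",
    "coefficient_system",
    "nullspace_basis",
    "classify",
    "analyze_condition",
    "required_datasets",
    "minimal_datasets",
    "stacked_rank_check",
    "numeric_rank",
    "DEFAULT_SEED",
    "MAX_SYMBOLS_EXACT",
]

#: above this many distinct symbols in the coefficient system, the exact
#: nullspace is computed at two exact rational condition draws instead of
#: with fully symbolic condition entries (the symbolic elimination cost
#: grows steeply with the symbol count, the verdicts do not change)
MAX_SYMBOLS_EXACT = 8

#: default seed for all numeric spot checks (draws uniform on [0.5, 2.0])
DEFAULT_SEED = 20151214

#: singular values below RANK_RTOL * sigma_max count as zero
RANK_RTOL = 1e-10


def numeric_rank(mat: np.ndarray, rtol: float = RANK_RTOL) -> int:
    """Rank via SVD with a relative singular-value threshold."""
    if mat.size == 0:
        return 0
    sv = np.linalg.svd(mat, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))


@dataclass(frozen=True)
class CoefficientSystem:
    """The homogeneous system beta * alpha = 0.

    ``rows[r][l]`` multiplies alpha_l in equation r; ``row_labels[r]`` is
    the (output index, s-power) the equation came from.  Entries contain no
    s; they are polynomial in parameters and condition symbols.
    """

    rows: tuple
    row_labels: tuple
    param_order: tuple
    symbols_present: frozenset

    @property
    def n_p(self) -> int:
        return len(self.param_order)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def as_matrix(self) -> sp.Matrix:
        return sp.Matrix([list(r) for r in self.rows]) if self.rows else sp.zeros(0, self.n_p)

    def evaluate(self, assignment: dict) -> np.ndarray:
        """Numeric beta matrix for a full symbol assignment."""
        syms = sorted(assignment, key=str)
        f = sp.lambdify(syms, [list(r) for r in self.rows], "numpy")
        return np.array(f(*(assignment[k] for k in syms)), dtype=float)

    def random_assignment(self, rng: np.random.Generator, lo=0.5, hi=2.0) -> dict:
        syms = sorted(
            set().union(*(e.free_symbols for r in self.rows for e in r))
            if self.rows
            else set(),
            key=str,
        )
        return {sym: float(rng.uniform(lo, hi)) for sym in syms}


def coefficient_system(cols: SensitivityColumns) -> CoefficientSystem:
    """Extract the beta matrix: one equation per (output, s-power) pair.

    Rows that are identically zero are dropped.
    """
    rows, labels = [], []
    for i in range(cols.n_y):
        entries = [sp.Poly(col[i], s) if col[i] != 0 else None for col in cols.columns]
        for k in range(cols.degree_bound + 1):
            row = tuple(
                sp.expand(e.coeff_monomial(s**k)) if e is not None else sp.Integer(0)
                for e in entries
            )
            if any(c != 0 for c in row):
                rows.append(row)
                labels.append((i, k))
    syms = set()
    for r in rows:
        for e in r:
            syms |= e.free_symbols
    return CoefficientSystem(
        rows=tuple(rows),
        row_labels=tuple(labels),
        param_order=cols.param_order,
        symbols_present=frozenset(syms & cols.condition_symbols),
    )


@dataclass(frozen=True)
class NullspaceVector:
    """One correlation relation: entries alpha_1..alpha_np, leading entry 1."""

    entries: tuple

    @property
    def support(self) -> frozenset:
        return frozenset(j for j, e in enumerate(self.entries) if e != 0)

    @property
    def free_symbols(self) -> set:
        return set().union(*(e.free_symbols for e in self.entries)) if self.entries else set()

    def evaluate(self, assignment: dict) -> np.ndarray:
        syms = sorted(assignment, key=str)
        f = sp.lambdify(syms, list(self.entries), "numpy")
        return np.array(f(*(assignment[k] for k in syms)), dtype=float)


def nullspace_basis(system: CoefficientSystem) -> list[NullspaceVector]:
    """Canonical basis of the right nullspace of beta over the field of
    rational functions in all symbols present.

    Computed by exact sparse elimination over the rational-function field
    (deterministic pivoting in parameter order); each basis vector is
    normalized so its first nonzero entry is 1.  An empty list means all
    alpha are forced to zero: every parameter is identifiable from a
    single dataset with the analyzed condition.
    """
    from sympy.polys.solvers import solve_lin_sys, sympy_eqs_to_ring

    n_p = system.n_p
    if not system.rows:
        # no constraints at all: every unit vector is in the nullspace
        basis = []
        for j in range(n_p):
            e = [sp.Integer(0)] * n_p
            e[j] = sp.Integer(1)
            basis.append(NullspaceVector(tuple(e)))
        return basis
    alphas = sp.symbols(f"_alpha0:{n_p}")
    eqs = [
        sp.Add(*(e * a for e, a in zip(row, alphas) if e != 0))
        for row in system.rows
    ]
    ring_eqs, ring = sympy_eqs_to_ring(eqs, alphas)
    sol = solve_lin_sys(ring_eqs, ring, _raw=False)
    if sol is None:  # homogeneous systems are always consistent
        raise RuntimeError("unexpected inconsistent homogeneous system")
    free = [a for a in alphas if a not in sol]
    basis = []
    for f in free:
        assign = {a: (sp.Integer(1) if a is f else sp.Integer(0)) for a in free}
        row = [
            sp.cancel(sol[a].subs(assign)) if a in sol else assign[a]
            for a in alphas
        ]
        lead = next(j for j, e in enumerate(row) if e != 0)
        le = row[lead]
        vec = tuple(sp.cancel(e / le) for e in row)
        basis.append(NullspaceVector(vec))
    basis.sort(key=lambda v: min(v.support))
    return basis


# ---------------------------------------------------------------------------
# classification and dataset counting
# ---------------------------------------------------------------------------

STATUS_IDENTIFIABLE = "identifiable"
STATUS_STRUCTURAL = "structurally-nonidentifiable"
STATUS_PRACTICAL = "practically-nonidentifiable"


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Per-parameter verdicts plus the bookkeeping behind the dataset count."""

    param_order: tuple
    status: dict = field(compare=False)
    groups: tuple = ()
    group_kinds: tuple = ()  # "structural" | "practical", parallel to groups
    basis: tuple = ()
    n_max: int = 0
    equations_per_dataset: int = 0
    observed_independent_rows: int = 0
    n_d: int = 0
    degree_bound: int = 0
    combinations: tuple = ()
    #: True when the basis was computed at an exact rational draw of the
    #: condition symbols (large systems); entries then carry the drawn
    #: condition numerically instead of symbolically
    condition_substituted: bool = False

    @property
    def identifiable(self) -> tuple:
        return tuple(p for p in self.param_order if self.status[p] == STATUS_IDENTIFIABLE)

    @property
    def nonidentifiable(self) -> tuple:
        return tuple(p for p in self.param_order if self.status[p] != STATUS_IDENTIFIABLE)

    def with_combinations(self, combos) -> "IdentifiabilityReport":
        return IdentifiabilityReport(
            **{**self.__dict__, "combinations": tuple(combos)}
        )


def _equations_per_dataset(model: LinearModel, groups, degree_bound: int) -> int:
    """Printed convention for the per-dataset equation count.

    n_y(2n_x - 2) when every correlated parameter lives in A only,
    n_y(2n_x + 1) when all four matrices carry parameters, and
    n_y(degree_bound + 1) otherwise.
    """
    blocks = model.param_blocks()
    grouped = set().union(*groups) if groups else set(model.params)
    a_only = set(blocks["A"])
    for key in "BCD":
        a_only -= set(blocks[key])
    if grouped and grouped <= a_only:
        return model.n_y * (2 * model.n_x - 2)
    if all(blocks[k] for k in "ABCD"):
        return model.n_y * (2 * model.n_x + 1)
    return model.n_y * (degree_bound + 1)


def _is_structural(
    vec: NullspaceVector,
    system: CoefficientSystem,
    cond_symbols: set,
    seed: int,
    tol: float = 1e-10,
) -> bool:
    """Structural iff the relation does not involve the condition.

    Symbolic test (no condition symbols survive cancellation) guarded by a
    two-draw numeric re-randomization of the condition symbols: the
    normalized vector must be numerically unchanged between two independent
    condition draws at a common random parameter point.
    """
    if vec.free_symbols & cond_symbols:
        return False
    if not cond_symbols:
        return True
    rng = np.random.default_rng(seed)
    psyms = sorted(
        (vec.free_symbols | set().union(*(e.free_symbols for r in system.rows for e in r)))
        - cond_symbols,
        key=str,
    )
    pvals = {sym: float(rng.uniform(0.5, 2.0)) for sym in psyms}
    draws = []
    for _ in range(2):
        cvals = {sym: float(rng.uniform(0.5, 2.0)) for sym in sorted(cond_symbols, key=str)}
        draws.append(vec.evaluate({**pvals, **cvals}))
    return bool(np.allclose(draws[0], draws[1], rtol=tol, atol=tol))


def classify(
    model: LinearModel,
    cond: ExperimentCondition,
    basis: list[NullspaceVector],
    *,
    system: CoefficientSystem | None = None,
    degree_bound: int | None = None,
    seed: int = DEFAULT_SEED,
) -> IdentifiabilityReport:
    """Assign per-parameter status and the dataset count from a basis.

    ``cond`` must be the (generic, symbolic) condition the basis was
    computed under.  Groups are the supports of the canonical basis; a
    group is structural when its relation survives re-randomization of the
    condition symbols, practical otherwise.
    """
    if system is None or degree_bound is None:
        cols = sensitivity_columns(model, cond)
        system = coefficient_system(cols) if system is None else system
        degree_bound = cols.degree_bound if degree_bound is None else degree_bound
    cond_syms = set(cond.symbols)
    params = tuple(model.params)
    groups, kinds = [], []
    for vec in basis:
        group = frozenset(params[j] for j in vec.support)
        groups.append(group)
        kinds.append(
            "structural"
            if _is_structural(vec, system, cond_syms, seed)
            else "practical"
        )
    status = {}
    for j, p in enumerate(params):
        in_groups = [k for g, k in zip(groups, kinds) if p in g]
        if not in_groups:
            status[p] = STATUS_IDENTIFIABLE
        elif "structural" in in_groups:
            status[p] = STATUS_STRUCTURAL
        else:
            status[p] = STATUS_PRACTICAL
    n_max = max((len(g) for g in groups), default=0)
    epd = _equations_per_dataset(model, groups, degree_bound)
    rng = np.random.default_rng(seed)
    observed = numeric_rank(system.evaluate(system.random_assignment(rng))) if system.rows else 0
    any_practical = any(k == "practical" for k in kinds)
    n_d = ceil(n_max / epd) if (any_practical and epd > 0) else 0
    return IdentifiabilityReport(
        param_order=params,
        status=status,
        groups=tuple(groups),
        group_kinds=tuple(kinds),
        basis=tuple(basis),
        n_max=n_max,
        equations_per_dataset=epd,
        observed_independent_rows=observed,
        n_d=n_d,
        degree_bound=degree_bound,
    )


def _canonical_numeric_nullspace(B: np.ndarray, rtol: float = RANK_RTOL):
    """Numeric right-nullspace in reduced row-echelon form.

    Returns a (k, n_p) array whose rows mirror the canonical symbolic
    basis: each row has a unit pivot in the leftmost possible column and
    zeros in the other rows' pivot columns, so supports and entries are
    directly comparable across draws.
    """
    _, sv, Vt = np.linalg.svd(B)
    n_p = B.shape[1]
    tol = (sv[0] if sv.size else 0.0) * rtol
    rank = int(np.sum(sv > tol)) if sv.size else 0
    null = Vt[rank:].copy()
    k = null.shape[0]
    if k == 0:
        return null
    # RREF of the nullspace row space, pivoting left to right
    pr = 0
    scale = np.abs(null).max()
    for col in range(n_p):
        if pr >= k:
            break
        i = pr + int(np.argmax(np.abs(null[pr:, col])))
        if abs(null[i, col]) < 1e-8 * scale:
            continue
        null[[pr, i]] = null[[i, pr]]
        null[pr] = null[pr] / null[pr, col]
        for r in range(k):
            if r != pr:
                null[r] = null[r] - null[r, col] * null[pr]
        pr += 1
    # order rows by leading column
    leads = [int(np.argmax(np.abs(r) > 1e-8 * max(np.abs(r).max(), 1e-300))) for r in null]
    return null[np.argsort(leads)]


def _classify_by_draws(
    model: LinearModel,
    cond: ExperimentCondition,
    system: CoefficientSystem,
    degree_bound: int,
    seed: int,
) -> IdentifiabilityReport:
    """Classification for systems too large for fully symbolic elimination.

    Parameters are fixed at one random draw; the condition symbols at two
    independent draws.  Each draw's canonical numeric nullspace is
    computed; a relation identical across the condition draws (to 1e-6)
    is structural, one that moves with the condition is practical.
    Supports are certified against a second parameter draw.
    """
    rng = np.random.default_rng(seed)
    params = tuple(model.params)
    psyms = sorted(set().union(*(e.free_symbols for r in system.rows for e in r))
                   - set(system.symbols_present), key=str)
    csyms = sorted(system.symbols_present, key=str)
    syms = psyms + csyms
    f_rows = sp.lambdify(syms, [list(r) for r in system.rows], "numpy")

    def nullsp(pvals, cvals):
        B = np.array(f_rows(*pvals, *cvals), dtype=float)
        return _canonical_numeric_nullspace(B)

    pvals = rng.uniform(0.5, 2.0, size=len(psyms))
    pvals2 = rng.uniform(0.5, 2.0, size=len(psyms))
    cvals1 = rng.uniform(0.5, 2.0, size=len(csyms))
    cvals2 = rng.uniform(0.5, 2.0, size=len(csyms))
    n1 = nullsp(pvals, cvals1)
    n2 = nullsp(pvals, cvals2)
    n1b = nullsp(pvals2, cvals1)

    def supports(null):
        out = []
        for row in null:
            nz = np.abs(row) > 1e-8 * max(np.abs(row).max(), 1e-300)
            out.append(frozenset(int(j) for j in np.flatnonzero(nz)))
        return out

    s1 = supports(n1)
    if s1 != supports(n2) or s1 != supports(n1b):
        raise RuntimeError(
            "nullspace support differs between random draws; "
            "the analysis appears degenerate -- rerun with another seed"
        )
    basis = [
        NullspaceVector(tuple(sp.Float(x) if abs(x) > 1e-8 else sp.Integer(0) for x in row))
        for row in n1
    ]
    groups, kinds = [], []
    for row1, row2, sup in zip(n1, n2, s1):
        groups.append(frozenset(params[j] for j in sup))
        same = bool(np.allclose(row1, row2, rtol=1e-6, atol=1e-6))
        kinds.append("structural" if same else "practical")
    b1 = basis
    status = {}
    for p in params:
        in_groups = [k for g, k in zip(groups, kinds) if p in g]
        if not in_groups:
            status[p] = STATUS_IDENTIFIABLE
        elif "structural" in in_groups:
            status[p] = STATUS_STRUCTURAL
        else:
            status[p] = STATUS_PRACTICAL
    n_max = max((len(g) for g in groups), default=0)
    epd = _equations_per_dataset(model, groups, degree_bound)
    observed = (
        numeric_rank(system.evaluate(system.random_assignment(rng)))
        if system.rows
        else 0
    )
    any_practical = any(k == "practical" for k in kinds)
    n_d = ceil(n_max / epd) if (any_practical and epd > 0) else 0
    return IdentifiabilityReport(
        param_order=params,
        status=status,
        groups=tuple(groups),
        group_kinds=tuple(kinds),
        basis=tuple(b1),
        n_max=n_max,
        equations_per_dataset=epd,
        observed_independent_rows=observed,
        n_d=n_d,
        degree_bound=degree_bound,
        condition_substituted=True,
    )


def analyze_condition(
    model: LinearModel,
    cond: ExperimentCondition,
    *,
    input_mode: str = "step",
    seed: int = DEFAULT_SEED,
    max_symbols_exact: int = MAX_SYMBOLS_EXACT,
):
    """Full correlation analysis under one experiment condition.

    The condition is first made generic (nonzero entries become symbols);
    returns ``(columns, system, report)``.  Systems whose total symbol
    count stays within ``max_symbols_exact`` are solved fully symbolically;
    larger ones go through the exact two-draw rational-condition path.
    """
    gcond = cond.generic(model)
    cols = sensitivity_columns(model, gcond, input_mode)
    system = coefficient_system(cols)
    all_syms = set()
    for row in system.rows:
        for e in row:
            all_syms |= e.free_symbols
    if len(all_syms) <= max_symbols_exact:
        basis = nullspace_basis(system)
        report = classify(
            model, gcond, basis, system=system,
            degree_bound=cols.degree_bound, seed=seed,
        )
    else:
        report = _classify_by_draws(model, gcond, system, cols.degree_bound, seed)
    return cols, system, report


def required_datasets(report: IdentifiabilityReport) -> int:
    """ceil(n_max / equations-per-dataset) when any group is practical, else 0."""
    if any(k == "practical" for k in report.group_kinds) and report.equations_per_dataset:
        return ceil(report.n_max / report.equations_per_dataset)
    return 0


def minimal_datasets(
    model: LinearModel,
    cond: ExperimentCondition,
    *,
    input_mode: str = "step",
    seed: int = DEFAULT_SEED,
) -> int:
    """Minimal number of datasets (from suitably different, fully nonzero
    conditions) needed for unique estimation of the parameters that the
    analysis under ``cond`` finds correlated.

    The base-condition analysis supplies n_max and the equation count; a
    group counts as remediable if enriching the condition (every x0 and u0
    entry generic nonzero) either removes its correlation outright or turns
    it condition-dependent.  Returns 0 when nothing is remediable (either
    no correlation at all, or a correlation that persists, condition-
    independent, even under the enriched condition -- truly structural).
    """
    _, _, base = analyze_condition(model, cond, input_mode=input_mode, seed=seed)
    if not base.groups:
        return 0
    if any(k == "practical" for k in base.group_kinds):
        return required_datasets(base)
    # structural under the base condition: check whether a richer condition
    # (everything switched on) breaks the correlation
    rich = ExperimentCondition(
        tuple(1 for _ in range(model.n_x)),
        tuple(1 for _ in range(model.n_u)),
    )
    _, _, rich_rep = analyze_condition(model, rich, input_mode=input_mode, seed=seed)
    rich_supports = [frozenset(g) for g in rich_rep.groups]
    remediable_sizes = []
    for g, k in zip(base.groups, base.group_kinds):
        persists_structurally = any(
            g <= rg and rk == "structural"
            for rg, rk in zip(rich_supports, rich_rep.group_kinds)
        )
        if not persists_structurally:
            remediable_sizes.append(len(g))
    if not remediable_sizes:
        return 0
    epd = base.equations_per_dataset
    return max(1, ceil(max(remediable_sizes) / epd)) if epd else 1


def stacked_rank_check(
    model: LinearModel,
    conditions: list[ExperimentCondition],
    group,
    seed: int = DEFAULT_SEED,
    *,
    input_mode: str = "step",
    n_s_points: int | None = None,
) -> tuple[int, bool]:
    """Numeric rank of the stacked multi-dataset sensitivity matrix Q(s)
    restricted to a correlated group's columns.

    One block of rows per condition (symbolic entries drawn uniform on
    [0.5, 2.0], zeros kept), evaluated at random s points; full rank of the
    stack means the listed conditions jointly pin down the group.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    group = [p if isinstance(p, sp.Symbol) else sp.Symbol(str(p)) for p in group]
    if not group:
        raise ValueError("group must be nonempty")
    idx = [model.params.index(p) for p in group]
    rng = np.random.default_rng(seed)
    pvals = {p: float(rng.uniform(0.5, 2.0)) for p in model.params}
    blocks = []
    for cond in conditions:
        ncond = cond.randomize(rng)
        cols = sensitivity_columns(model, ncond, input_mode)
        if n_s_points is None:
            n_pts = cols.degree_bound + 2
        else:
            n_pts = n_s_points
        svals = rng.uniform(0.5, 2.0, size=n_pts)
        funcs = [
            [sp.lambdify(s, col[i].subs(pvals), "numpy") for i in range(cols.n_y)]
            for col in (cols.columns[j] for j in idx)
        ]
        rows = []
        for sv in svals:
            for i in range(cols.n_y):
                rows.append([funcs[c][i](sv) for c in range(len(idx))])
        blocks.append(np.array(rows, dtype=float))
    Q = np.vstack(blocks)
    r = numeric_rank(Q)
    return r, r == len(group)
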