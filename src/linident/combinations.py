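"""Identifiable parameter combinations from a correlation nullspace.

A function phi(p) of correlated parameters is fixed by the data exactly
when its directional derivative along every correlation direction alpha
vanishes:

    sum_j alpha_j(p) * d(phi)/d(p_j) = 0   for every nullspace vector alpha.

This first-order linear PDE is solved with a polynomial ansatz: phi is a
generic linear combination of all monomials up to a chosen degree in the
correlated group's parameters, the invariance condition is cleared of the
alpha denominators and collected over the polynomial ring, and the
resulting exact linear system in the ansatz coefficients is solved over
the rationals.  All textbook combinations for compartment models are
polynomial of low degree, so the ansatz is exact and deterministic; the
price is that non-polynomial invariants are out of reach by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .correlation import DEFAULT_SEED, NullspaceVector, numeric_rank

__all__ = [
    "IdentifiableCombination",
    "invariance_residual",
    "find_combinations",
    "GroupTooLargeError",
]


class GroupTooLargeError(ValueError):
    """The monomial ansatz would exceed the configured cap; raise the cap
    or lower the degree."""


@dataclass(frozen=True)
class IdentifiableCombination:
    """A polynomial of correlated parameters whose value the data pin down."""

    expression: sp.Expr
    group: frozenset
    degree: int

    def __str__(self):
        return str(self.expression)


def _vector_field(vec: NullspaceVector, params):
    """(cleared alpha entries, clearing factor): multiply the rational
    alpha entries by the lcm of their denominators so the invariance
    condition becomes a polynomial identity."""
    entries = [sp.cancel(e) for e in vec.entries]
    dens = [sp.fraction(e)[1] for e in entries]
    L = sp.Integer(1)
    for d in dens:
        L = sp.lcm(L, d)
    cleared = [sp.expand(sp.cancel(e * L)) for e in entries]
    return cleared, L


def invariance_residual(phi: sp.Expr, basis, params) -> list[sp.Expr]:
    """Directional derivatives of phi along each basis vector (simplified).

    ``params`` fixes the position -> symbol correspondence of the vectors.
    An all-zero list certifies phi as an identifiable combination.
    """
    phi = sp.sympify(phi)
    extra = phi.free_symbols - set(params)
    if extra:
        raise ValueError(f"phi contains non-parameters {sorted(extra, key=str)}")
    out = []
    for vec in basis:
        d = sum(e * phi.diff(p) for e, p in zip(vec.entries, params))
        out.append(sp.cancel(sp.together(d)))
    return out


def _components(basis, params):
    """Connected components of overlapping supports, as ordered param tuples."""
    supports = [v.support for v in basis]
    comps: list[set] = []
    for sup in supports:
        touching = [c for c in comps if c & sup]
        merged = set(sup).union(*touching) if touching else set(sup)
        comps = [c for c in comps if not (c & sup)] + [merged]
    out = []
    for c in comps:
        out.append(tuple(p for j, p in enumerate(params) if j in c))
    out.sort(key=lambda t: min(params.index(p) for p in t))
    return out


def _monomials(group, max_degree):
    """Monomials of total degree 1..max_degree, sorted by (degree, lex)."""
    monos = sorted(
        (m for m in sp.polys.monomials.itermonomials(group, max_degree) if m != 1),
        key=lambda m: (sp.Poly(m, *group).total_degree(), str(m)),
    )
    return monos


def _candidate_polys(basis_vectors, group, all_params, max_degree, cap):
    """Solve the cleared invariance condition with a generic polynomial
    ansatz; return candidate invariant polynomials (canonicalized)."""
    monos = _monomials(group, max_degree)
    if len(monos) > cap:
        raise GroupTooLargeError(
            f"{len(monos)} monomials for group of {len(group)} at degree "
            f"{max_degree} exceeds cap {cap}; raise the cap or lower the degree"
        )
    rows_per_vec = []
    for vec in basis_vectors:
        cleared, _ = _vector_field(vec, all_params)
        residuals = []
        for mono in monos:
            r = sum(
                e * mono.diff(p) for e, p in zip(cleared, all_params) if e != 0
            )
            residuals.append(sp.expand(r))
        # collect the polynomial identity over all parameter monomials
        psyms = sorted(
            set().union(*(r.free_symbols for r in residuals)) | set(group), key=str
        )
        polys = [sp.Poly(r, *psyms) for r in residuals]
        all_pmonos = sorted({mm for pl in polys for mm in pl.monoms()})
        for pm in all_pmonos:
            rows_per_vec.append(
                [sp.Rational(pl.coeff_monomial(pm)) for pl in polys]
            )
    M = sp.Matrix(rows_per_vec)
    null = M.nullspace()
    candidates = []
    for v in null:
        poly = sp.expand(sum(c * m for c, m in zip(v, monos)))
        if poly == 0:
            continue
        # clear rational content, fix sign
        p = sp.Poly(poly, *group)
        dens = [sp.Integer(sp.fraction(c)[1]) for c in p.coeffs()]
        denlcm = sp.Integer(1)
        for d in dens:
            denlcm = sp.ilcm(denlcm, d)
        p = sp.Poly(poly * denlcm, *group)
        content = sp.Integer(0)
        for cfs in p.coeffs():
            content = sp.igcd(content, int(cfs))
        poly = sp.expand(poly * denlcm / content)
        if sp.Poly(poly, *group).coeffs()[0] < 0:
            poly = -poly
        candidates.append(poly)
    return candidates


def _jacobian_ranks(polys, group, seed, n_points=2):
    """Rank of the functions' Jacobian at each of several random points.

    Functional independence of the set <=> full rank at a generic point,
    so a dependent candidate never raises the rank at any point (testing
    per point matters: stacking points would let phi and phi**2 look
    independent).
    """
    rng = np.random.default_rng(seed)
    grads = [[sp.lambdify(group, sp.diff(q, p), "numpy") for p in group] for q in polys]
    ranks = []
    for _ in range(n_points):
        pt = rng.uniform(0.5, 2.0, size=len(group))
        J = np.array([[float(f(*pt)) for f in g] for g in grads])
        ranks.append(numeric_rank(J, rtol=1e-9))
    return ranks


def find_combinations(
    basis,
    params,
    max_degree: int = 3,
    *,
    monomial_cap: int = 500,
    seed: int = DEFAULT_SEED,
) -> list[IdentifiableCombination]:
    """Canonical set of identifiable combinations for each correlated group.

    For a group of k parameters constrained by r independent correlation
    relations there are k - r functionally independent invariants; the
    solution space of the ansatz is reduced to such a set by preferring
    lowest total degree, then fewest terms, then lexicographic order, and
    discarding candidates that are functionally dependent (numeric
    Jacobian rank) on those already selected.
    """
    if not 1 <= max_degree <= 4:
        raise ValueError("max_degree must be in 1..4")
    params = tuple(params)
    out = []
    for group in _components(basis, params):
        gset = set(group)
        vecs = [v for v in basis if {params[j] for j in v.support} & gset]
        target = len(group) - len(vecs)
        if target <= 0:
            continue
        candidates = _candidate_polys(vecs, group, params, max_degree, monomial_cap)
        candidates.sort(
            key=lambda q: (
                sp.Poly(q, *group).total_degree(),
                len(sp.Add.make_args(q)),
                str(q),
            )
        )
        selected = []
        for cand in candidates:
            if len(selected) == target:
                break
            trial = selected + [cand]
            if all(r == len(trial) for r in _jacobian_ranks(trial, group, seed)):
                selected.append(cand)
        for poly in selected:
            res = invariance_residual(poly, vecs, params)
            if any(r != 0 for r in res):  # defensive; ansatz solutions are exact
                continue
            out.append(
                IdentifiableCombination(
                    expression=poly,
                    group=frozenset(gset),
                    degree=int(sp.Poly(poly, *group).total_degree()),
                )
            )
    return out
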