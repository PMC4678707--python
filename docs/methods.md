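# Methods

## The model class and the question

`linident` analyzes time-invariant linear state-space models

    dx/dt = A x + B u,    x(0) = x0
        y = C x + D u

whose matrix entries are expressions in unknown rate parameters
p = (p_A, p_B, p_C, p_D), observed through n_y ≤ n_x output mixtures.
The controls u are constant during an experiment and, together with x0,
are chosen by experimental design.  The question is whether noise-free,
continuous records of y determine the parameters uniquely, and when they
do not, *which* parameters compensate for one another, whether the
compensation can be broken by a different experiment, and what functions
of the parameters the data do pin down.

## Output sensitivity columns in the Laplace domain

The state transform is X(s) = (sI − A)⁻¹(B U(s) + x0) with U_i(s) =
u0_i/s for step inputs.  The derivative of the output transform with
respect to one parameter is

    ∂Y/∂p = C (sI−A)⁻¹ [(∂A/∂p) X + (∂B/∂p) U] + (∂C/∂p) X + (∂D/∂p) U.

Computing (sI−A)⁻¹ as adjugate/Δ with Δ = det(sI−A) keeps every entry
polynomial; all n_p sensitivity vectors are put over the common
denominator s^m Δ² (m = 1 when a step input is active).  Any polynomial
factor shared by *every* entry of every column — typically the excitation
factor (u0 + s·x10) or an isolated mode (s + p) — is divided out, because
linear dependence of the columns is invariant under common nonzero
scaling.  A parameter whose column is identically zero never reaches the
output under this condition and is trivially non-identifiable.

Two input conventions are implemented: `step` (U = u0/s, what the
experiment applies) and `generic` (U a free constant symbol, the common
notational convention).  They give identical verdicts on all fixtures,
and a test asserts this.

## The coefficient system and its nullspace

A dependence Σ_j α_j q_j(s) ≡ 0 must hold coefficient-by-coefficient in
s, giving a homogeneous linear system β·α = 0 whose entries are
polynomial in the parameters and the condition symbols.  The right
nullspace over the field of rational functions is computed exactly with
sympy's sparse linear solver over the polynomial ring
(`solve_lin_sys`), with deterministic pivoting in parameter order;
vectors are normalized to leading entry 1.  The supports of the
canonical basis are the correlated groups.

Systems carrying more than 8 distinct symbols are classified
numerically instead (exact elimination cost grows steeply with the
symbol count): parameters are fixed at one seeded random draw, the
condition symbols at two independent draws, and the canonical numeric
nullspace (SVD followed by row-echelon reduction of the nullspace rows,
zero threshold 1e-8 relative) is compared across the draws.  Supports
are additionally certified against a second parameter draw.  All
structural verdicts on the built-in fixtures fall in the exact-symbolic
regime; the numeric path serves the enriched "remedy" conditions, whose
basis entries are condition-specific by nature.  Reports carry a
`condition_substituted` flag when this path was taken.

## Structural versus practical

The analysis condition is the *generic* version of the requested one:
zero entries stay zero, nonzero entries become free symbols — only the
zero pattern matters symbolically.  A correlation relation is
*structural* when its basis vector, after cancellation, contains no
condition symbols and is numerically unchanged between two independent
re-draws of the condition symbols (the re-draw guards against
unsimplified-but-cancelling terms); it is *practical* when the relation
itself depends on the condition, so datasets from different conditions
constrain different directions and stacking enough of them forces
α = 0.  A parameter is identifiable exactly when it lies in no group.

One caution this package surfaces explicitly: "structural" is relative
to the zero pattern analyzed.  A relation whose coefficients contain no
condition symbols can still disappear under a condition with *more*
nonzero entries (the four-compartment fixture behaves this way), which
is why remediability is decided by re-analysis under the enriched
condition rather than by the label alone.

## Dataset counting

Per dataset the printed bookkeeping convention supplies
`equations_per_dataset`: n_y(2n_x − 2) when every correlated parameter
lives in A only, n_y(2n_x + 1) when all four matrices carry parameters,
n_y(degree_bound + 1) otherwise.  The observed independent row count of
β (which can differ from the convention by one) is stored alongside.
For a report with practical groups, n_d = ceil(n_max /
equations_per_dataset) with n_max the largest group.  `minimal_datasets`
answers the design question "how many datasets from fully-exciting
conditions remedy what this condition cannot see": it takes n_max over
the base-condition groups that an enriched condition (every x0 and u0
entry nonzero) either removes or turns condition-dependent, and divides
by the same equation count (minimum 1).  `stacked_rank_check` verifies a
proposed set of conditions numerically by evaluating the stacked
multi-dataset column matrix at random parameter and s values.

## Identifiable combinations

A function φ(p) is fixed by the data when Σ_j α_j ∂φ/∂p_j = 0 for every
basis vector α.  The solver uses a polynomial ansatz: all monomials of
total degree 1..max_degree (default 3, cap 500 monomials) in the
correlated group's parameters, the invariance condition cleared of the
α denominators and collected over the parameter monomials, and the
resulting exact rational linear system solved for the coefficient
space.  Candidates are canonicalized (integer content removed, leading
coefficient positive), ordered by total degree, then term count, then
lexicographically, and selected greedily while the Jacobian of the
selected set keeps full rank at two random points — the per-point rank
test is what rejects φ² or products of already-selected invariants.
For a group of k parameters bound by r independent relations the
selection stops at k − r combinations.

Limitations by construction: only polynomial invariants in the group's
own parameters are searched.  Invariants that mix in identifiable
parameters exist (for the two-compartment model with the second state
excited, the second functional invariant involves the identifiable p3)
and are deliberately out of scope, as are non-polynomial invariants.

## Simulation, fitting, scans

Simulation is exact: the constant-input system is embedded in the
augmented homogeneous matrix [[A, B u0], [0, 0]] and propagated with one
matrix exponential per distinct time step.  Fits minimize the stacked
squared output residuals over all datasets with scipy's trust-region
reflective least squares, bounds (1e-6, 1e3), tolerances 1e-12, one
user-supplied start (default all ones) plus four log-uniform [0.1, 10]
multistarts (seed 20151214 by default; every random draw in the package
is seeded and uniform on [0.5, 2.0] unless stated).  Correlation scans
fix one parameter of a correlated group at a grid of values, refit the
rest warm-started from the previous row, and certify each row by its
residual (noise-free data must fit to ~1e-10 or the row is meaningless).
Along such a scan every identifiable combination is constant while the
individual parameters drift — this is the numerical validation of the
symbolic verdicts.

The scan grids respect the *real positive* section of the correlation
manifold, which is bounded: for the two-compartment model p4 =
1.4 − 0.7/(1.4 − p1) forces p1 < 0.9, and for the four-compartment model
the (p42, p04) sum/product pair loses real roots below p43 ≈ 3.26.
Default grids: two-compartment 100 points on [0, 10], sweep p1 in
[0.05, 0.85] (case 2: [0.5, 0.9]); mammillary three-compartment 400
points on [0, 2] (its fixture's published protocol), sweep p21 in
[0.7, 1.5]; four-compartment 200 points on [0, 5], sweep p43 in
[3.4, 4.8].  Scan lengths in the shipped tests and the acceptance script
are 5–10 rows; the constants they measure are flat to ~1e-12, so row
count does not limit precision.

Identifiability from a single output is *local*: the coefficient map has
finite fibers, so discrete mirror solutions can coexist with the true
one (the receptor model's surface output is invariant under swapping
p54 and p15; the mammillary model's sum/product pair gives the
two-branch phenomenon where (p02+p12, p03+p13) can exchange values).
Recovery tests therefore start fits on the true branch (a ±5%
perturbation of the truth); global multistart fits may legitimately land
on a mirror branch with machine-zero residual.

## The independent oracle

`finite_difference_sensitivity_rank` stacks central-difference output
sensitivities (relative step 1e-6) from exact simulations over a time
grid and takes the numeric rank (threshold 1e-8 relative, looser than
the 1e-10 used on symbolically evaluated matrices because the
differencing itself carries O(step²) error).  It shares nothing with the
Laplace pipeline — no adjugates, no coefficient extraction — and the
test suite asserts rank = n_p − dim(nullspace) on all fixtures and on
seeded random compartment models.  During development a second
independent route (the Jacobian of the transfer-function coefficient
map) was used to adjudicate fixture results; the suite keeps the
finite-difference oracle.

## Fixtures and what the random generator does not emulate

The five built-in fixtures are the classic benchmark compartment models
(two-compartment exchange observed through x1/V; a three-compartment
chain observed at x2, the known failure case of differential-algebra
testers at x30 = 0; a mammillary three-compartment model; a
four-compartment model with two observed pools; and a five-compartment
insulin-receptor trafficking model whose bilinear insulin-binding term
p21·u is absorbed into the single rate p21p at constant input).
Published true values are attached where they exist (fixtures 1, 3, 4);
the receptor and chain fixtures carry none, and tests draw synthetic
positive rates for them.  One printed relation for the receptor model
was found to be inconsistent with its own model equations (its p15
terms); the package reports the relation its method derives, which the
exact time-domain oracle confirms to machine precision, and likewise
reports the internalization output y2 as leaving four rates correlated
— the same relation as the phosphorylation output — which both the
finite-difference and coefficient-map oracles confirm.

`random_model` generates compartment-style models: random transfer
edges with one rate each, a leak per compartment, C selecting observed
states, rates uniform on [0.5, 2.0].  It emulates sparse mass-exchange
topology only — no time-varying inputs, no measurement scaling
parameters, no stiffness extremes, no conservation constraints beyond
what the topology implies.  Passing the oracle-agreement tests on these
models therefore certifies the symbolic pipeline's correctness on
generic compartment structure, not performance on noisy or partially
sampled real data; the method itself is a noise-free, continuous-data
necessary-condition analysis by construction.

## Numerical choices (summary)

- Rank threshold: singular values < 1e-10 × largest are zero (1e-8 for
  finite-difference matrices).
- Random draws: uniform [0.5, 2.0], default seed 20151214.
- Symbolic-vs-numeric nullspace switch: 8 distinct symbols.
- Nullspace pivoting: parameter order; vectors normalized to leading 1;
  ties in candidate combinations broken by (degree, term count, string).
- Degenerate input (x0 = 0, u = 0) raises `AllColumnsZeroError`; the CLI
  maps it to exit code 3, schema violations to exit code 2.
- Fit: trf, bounds (1e-6, 1e3), xtol = ftol = gtol = 1e-12, 5 starts.
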