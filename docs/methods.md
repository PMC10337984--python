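# Methods

## Model

Two players repeat the donation game: cooperation costs the donor *c* and
gives the recipient *b*, with *b* > *c* > 0, so one-round payoffs are
(R, S, T, P) = (b−c, −c, b, 0).  This matrix satisfies equal gains from
switching, R + P = T + S, the structural condition behind the time-reversal
duality used throughout.  A memory-one strategy
**p** = (p_CC, p_CD, p_DC, p_DD) fixes the cooperation probability after
each joint outcome of the previous round (focal player's move first).  Play
between **p** and **p′** is a Markov chain over the four outcomes; for
interior strategies it has a unique stationary distribution **v**, and the
long-run payoff is A(**p**, **p′**) = R·v_CC + S·v_CD + T·v_DC + P·v_DD.

The engine computes **v** by solving the linear system (Mᵀ − I)v = 0 with a
normalisation row appended (least squares on the stacked 5×4 system), and
A(**p**, **p′**) by the Press–Dyson determinant quotient.  Uniqueness is
checked through the singular values of Mᵀ − I; reducible or periodic pairs
(deterministic corners such as tit-for-tat against itself) raise
`NonUniqueStationaryError` / `DegenerateChainError`.  An explicit
`perturb=ε` option (default 1e-9 when used) replaces deterministic entries
by ε / 1−ε and is documented as a one-sided limit approximation — a
convention of this package, since the underlying model leaves such corner
payoffs undefined.  Memory-n strategies (n ≤ 4 by default) use the same
machinery on the 4ⁿ histories, with a power-iteration fallback.

## Adaptive dynamics and the polynomial fields

Adaptive dynamics moves a homogeneous resident along the invader-payoff
gradient, ṗᵢⱼ = ∂A(**p′**, **p**)/∂p′ᵢⱼ at **p′** = **p**.  Multiplying by
(1 − p_CD + p_DC)·r(**p**)², a factor positive on the open cube, gives a
polynomial field whose components factor as fᵢ·(b·gᵢ + c·hᵢ); the i = 3, 4
auxiliary polynomials are argument-reversal substitutions of the i = 1, 2
ones.  The production field is this rescaled polynomial: it has the same
orbits as the raw gradient in the interior (only the timescale changes) and
is total on the closed cube, which the boundary analysis and the grid
censuses require.  The raw central-difference gradient of the determinant
payoff (step 1e-6) serves as an independent oracle in the tests; the two
agree componentwise to ~1e-8 relative and in sign on thousands of seeded
points.

One substitution identity for the ṗ_DD component is implemented as
g₄(x,y,z,w) = g₁(1−w, 1−z, 1−y, 1−x) — the same argument pattern as h₄.
This is the form the gradient oracle verifies; with the middle arguments
exchanged the ṗ_DD component is wrong everywhere, and the structural
duality below would fail.

Counting strategies (p_CD = p_DC, written **q** = (q₂, q₁, q₀)) form an
invariant subspace; the closed form for d/dt (p_CD − p_DC) vanishes
identically on it.  The 3-cube of counting strategies carries its own
adaptive dynamics with the gradient taken in three variables (the middle
component doubles relative to the embedded four-variable gradient, because
the embedding is not distance-preserving); the rescaled counting field uses
its own r(**q**)², nonzero on the open cube.

**Duality.**  σ(**p**) = (1−p_DD, 1−p_DC, 1−p_CD, 1−p_CC) is an involution
whose derivative is minus the component reversal.  The field satisfies
F(σ**p**) = reversed F(**p**) exactly (it is the same polynomial expression
term by term), so σ conjugates the forward flow to the backward flow:
orbits come in forward/backward pairs, and sign-census tallies mirror
(count of pattern *abcd* = count of *dcba*).

**Critical points and equalizers.**  Interior rest points form the plane
b(p_CC − p_CD) = c(1 − p_CC + p_DC), p_CC + p_DD = p_CD + p_DC; solving
gives p_CC = (c + b·p_CD + c·p_DC)/(b+c), p_DD = (c(p_CD−1) + b·p_DC)/(b+c),
with the bounds p_CC > c/b and p_DD < 1 − c/b.  These points coincide with
the equalizer strategies — strategies that pin every opponent to the same
payoff — and the tests verify constancy over 100 random opponents to 1e-8.
For counting strategies the critical set is the straight line
(t + c/(b+c), t, t − c/(b+c)), t ∈ (c/(b+c), b/(b+c)), of length
√3·(b−c)/(b+c).

**Linearisation of the counting field.**  The Jacobian is assembled from
hand-coded analytic partials of the auxiliary polynomials (product rule,
chain rule through the substitutions) and checked against finite
differences.  Because the critical line is a continuum of equilibria, one
eigenvalue is structurally zero (the line direction); classification uses
the two transverse eigenvalues: source / spiral source / sink / spiral sink
/ saddle, with "non-hyperbolic" reported when a transverse real part falls
below 1e-10.  All five generic types occur across cost values, and σ maps
the type at line parameter t to the time-reversed type at 1 − t.

**Boundary.**  The boundary proper is the set of points with exactly one
coordinate in {0, 1}.  A face point is saturated when the field does not
point into the interior.  On the face p_CC = 1 the tangential components
vanish identically and saturation reduces to a quotient of two polynomials
in (p_CD, p_DC, p_DD) exceeding c/b; the package evaluates it
cross-multiplied (fraction-free), reporting the 0/0 locus (e.g. the
tit-for-tat tail) as "degenerate".  The cooperative Nash set on that face —
(1−p_CD)/p_DD ≥ c/(b−c) and (1−p_CD)/p_DC ≥ c/b, also cross-multiplied —
is a strict subset of the saturated set.  On the counting faces q₂ = 1 and
q₀ = 0 the tangential components vanish too; boundary critical curves are
resolved by sign-change bisection of the normal component along grid lines,
and the edge q₂ = 1 ∧ q₀ = 0 is critical in its entirety (GRIM = (1,0,0)
sits on it).

## Trajectories and endpoint classes

Dynamics cease at the boundary of the cube.  The integrator is a vectorised
adaptive Dormand–Prince RK45 (rtol 1e-8, atol 1e-10, step cap 100) over a
batch of starts; a step that lands within `boundary_tol` = 1e-6 of a face
is re-taken with halved steps until the first true crossing is localised.
Interior convergence is declared when the field max-norm stays below
`conv_tol` = 1e-10 for 50 consecutive accepted steps.  Trajectories still
moving at t = 1e4 rescaled units — typically orbits crawling along the
critical line, where the transverse rate can be ~1e-4 — are finished with
stiff LSODA (events on boundary contact and field norm) up to t = 1e8.
Endpoint classes, in tie-break order: `full_cooperation` (first coordinate
at 1), `full_defection` (last coordinate at 0), `other_boundary`,
`interior_critical` (converged in the open cube, or satisfying the critical
conditions at 1e-5 at the cap), else `undecided`.  The cooperation rate
C(**p**) = A(**p**,**p**)/(b−c) = v_CC + (v_CD + v_DC)/2 is evaluated along
paths with an ε-perturbation at exact corners.

Starting points on a face cease immediately unless the field at a
2·`boundary_tol` inward nudge points strictly into the cube at every
extreme coordinate (the tangential components vanish *on* the invariant
faces, so the test must be made just inside).

## Grid censuses

All censuses use an evenly spaced **interior** grid, coordinates k/(n+1)
for k = 1..n per axis (n = 9 gives 0.1, …, 0.9 and 6561 / 729 points).
Interior placement is forced by the structure of the field: on each face
several components vanish identically, so an endpoint-inclusive grid would
report thousands of zero sign components and would start trajectories where
dynamics have already ceased; the interior grid reproduces the known
directional tallies exactly.

Sign classification is exact: any component below 1e-12 in floating point
is re-evaluated in rational arithmetic (`fractions.Fraction`, with grid
coordinates and b, c carried exactly), and '0' is assigned only to true
zeros.  On the reference grid this resolves 8 all-zero points and 10 points
with some but not all components zero; floating-point evaluation at
decimal-fraction coordinates would otherwise mis-assign those by rounding
noise.  The "forbidden" sign combinations (ṗ_CC < 0 with ṗ_DC > 0;
ṗ_DD < 0 with ṗ_CD > 0; rising q₁ with falling q₂ or q₀) are absent on the
census grids; they are *not* universal on the open cube — thin regions
(~0.1% of uniform samples) violate them, with the finite-difference
gradient agreeing in sign, so the tests assert grid-level absence only.

The cooperative-region census classifies each grid point by the sign of the
directional derivative of C along the field — the inner product of the
field with the central-difference gradient (step 1e-6) of C — with the 8
exact rest points reported as "critical".  This quantity satisfies
C(σ**p**) = 1 − C(**p**) and Ċ(σ**p**) = Ċ(**p**), identities the tests
verify; the reactive-strategy slice (p_CC = p_DC, p_CD = p_DD) reduces to
the classical rule "cooperativity rises iff p_C − p_D > c/b".

### Convention sensitivity of the endpoint censuses

The endpoint tallies depend on conventions that any census must fix: the
cease threshold at the boundary, the convergence test near the critical
set, and the time horizon.  The defaults above were chosen so that the
counts are stable — they are unchanged under halving all tolerances and
under tightening the integrator by three orders of magnitude, and the batch
integrator agrees with an independent high-accuracy solver on sampled
endpoints.  Finite-horizon variants are *not* stable: orbits shed slowly by
the spiralling regions of the critical plane migrate between the
"interior critical" and the boundary classes as the horizon grows, so a
census read off at a fixed time reflects that choice of time.  The package
deliberately reports the converged-limit census.

## What the tests show, and limits

The test suite exercises exact engine identities (determinant vs stationary
payoffs, memory-n consistency, equalizer constancy, subspace invariances
for general 2×2 payoffs and memory-2), the structural field identities
(rescale, duality, mirror tallies), the critical-set geometry, the
eigenvalue taxonomy with its sink/source duality, the qualitative
cooperation-rate behaviors of four showcase counting orbits, and the
censuses.  All inputs are synthetic by construction — the model is
self-contained game theory with no external data — so passing tests
certify the mathematics and the numerics, not any empirical claim about
behavior.

Known limitations: payoffs at degenerate deterministic corners exist only
as ε-limits; the closed-form polynomial fields are specific to the donation
game (general (R,S,T,P) games are served by the numeric gradient only);
discounted or finitely repeated games, observation noise, and
finite-population stochastic dynamics are out of scope; eigenvalues of the
critical line are computed numerically, with no closed form; and basin
boundaries near the spiralling critical sets are resolved only to the
stated tolerances, so individual marginal starting points (as opposed to
the stable aggregate counts) can be sensitive to the integration settings.
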