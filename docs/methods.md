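# Methods

## Model

`parsimix` fits a `k`-component Gaussian mixture to an `n x p` data matrix by
maximum likelihood, either of the mixture log-likelihood

    L_mix(theta) = sum_i log sum_j pi_j phi(x_i; mu_j, Sigma_j)        (EM)

or of the classification log-likelihood of a hard partition {H_j}

    L_cla(theta) = sum_j sum_{i in H_j} log( pi_j phi(x_i; mu_j, Sigma_j) )   (CEM)

Both likelihoods are unbounded over unrestricted covariances (a component can
collapse onto a few near-collinear points), which produces spurious
high-likelihood solutions.  The package therefore constrains the component
covariances through their decomposition

    Sigma_j = d_j * R_j * diag(D_j) * R_j',      d_j = |Sigma_j|^(1/p),

with unit-determinant shape vector `D_j` and orthogonal rotation `R_j`, via
three constants (each >= 1, `inf` = unconstrained):

* `c_det`  — max_j |Sigma_j| / min_j |Sigma_j| <= c_det (relative volumes),
* `c_shw`  — max_l D_jl / min_l D_jl <= c_shw for every j (sphericity control
  within a component),
* `c_shb`  — max_j D_jl / min_j D_jl <= c_shb for every coordinate l
  (similarity of shapes across components),

plus a rotation regime `rot`: `I` (all rotations identity, axis-aligned
components), `E` (one common rotation), `V` (free rotations).  Under `V` the
shape elements are kept in non-increasing order; the shape-between constraint
and its feasibility bound are defined on these ordered elements.  Sending each
constant to 1 or infinity recovers the 14 classical parsimonious models
(EII ... VVV) as limit cases, and intermediate values interpolate smoothly
between them.

Because any within-ratio bound already limits how much ordered shape elements
can differ across components, `c_shb > c_shw^((p-1)/p)` can never bind; the
package clamps `c_shb` to this bound with a warning.  (The bound is a theorem
only for ordered shapes: unordered shapes can reach cross-ratios up to
`c_shw`.  The clamp is applied in every regime, matching the methodology's
convention.)

## Estimation: nested ECM

Each of `n_init` random starts draws `k (p+1)` observations, splits them into
`k` groups and uses the group means/covariances as `theta^(0)` (constraints
are *not* imposed on the initializer).  Each outer iteration then performs:

1. **E-step** — posterior responsibilities (EM) or one-hot argmax weights
   (CEM, ties to the lowest component index), computed in log space through
   Cholesky factors.
2. **Weights and means** — the closed-form weighted updates, giving component
   masses `n_j` and weighted scatter matrices `S_j`.
3. **Constrained scatter update** — volumes initialize at `|S_j|^(1/p)`
   (floored at `1e-12` of the mean per-coordinate variance when singular) and
   rotations per regime (eigenvectors of `S_j`; the identity; eigenvectors of
   the volume-standardized pooled scatter).  The update then cycles until the
   decomposition stabilizes:
   * **shape** — starting from the conditional maximizer
     `diag(R_j' S_j R_j)/d_j`, iterate: within-truncation (unit weights, per
     component) -> sort (regime `V`) -> between-truncation (weights `n_j`,
     per coordinate) -> unsort -> determinant normalization.  Normalizing
     *after* the truncations matters: the between-truncation objective is the
     exact conditional likelihood only when applied to the raw conditional
     maximizers, and only this order reproduces the classical pooled shape
     estimators exactly at the limit configurations.
   * **volume** — truncate the proxies `nu_j = tr(D_j^{-1} R_j' S_j R_j)/p`
     with weights `n_j` at `c_det^(1/p)`.
   * **rotation** (regime `E` only) — when all shapes are equal the exact
     conditional solution is the eigenbasis of `M = sum_j (n_j/n) S_j / d_j`
     (largest eigenvalues paired with largest shape elements); otherwise a
     majorization step: maximize `<R, G>` with
     `G = sum_j (omega_j I - W_j) R^(r-1) A_j`, `W_j = (n_j/n) S_j`,
     `omega_j = lambda_max(W_j)`, `A_j = d_j^{-1} D_j^{-1}`, solved by the
     SVD of `G` (`R = U V'`).  Each step cannot decrease the complete-data
     target.

All three constraint types are imposed by one primitive, the weighted optimal
truncation operator: clamp nonnegative values `v_j` with weights `n_j` into
`[t, c t]`, choosing `t` to minimize `f(t) = sum_j n_j [log m_t(v_j) +
v_j/m_t(v_j)]`.  The minimizer is found exactly from the finitely many
breakpoints `{v_j, v_j/c}` and the per-interval stationary value
`t = (sum_L n_j v_j + c^{-1} sum_U n_j v_j) / sum_{L u U} n_j`.

The truncation alternation is a heuristic, not an exact joint maximizer; near
convergence a fresh pass can land a hair worse than the previous iterate.  The
scatter update therefore keeps the previous (feasible) decomposition whenever
it has the better complete-data objective, which turns every outer iteration
into a monotone generalized-EM step.  The target sequence is non-decreasing
from the first constrained iterate onward (the random initializer itself may
be infeasible, so the very first transition can drop).

Convergence is monitored by relative parameter changes
`max_j ||vec(b_j^(h)) - vec(b_j^(h-1))|| / ||vec(b_j^(h-1))||` (zero-norm
previous values count as infinite change) and, for rotations,
`|p - trace[((R^(h))' R^(h-1))' (R^(h) (R^(h-1))')]| / p`.

### Defaults and degenerate cases

* `n_init = 50`, `max_iter = 100` outer iterations, 20 iterations for each
  nested loop, all relative tolerances `1e-6`.  (Large simulation studies in
  the field use up to 1000 starts; 50 is a practical default and every knob
  is exposed.)
* An empty or vanishing-mass component aborts that start; the fit reports how
  many starts survived and fails only if all degenerate.
* Zero shape/volume entries are clamped upward by the truncation operator
  whenever the relevant constant is finite; with infinite constants a
  `1e-12`-relative floor is applied (the fully unconstrained problem is
  unbounded).  A component whose scatter collapses entirely raises a
  degenerate-scatter error.
* Constraint satisfaction of a fit is certified by `check_constraints` at
  relative tolerance `1e-5` (the inner loops stop at relative changes of
  `1e-6`, so ratios can sit within that order of the cap; limit cases are
  exact).
* Two engines implement the identical inner loop: a numba-compiled fast path
  (default when numba is importable) and a pure-numpy reference; an
  equivalence test holds them together.

## Model selection

The criterion is `BIC[k, pars] = -2 L + v log n` (minimized), with

    v = kp + (k-1) + [(k-1)(1 - c_det^{-1/p}) + 1]
        + (p-1)(1 - 1/c_shw) [ (k-1)(1 - 1/c_shb) + 1 ]
        + k(rot) p(p-1)/2,       k(rot) = 0 / 1 / k  for I / E / V.

At the limit configurations `v` equals the free-parameter count of the
corresponding classical model; in between it grows continuously with the
allowed flexibility.  The criterion direction is arg min of `-2L + v log n`
throughout (the usual BIC orientation).  Search is two-phase:

1. fit every `k <= K` under each of the 14 limit patterns with infinity
   replaced by `2^(C-1)` (slightly constrained, so no configuration is
   numerically unbounded); the best row fixes `k*`, `rot*` and pins any
   constant that came out 1;
2. refine the remaining constants over powers of two up to their phase-1
   values (the shape-between axis also capped by `c_shw^((p-1)/p)`;
   infeasible triples are skipped), at fixed `k*` and `rot*`.  Phase-2 fits
   add the phase-1 winner's parameters as one extra start (this can only
   raise the maximized target), and a configuration identical to an already
   fitted one reuses that fit.  BIC ties break toward the smaller penalty,
   then the smaller `k`.

## Synthetic data

Two fixed designs emulate controlled benchmark conditions:

* **Design A** — three bivariate normals, means (0,0), (2,6), (6,0),
  covariances diag(2,2), diag(3,1), diag(1,2), sizes (50,20,20) (doubled in
  the `higher_n` variant), plus one (or two, `higher_p`) independent N(0,100)
  noise coordinates that make every component strongly elongated in an
  uninformative direction.
* **Design B** — six spherical bivariate components with printed means and
  sizes (23,36,93,38,123,12) plus one N(0,100) noise coordinate.  The source
  design states a common spherical in-plane scatter without a value; unit
  variance is used here, consistent with visibly separated clusters several
  units apart.

The **overlap-controlled generator** draws mixture parameters whose
covariances satisfy a requested constraint pattern exactly — volumes
log-uniform within the determinant band, shapes log-uniform then projected by
the same truncation machinery (kept in sorted order under free rotations),
rotations Haar-distributed (shared when the pattern requires) — with limit
patterns realized through the finite stand-ins 100 (`c_det`, `c_shw`) and 10
(`c_shb`).  Pairwise overlap between components j and l is the sum of the two
directed misclassification probabilities
`w_{j|l} = P[pi_l phi_l(X) < pi_j phi_j(X)]`, `X ~` component `l`, averaged
over the `k(k-1)/2` pairs; it is estimated by Monte Carlo (default 50 000
draws per component during calibration, standard error of the average well
under 0.002 at the 0.05 level).  Means are drawn on the unit hypercube and
rescaled about their centroid by bisection — with common random numbers
across candidate scales, so the overlap curve is smooth and monotone — until
the average overlap is within 0.005 of the target.  Mean scaling (rather than
covariance inflation) is the control knob because it preserves the covariance
pattern exactly.

What the generator does *not* emulate: non-Gaussian clusters, outliers or
heavy tails, unequal mixing weights in the overlap study, and exact-overlap
matching of specialized simulation suites (the bisection hits the average
overlap to a tolerance, not exactly).  Passing tests therefore certify the
estimation and selection machinery under correctly specified Gaussian
mixtures, not robustness to model misspecification.

## Problem sizes used in the checks

The test suite exercises: parameter recovery on Design A over 30 seeds with
10 random starts per fit; model selection on Design A (K=5, C=6, 50 starts)
over 10 seeds; 100 random EM/CEM runs (n <= 200, p <= 5, 3 starts) for
monotonicity and constraint satisfaction; the truncation operator against a
10^6-point grid oracle on 100 random tasks; and the overlap generator at
k=3, p=10 with 10^5 verification draws.  The acceptance script regenerates
the overlap calibration from scratch and reports the independently
re-estimated average overlap.

## Known limitations

* The nested truncation alternation maximizes each block conditionally; it is
  guaranteed monotone but, like every EM-type scheme, finds local maxima —
  hence multiple random starts.
* CEM with small components can abort starts (empty classes are not
  re-seeded; the affected start is discarded).
* The shape-between constraint under free rotations is defined on ordered
  shape elements; two components with identical but oppositely ordered axis
  variances count as having equal shapes.
* The overlap calibration is Monte-Carlo based; its tolerance (0.005) and
  draw counts trade accuracy for runtime and are configurable.
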