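# Methods

This note records the model, the numerical choices and the limits of what the
test suite establishes. It is the maintainer's account of *why* the package
is built the way it is; the README shows *how* to use it.

## Problem and discretization

We estimate parameters θ (and optionally initial conditions and instrument
offsets) of ż = g(z, θ, t) by minimizing the sum of squared residuals against
sampled observations. The dynamics are fully discretized by orthogonal
collocation on finite elements:

- **Nodes.** Inside each element, the state is a Lagrange polynomial on the
  support {0} ∪ {shifted Gauss–Legendre roots of degree NK}. Legendre (not
  Radau) roots are used; the τ=0 point carries the entering state and is not
  collocated. Node accuracy is that of `numpy.polynomial.legendre.leggauss`
  (≤ 1e-15).
- **Derivatives.** The basis derivative table ϕ̇ₖ(τ_q) comes from the
  analytic barycentric formula, not finite differences, so residual rows are
  bit-stable across runs.
- **Elements.** Equal length by default; explicit edges are accepted
  (`OaConfig.edges`). A stiff opening transient is best absorbed by one short
  first element — the shortened proteinase fixture uses
  (0, 2, 75, 150, 225, 300) s for exactly this reason.
- **Measurements.** A sampling time belongs to the element whose half-open
  interval [ηₑ, ηₑ₊₁) contains it; the right horizon endpoint is assigned to
  the last element at τ=1, so every admissible time has a home.

Equation counts per experiment: NE·NK·|J| residual, (NE−1)·|J| continuity,
|J| initial, |U|·|J_M| measurement rows. Experiments replicate coefficients
and share the global θ; free initial conditions and per-experiment offsets
enter the initial and measurement rows linearly, one variable per experiment.

## Canonical form and relaxation

Equations are decomposed recursively into a linear core plus registered
atoms. Design choices made where several routes exist:

- **Quotients** always take the bilinear transform (w = x/y becomes the
  product identity w·y = x); tailored fractional envelopes are not built —
  neither benchmark needs them.
- **Squares** are relaxed through the bilinear route x·x; only the objective
  residual squares are treated differently, by supporting hyper-planes.
- **Common subexpressions are shared** (one auxiliary per distinct atom), so
  the binaries of the piecewise relaxation scale with the number of distinct
  partitioned *variables*, not atoms. Sharing can be disabled
  (`share_common=False`) at the cost of a larger master.
- **Partitioned factor.** For parameter-state products the parameter is
  partitioned; for state-state products the alphabetically-first factor.
  All atoms of one partitioned variable share one segment grid and one set
  of binaries.
- **Active-segment linking.** The piecewise construction describes the
  binary as "active for the segment containing x"; we enforce that semantics
  explicitly with Σ edgeᴸ(n)λ(n) ≤ x ≤ Σ edgeᴿ(n)λ(n). Without the linking
  rows the formulation is still valid but no tighter than intended.
- **Interval boxes.** Auxiliary boxes come from natural interval extension;
  they inherit its dependency-effect overestimation, which only loosens (never
  invalidates) the relaxation. Unbounded variables reachable from a nonlinear
  atom are rejected up front.
- **Hyper-plane anchors** are spread uniformly over each residual's interval
  box; the anchor at zero is always included so the epigraph variables are
  explicitly nonnegative, making every lower bound trivially ≥ 0 for
  least-squares objectives.

## Solver backends and rigor

- The master is solved by HiGHS through `scipy.optimize.milp` / `linprog`.
  The lower bound is the solver's **proven dual bound**, never the incumbent
  objective, so a time-capped master cannot produce an invalid LB. For pure
  LP masters the optimum at optimal status is itself the proven bound.
- The local (upper-bound) stage eliminates the collocation coefficients:
  the square residual/continuity/initial system is solved by per-element
  damped Newton marching (a single step for models linear in the states),
  and the remaining degrees of freedom are fitted by bounded trust-region
  least squares. Any returned point satisfies the transcription to Newton
  tolerance (1e-12 relative), so its SSE is a valid upper bound.
- OBBT minimizes/maximizes each target variable over the master's **LP
  relaxation** (binaries in [0, 1]) — valid regardless of how the binaries
  would resolve — iterated `obbt_rounds` times (default 3) so contractions
  propagate. The objective cut Σα ≤ UB₀ from the initial multistart solve is
  included, which is the standard incumbent-aware OBBT.
- Temporal strengthening cuts: a window-restricted sub-master (continuity
  into the window's first element removed, initial row kept only if element 1
  is inside) bounds that window's partial SSE from below; the bound is added
  as a row over the full master's epigraph variables.
- Gap: OG = |UB − LB| / |UB|, measured absolutely once |UB| < 1e-12 —
  otherwise a perfect zero-residual fit could never "converge" relatively.
- Refinement: hyper-planes are added at the master's residual values;
  segment bisection splits the active segment at its midpoint. With
  `fixed_np=True` (the first benchmark's regime) only anchors are added. A
  refinement whose anchors all duplicate existing ones widens to both
  actions before reporting a no-op.
- Determinism: all randomness flows from `OaConfig.seed`; identical
  configurations produce identical ledgers with these backends.

## Synthetic data: what it emulates, what it does not

The generator integrates the true model with LSODA at rtol 1e-10, applies the
linear observation map, and adds independent Gaussian noise. Fixture
defaults are the stated world of the benchmarks:

- `pinene_clean` / `pinene_noisy`: the historical eight sampling times
  (1230 … 36420 min), rates at the literature-standard estimates
  (5.93e-5, 2.96e-5, 2.05e-5, 2.75e-4, 4.00e-5 min⁻¹ — inside the [0, 1]
  box; a *random* draw from that box would be unidentifiable at this
  horizon). The noisy variant uses σ = 0.7 mass-fraction units, chosen so
  that the expected SSE over the 40 residuals (n σ² ≈ 19.6) matches the
  misfit level of the historical fit.
- `hiv_small`: two experiments (no inhibitor / 1.5 nM inhibitor), horizon
  shortened to 300 s, enzyme 0.004 μM, substrate 25 μM, best-known rate
  constants, signal scale fixed to 1 (the scale is not among the benchmark's
  adjustable parameters and its value is not published). Titration-style
  uncertainty is represented by the free per-experiment E₀/S₀, not by a
  multiplicative noise model.
- `toy_linear` (ż = θ, data y = 2t, optimum θ = 2, SSE = 0) and
  `toy_bilinear` (ż = a·b, data y = 6t, optimal manifold a·b = 6) have
  closed-form optima and exercise the hyper-plane and envelope machinery in
  isolation.

The generator does **not** emulate fluorimeter drift, autocorrelated noise,
or the two historical laboratory datasets themselves — those numbers were
never published. A green fixture test therefore establishes correctness of
the machinery on data with the benchmarks' *structure*, not reproduction of
the papers' archival fits.

## Numerical choices and degenerate inputs

- Multistart sampling is log-uniform for nonnegative boxes spanning ≥ 3
  decades (rate constants), uniform otherwise; the box-midpoint start is
  always included. Rate constants of chemical networks are scale-free, so a
  uniform draw from [0, 1] would concentrate mass at dynamics far too fast
  for the horizon.
- Zero-noise recovery runs use a mesh (NE=12, NK=7) fine enough that the
  interpolation error at the sampling times is at round-off (SSE ≈ 1e-17);
  at the benchmark mesh (NE=5, NK=3) discretization error floors the SSE
  near 1e-3, which is invisible under realistic noise but dominates a
  noise-free fit.
- Degenerate envelope boxes (point intervals) collapse McCormick to the
  exact equality. Duplicate anchors are deduplicated at 1e-9. A collocation
  Newton that fails (singular stage Jacobian, non-finite residual) marks the
  local stage infeasible — triggering refinement, not an abort.
- OBBT results are padded by a 1e-12 relative margin before replacing a
  bound, so LP round-off cannot cut a feasible point.

## Known limitations

- The master grows quickly with NE·NK and experiments; the full proteinase
  benchmark (5 experiments, NE=NK=5, 20 free quantities) is hours-scale, as
  is closing a 5% gap on noisy isomerisation data — consistent with the
  benchmarks' reported CPU times. Desk-scale runs use the toy and shortened
  fixtures.
- Only box constraints, equality dynamics and least-squares objectives are
  supported; no path constraints, events, delays or stochastic kinetics.
- Univariate atoms that change curvature on their box are rejected rather
  than split automatically.
- Moving finite elements / adaptive mesh refinement are out of scope; choose
  element edges by inspection of the dynamics' timescales.
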