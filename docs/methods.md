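# Methods

## Model

The package integrates the compartmental system

```
dx/dt = eps2 · g(N) · R(t) · x + eps1 · A · x,    N(t) = 1ᵀx(t),
```

and its linear part `dy/dt = eps1 · A · y`, and checks the sufficient
conditions under which the two are asymptotically equivalent:

1. **Companion pair.** A positive function `h(N)` and constant `C > 0`
   solving `−C/(N·h) = d/dN (g/h)` on the relevant size interval. For the
   built-in families the pair is analytic: logistic
   `g = 1 − (N/K)^γ, h = N^γ, C = γ`; Gompertz `g = γ·ln(K/N), h ≡ 1,
   C = γ`; von Bertalanffy `g = v·N^{−γ} − w, h = N^{−γ}, C = wγ`. For
   custom laws the pair is supplied (or omitted) by the user and verified
   numerically. A corollary of the companion ODE is the slope identity
   `N*·g'(N*) = −C` at the root of `g`, which also forces the root to be
   unique and stable; both are checked.
2. **Conservative switching.** `A` has non-negative off-diagonal entries
   and zero column sums. Gershgorin's theorem then places the spectrum in
   the closed left half-plane with `0` always an eigenvalue; the checker
   additionally requires the zero eigenvalue to be simple so that the
   stationary composition `π` (normalized null vector) is well defined.
3. **Rate floor.** The abundance-weighted mean intrinsic rate `r̄(t)` must
   be bounded below by some `r_min > 0` for all `t ≥ t_r`. For the built-in
   schedule kinds (constant, piecewise-constant, sinusoid) the floor and
   the threshold time are computed exactly from the schedule; `t_r` is
   snapped to the schedule breakpoint inside the bracketing grid interval
   so the decay envelope below remains valid from `t_r` onward.

When all conditions hold, the checker measures:

- the Lyapunov function `V(N) = |g(N)|/h(N)`, its exact decay identity
  `V(t) = V(0)·exp(−eps2·C·∫₀ᵗ r̄ ds)` and the envelope
  `V(0)·e^{eps2·C·r_min·t_r}·e^{−eps2·C·r_min·t}`;
- the perturbation envelope `η(t) = c·e^{−λt}` with
  `λ = eps2·C·r_min` and `c = eps2·r_max·Q1·Q2·e^{λ t_r}`, where `Q1, Q2`
  are the maxima of `h` and `V` on the invariant size interval;
- the convergence integral `∫ tᵖ e^{μt} η(t) dt` with
  `p = m + q − 2` from the multiplicities of the dominant eigenvalue
  cluster of `eps1·A`, in closed form `p!·c·(λ−μ)^{−(p+1)}` for `μ < λ`;
- the realized gap `|x(t) − y(t)|₁` against the matched linear solution
  `y₀ = (N*/N₀)·x₀`, its tail maximum, its fitted decay rate, and the
  distance of both normalized end states from `π`.

## Parameter defaults and rationale

- `eps1 = eps2 = 1` unless overridden; the time-scale experiment sweeps
  `{0.01, 1, 100}²`.
- Invariant size interval `[U1, U2] = [min(N1/2, N0), max(2·N2, N0)]`:
  a strict enlargement of `[N1, N2]`, so the trapping argument applies and
  the initial size is always inside.
- Companion maxima `Q1, Q2` are taken on a 2048-point grid over
  `[U1, U2]` and inflated by 1%. The inflation dominates the `O(step²)`
  undershoot of a grid maximum of a smooth 1-D function, keeping the
  envelope a true bound.
- Default horizon: long enough for both decay channels —
  `max(20/(eps2·C·r_floor), 20/(eps1·gap₂))` where `gap₂` is the spectral
  gap of `A` — i.e. roughly 20 e-foldings of the slower of the nonlinear
  and the mixing relaxation. Without the second term, slow mixing or small
  `eps1` would leave the linear composition unconverged at the end of the
  run and the equivalence measurement would fail for a spurious reason.
- Equilibrium finding: sign-change scan on a geometric grid over
  `[N1/2, 4·N2]` followed by Brent's method at relative tolerance 1e-12.
- Eigenvalue clustering tolerance `1e-7·max(1, ‖A‖₁)`; zero-eigenvalue
  simplicity is decided from the SVD of `A` with the second-smallest
  singular value required to exceed `max(10³·s_min, 1e-12·scale)`.

## Numerical choices

- **Integrator.** LSODA via `scipy.integrate.solve_ivp`, `rtol = 1e-10`,
  `atol = 1e-12`, segmented at rate-schedule breakpoints (each segment gets
  its own smooth right-hand side and dense output), 1000 output points by
  default. States are clipped to zero only below `−100·atol`, and the count
  of clipped entries is recorded.
- **Exact rate integral.** `∫ r̄ ds` is carried as an augmented ODE state,
  so the Lyapunov identity is checked against a quantity accurate to solver
  tolerance rather than to trapezoid-rule error.
- **Linear flow.** Propagated by `scipy.linalg.expm` of the per-step
  matrix (one `expm` per distinct step size on uniform grids), which
  conserves the 1-norm to machine precision; an ODE-based alternative is
  available and cross-checked in tests.
- **Lyapunov envelope floor.** Along a 20-e-folding run, `V(t)` falls some
  20 decades below `V(0)` — far beneath what any finite-tolerance solver
  can represent pointwise. Envelope violations are therefore normalized by
  `V(0)` and excesses below `1e-7·V(0)` are treated as solver noise, not
  violations. A per-point relative comparison at the tail would measure
  solver round-off, not the mathematics.
- **Gap decay fit.** The exponential decay rate of `|x − y|₁` is fitted by
  least squares on `log(gap)` over the final half of the samples above a
  noise floor of `100·(atol + rtol·max N)`. The floor must scale with the
  trajectory magnitude: relative solver error `rtol·N` dominates `atol`
  whenever `N ≫ 1`, and fitting into that plateau yields meaningless
  (even positive) slopes.
- **Custom laws.** Expression strings are parsed with sympy restricted to
  the symbol `N` and a small function whitelist; derivatives, including
  `d/dN (g/h)` for the companion check, are obtained symbolically. When no
  analytic derivative exists (callable input), central differences with
  relative step 1e-6 are used.
- **Serialization.** Configs are JSON with a schema version and strict
  unknown-key rejection; trajectories are TSV written with `%.17g` and read
  with round-trip float parsing, so write–read is bit-exact.

## Scenario generator

`generate_scenario(seed, …)` draws every quantity from a single
`numpy.random.default_rng(seed)` stream and records the draw in the
scenario provenance, so runs are replayable bit-for-bit. Ranges: carrying
size log-uniform in `[1, 100]`, exponents log-uniform in `[0.5, 2]`,
switching rates uniform in `[0.2, 2]` times a scale, intrinsic rates
log-uniform in `[0.2, 2]` (piecewise schedules use 2–3 segments, sinusoids
keep the amplitude strictly below the offset so the floor stays positive),
initial compositions Dirichlet, initial sizes log-uniform in
`[N1/2, 2·N2]`. Matrices are redrawn (up to a cap) until the zero
eigenvalue is simple and the spectral gap exceeds 0.1, so every generated
scenario satisfies the theorem's hypotheses by construction.

That construction is deliberate and bounds what the passing suites show:
they demonstrate that the implementation agrees with the theory *on the
hypothesis class*, not that real cell populations satisfy the hypotheses.
Inapplicable inputs (multi-root laws, zero rate floors, non-simple zero
eigenvalues, invalid companion pairs) are exercised separately and must be
diagnosed, not silently processed.

## Limitations

- The equivalence verdict is numerical evidence at a finite horizon and
  finite tolerance, not a proof; tolerances (tail gap ≤ 1e-5·N*, etc.) are
  those of the acceptance suite.
- Rate schedules are limited to the three built-in kinds; arbitrary `r(t)`
  callables are not accepted, because exact suprema and floors are needed
  for the envelope constants.
- The rate floor is computed for the *schedule*, with the weighted mean
  `r̄` along the trajectory checked against it; schedules whose floor is
  positive only on a measure-theoretic average (allowed by the theory's
  integral condition) are conservatively rejected.
- `A` is constant in time; time-varying switching is out of scope.
- Stiff extremes far beyond the tested `eps` range (`≫ 100` or `≪ 0.01`)
  may need tighter tolerances or longer horizons than the defaults.
- The model is deterministic ODE; no demographic stochasticity.
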