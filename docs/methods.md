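# Methods

## Models and assumptions

All four networks are closed, reversible, mass-action systems whose
totals are conserved:

1. **Minimal sequestration.** T + S ⇌ TS̄ with conserved T_T and S_T.
   One stochastic degree of freedom (the free-target count T); support
   T ∈ [max(0, T_T − S_T), T_T]. Detailed balance gives the stationary
   law P(T) ∝ (K^d)^T C(T_T, T) / [S_T − (T_T − T)]!, where K^d = k₋/k₊
   is the dissociation constant **in molecule-number units** (the
   concentration-based constant times the system volume). All stationary
   quantities depend on the rates only through K^d; individual k₊, k₋
   enter only the stochastic simulator.
2. **Two competing targets.** Two independent binding reactions to one
   shared sequestrant pool; two degrees of freedom (T₁, T₂). The joint
   stationary law is the grand-canonical product form restricted to the
   feasible region where the free sequestrant
   S = S_T − (T_1T − T₁) − (T_2T − T₂) is nonnegative.
3. **Competitive inhibition, one enzyme.** The free enzyme either binds
   the inhibitor (complex C) or binds substrate — held at a fixed, large
   concentration c_s — to become active (T_A). In the quasi-equilibrium
   limit (product formation much slower than binding/activation) the
   remaining network is reversible and P(T_A, C) takes a product form
   with activation weight a^{T_A}, a = c_s·k_f/k_r, and binding weight
   (1/K_d)^C. The closed form is established in-repo by asserting the
   two edge-wise detailed-balance ratios on every feasible edge of every
   constructed table, and independently by the enumerated-generator
   oracle in the tests; it is not taken on citation.
4. **Two enzymes, shared inhibitor.** The four-axis analogue over
   (T_1A, C₁, T_2A, C₂) with the shared factor 1/(S_T − C₁ − C₂)!.
   Its (T_1A, T_2A) projection carries the active-enzyme correlations.

Substrate and product pools are never modeled explicitly; the general
(non-quasi-equilibrium) inhibition case is covered numerically by the
simulator with a catalytic rate k_cat added to the deactivation channel,
not by a second closed form.

## Extrinsic noise

Cell-to-cell variability of the sequestrant total is **static**: each
realization draws an integer S_T once, and observables are mixtures of
the conditional stationary laws (law of total probability). This is the
slow-fluctuation limit of a dynamically varying sequestrant. Families:

* `gaussian(mean, sigma)` — kernel exp(−(s−⟨S_T⟩)²/2σ²) on the integers
  s ≥ 0, truncated (not resampled) and renormalized. The support is cut
  at ⟨S_T⟩ + 10σ and wherever the per-point weight falls below 1e−16 of
  the peak, which bounds the truncation error of the infinite mixture
  far below every test tolerance. Truncation at zero is the simplest
  reading of a "positive-values" Gaussian; for ⟨S_T⟩ ≥ 3σ the induced
  mean shift is below 0.5 counts (tested).
* `uniform(lo, hi)` — equal weights; included because a flat law piles
  mass into the repressed peak but cannot build a competing unrepressed
  mode (tested qualitatively).
* `point(mean)` — no extrinsic noise; recovers the pure-intrinsic laws.

**Mode counting** uses strict local maxima with a relative tie tolerance
of 1e−12, no prominence threshold, boundary values compared against an
implicit zero outside the support, and plateaus (runs equal within the
tolerance) flanked by strictly smaller neighbours counted once. The
tolerance exists only to absorb floating-point ties; it is exposed as a
parameter. Because no prominence rule is applied, bimodal-region
boundaries can shift by roughly one grid step relative to analyses that
discard shallow secondary peaks.

**Bimodality scans** use steps ΔT_T = 1 and Δσ = 0.25 by default. The
conditional laws are computed once per (T_T, S_T) pair and reused across
all noise levels; the bimodal region is the set of grid nodes with
exactly two modes and the reported boundary is its edge-node set.

## Key parameters and defaults

| parameter | meaning | units | notes |
|---|---|---|---|
| T_T, S_T, T_iT | total copy numbers | molecules | any nonnegative integers; degenerate zeros give forced point masses |
| K^d | dissociation constant | molecules | small ⇒ sharp threshold; typical study values 0.02–5 |
| a = c_s·k_f/k_r | activation ratio | dimensionless | 1.25 in the reference inhibition setting |
| ⟨S_T⟩, σ | extrinsic-noise mean and level | molecules | reference setting ⟨S_T⟩ = 30 (or 60 for two targets) |
| k₋ | unbinding rate | 1/time | SSA only; defaults to 1 and sets the time unit |

## Numerical choices

* Every factorial/binomial is a log-gamma evaluation; normalization is
  log-sum-exp after a max shift. Direct arithmetic overflows near copy
  number 170, the log-space path is exercised up to 10⁴ in the tests.
* The hypergeometric mean formula has ₁F₁ functions with
  negative-integer first arguments: finite polynomials. They are summed
  as at most T_T+1 (or S_T+1) positive log-space terms — at a negative
  argument every term of the terminating series is positive, so there is
  no cancellation and no need for arbitrary-precision arithmetic, and no
  generic hypergeometric routine (unreliable at negative-integer
  parameters) is involved.
* The rate-equation root uses the cancellation-free branch of the
  quadratic formula (rationalized form when T_T − S_T − K^d < 0).
* Joint tables are materialized densely over the full copy-number
  rectangle with exact zeros outside the feasible region; the printed
  nested summation limits of the normalization constants are enforced
  implicitly by feasibility. The four-axis two-enzyme table carries a
  configurable state-count guard (default 5·10⁷ cells).
* Pearson's coefficient returns a NaN sentinel when a marginal is
  degenerate (zero variance) instead of raising; the Gaussian-equivalent
  transform returns +inf at |ρ| = 1. Mutual information is reported in
  bits by default (nats switch available) with 0·log 0 := 0 enforced
  before any logarithm.
* Argmax searches (correlation-maximum locus) break ties toward the
  smaller T_1T so tables are byte-reproducible.

## Oracles

* **Enumerated master equation.** States are all nonnegative integer
  solutions of the conservation laws, in lexicographic order (guarded
  DFS). The stationary law is the normalized solution of Qᵀp = 0 with a
  normalization row, solved sparsely; residuals above 1e−9 of the
  propensity scale raise. Irreducibility holds for these reversible
  networks with positive rates, so the null vector is unique.
* **Gillespie direct method.** Jit-compiled inner loop (pure-Python
  fallback), mandatory integer seed, mass-action propensities via
  falling factorials, integer state updates so conservation is exact at
  every sample. Defaults: burn-in 50, sampling interval 5 in units of
  1/k₋. These are implementation choices — the networks carry no
  physical timescale at stationarity — and the burn-in-doubling
  stationarity test guards them.

## What the tests do and do not show

All inputs are parameter sets; there is no external data. The study
conditions are the reference settings above, and the test suite scans
them at desk scale: totals up to a few hundred for exact/oracle
comparisons (10⁴ for overflow checks), bimodality grids over
T_T ∈ [20, 60] × σ ∈ [0, 13], locus searches over T_1T ≤ 100, and 10⁵
SSA samples per network (total variation against the exact laws
comfortably below 0.02). Passing shows internal exactness and the
noise-induced phenomenology under the stated static-noise model. It does
not show anything about open systems with synthesis and degradation,
dynamically correlated extrinsic noise, more than two competitors, or
parameter inference from measured distributions — all out of scope.

## Known limitations

* The static-mixture treatment of extrinsic noise is the slow-limit
  approximation; finite correlation times would smear the mixture.
* Mutual information exceeds the Gaussian-equivalent baseline
  −½log₂(1−ρ²) over the pre-saturation sweep range, but deep past
  saturation (|ρ| → 1, strongly peaked joints) the inequality reverses;
  the information tests therefore probe the regime where the joint is
  not yet degenerate (T_1T ≤ 80 at the reference two-target setting).
* The two-enzyme solver materializes the dense four-axis table; very
  large totals hit the state guard and need the SSA instead.
* The quasi-equilibrium inhibition form is exact only for k_cat → 0;
  with a finite catalytic rate it remains accurate while
  k_cat ≪ k_r (verified at k_cat = 10⁻³·k_r by simulation).
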