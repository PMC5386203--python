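# Methods

## Model and assumptions

`gpanet` grows undirected networks on the hyperbolic plane of curvature
K = −1. Node `t` carries polar coordinates `(r_t, θ_t)`: the radius encodes
age/popularity (`r_t = 2 ln t` at birth, fading outward as
`r_s(t) = β r_s + (1 − β) r_t`), the angle encodes similarity. Placement is
geometric preferential attachment: among `t` uniform candidate angles, the
newcomer picks location `φ` with probability proportional to
`A_t(φ) + Λ`, where the attractiveness `A_t(φ)` counts existing nodes within
hyperbolic distance `r_t` of `(r_t, φ)`. It then links to its `m`
hyperbolically closest predecessors. Nodes never move after birth; edges are
never deleted; the graph is simple by construction.

Working distance is the standard large-radius approximation
`x ≈ r_p + r_q + 2 ln(Δθ/2)` (module default, `distance_mode="approx"`),
which preserves the ranking by the popularity–similarity score
`s^β θ_st` exactly; the exact law of cosines
`cosh x = cosh r_p cosh r_q − sinh r_p sinh r_q cos Δθ` is available
everywhere (`distance_mode="exact"`). The `Δθ/2` (not `sin(Δθ/2)`) form is
used deliberately; its relative error against the exact distance is below
1% for `r ≥ 10` and `Δθ ≲ 1`, growing to ≈4% at `Δθ = π` — immaterial for
nearest-neighbour ranking, which only probes small `Δθ`.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `n` | nodes | — | experiments here use `n ≤ 10⁴` |
| `m` | links per new node | 3 | sets mean degree ≈ 2m |
| `β` | popularity-fading speed, (0, 1] | 2/3 | degree exponent γ = 1 + 1/β (2.5 at default) |
| `Λ` | initial attractiveness, ≥ 0 | 1.0 | constant or a `t → Λ(t)` schedule; controls angular heterogeneity only |
| `distance_mode` | approx / exact | approx | both for attractiveness disks and linking |
| `seed` | RNG seed | none | per node: `t` candidate draws, then one selector |

All angles are canonicalised to `[0, 2π)`; angular arithmetic goes through
`π − |π − |θ_s − θ_t||`.

## Numerical and algorithmic choices

- **Disk membership as an angular window.** For both distance modes the
  condition "node `s` lies within `r_t` of `(r_t, φ)`" reduces to
  `Δθ(φ, θ_s) ≤ w_s`, with `w_s = 2 e^{−r_s(t)/2}` (approx) or the arccos
  inversion of the law of cosines (exact), capped at π. Attractiveness for
  all candidates at one step is then a sorted sweep with a difference
  array, O((t + t) log t), making growth O(n² log n) overall instead of the
  naive O(n³) distance loop. The reduction is exact, and the naive count is
  kept as a brute-force oracle in the test suite.
- **Exact distance stability.** `|Δθ| < 10⁻⁹` returns `|r_p − r_q|`
  directly; radii above 350 switch to a log-sum form before `cosh`
  overflows.
- **Tie-breaks.** The `m` closest predecessors are chosen by
  (distance, birth time) lexicographic order; ties have measure zero but
  resolve deterministically.
- **Degenerate selection weights.** With `Λ = 0` a candidate set in which
  every location is empty (`ΣA = 0`) carries zero total weight. The
  single-step sampler (`select_candidate`, `sample_angle`) resolves the 0/0
  limit uniformly. The full simulator instead *redraws* such candidate sets
  (`zero_weight_policy="resample"`, default): under pure density-following
  a newcomer always follows somebody, so zero-attractiveness placements
  have probability zero — exactly the event set to which the likelihood
  assigns `−∞` at `Λ = 0`. This keeps generator and estimator measure-
  theoretically consistent and makes zero-`Λ` recovery categorical rather
  than seed-dependent; `"uniform"` restores the plain 0/0 convention.
  At `t = 1` (and whenever `Λ > 0`) the policy never triggers.

## Degree-distribution fitting

`fit_power_law` implements the standard discrete recipe: for each candidate
cutoff `k_min` (every observed degree whose tail keeps ≥ 10 points and two
distinct values), the exponent is the Hurwitz-zeta MLE and the cutoff
minimising the tail KS distance wins. An optional semi-parametric bootstrap
(default B = 100 when requested) refits synthetic body+tail resamples and
reports the fraction of KS distances exceeding the observed one
(conventional acceptance at p > 0.1). Exact inverse-CDF sampling of the
discrete power law backs both the bootstrap and the recovery tests.

A caveat the package makes explicit: the model's mean-degree law is
`k̄_s(t) = m[1 + ((1−β)/β)((t/s)^β − 1)]`, i.e. a *shifted* power law with
offset `A = m(1 − (1−β)/β)`. Its CCDF `((k − A)/B)^{−1/β}` has local
log-slope `(1/β)·k/(k − A)` — steeper than `1/β` at small `k` — so
finite-size fits at the modal cutoff `k_min = m` overshoot the asymptotic
exponent: ≈2.73 instead of 2.5 at `β = 2/3`, `n = 10³`, and badly (≈2.97 vs
2.25) at `β = 0.8`, where the offset is largest. This is a property of the
model plus the fitting convention, not of the implementation (the fitter
recovers γ to ±0.01 on exact discrete-ζ samples); the exponent-tracking
tests therefore cover `β ∈ {0.5, 2/3}`, where the offset is zero or mild.

## Soft communities

`θ_c` defaults to the closed form `(2π/n)(ln n + γ_E)`; the exact
`(2π/n) H_n` (via digamma) is one flag away. Splitting is *strictly* greater
than `θ_c` (equality has measure zero); the block spanning the `2π → 0` seam
is one community; communities are ordered by their first member's angle.
With a single community the separation `S` is undefined and raises a typed
error rather than returning a sentinel — at large `Λ` (uniform angles) the
expected number of super-critical gaps is `e^{−γ_E} ≈ 0.56`, so
single-community outcomes dominate by design, and ensemble averages of `S̄`
are taken over the replicates where it exists. Gap autocorrelation is the
biased sample ACF (statsmodels) of the circularly ordered gap sequence.

## Λ likelihood

The placement likelihood factorises over birth steps; each step's
normalising constant is an expectation over the `t − 1` latent candidate
angles, estimated by Monte Carlo from `N` uniform sample paths drawn once
and truncated per step. The per-path denominator treats the observed
position as one of the `t` candidates,
`D_t^{(j)} = (A_t(θ_t) + Λ) + Σ_i (A_t(φ_i^{(j)}) + Λ)`, and the average
over paths is taken *before* the logarithm; the resulting O(1/N) bias is
second-order, and an average-of-logs variant (whose Jensen bias has the
opposite sign) is available behind a flag. Because every attractiveness is
precomputed into an immutable bank, profiling `l(Λ)` over any grid adds no
distance computations. Defaults `n₀ = 500`, `N = 100`; the recovery tests
use `n₀ ≤ 200` for speed — at those sizes `|Λ̂ − Λ| ≤ 0.3` holds in ≥ 4/5
replicates for `Λ ≤ 1`, with error growing in `Λ` as the profile flattens.
`Λ = 0` with any observed zero attractiveness reports `l = −∞` (not an
exception). Temporal profiles rerun the full MLE on growing birth-order
prefixes; when birth times are unknown they can be assigned as ranks in
decreasing degree order (ties by node id).

Radial coordinates are never read from data: they are reconstructed from
birth order (`r_t = 2 ln t`, faded by β). For embedded real networks β is
supplied by the user, e.g. `1/(γ − 1)` from a degree-distribution fit.

## What the generator does and does not emulate

The simulator *is* the model, so tests against it validate internal
consistency: scale-freeness, clustering, their Λ-invariance, gap statistics,
and parameter recovery under correctly specified coordinates. It does not
emulate what real embedded data adds: coordinate noise from embedding
algorithms (which smooth the angular density toward uniformity and bias `Λ̂`
upward), degree-ordering violations in birth-time reconstruction, or
non-constant unknown `Λ(t)` beyond user-supplied step schedules. Passing
tests therefore demonstrate method correctness, not robustness to
misspecified coordinates.

## Problem sizes used by the test suite

Ensembles of 10 (degree/clustering invariance) and 100 (KS/separation
monotonicity) replicates at `n = 10³`; two replicates per `Λ` at `n = 10⁴`
for gap-ACF and `c̄(k)`-spectrum checks; Monte-Carlo checks of the critical
gap use 10⁵ samples of 100 points. These sizes match the regime the model
was designed for while keeping the full suite in a few minutes.

## Known limitations

- Growth is O(n² log n); `n ≤ 10⁴` is the intended regime.
- The likelihood bank is O(n₀³N) attractiveness counts; `n₀ = 500` is
  comfortable, `n₀ = 10⁴` is not.
- No embedding inference (coordinates must come from elsewhere), no moving
  nodes, no edge deletion, no directed or weighted variants, and no
  parametric law for decaying `Λ(t)` — only step schedules and per-prefix
  estimation.
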