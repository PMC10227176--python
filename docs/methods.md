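# Methods

This note documents the models implemented in `seedrift`, the defaults and
their rationale, the numerical choices, and the limits of what the test suite
demonstrates.

## System and scope

The models describe hydrochorous (water-borne) seed dispersal of semelparous
shoreline plants along a stream: dispersal is strictly downstream and
one-dimensional, each grid cell (1 cell = 1 m) holds at most one plant, and
habitat comes in equal patches of `x_h` cells separated by uninhabitable
matrix stretches of `x_ipd` cells, with the pattern starting on a habitable
run. Out of scope by design: 2-D landscapes, unequal or clustered patches,
habitat-quality gradients, patch turnover, upstream or vector-mediated
dispersal, fat-tailed kernels, seed banks, and overlapping generations.

## Dispersal kernel

A floating seed settles with constant per-cell probability `1 − λ`; the
retention curve is `F_d = λ^d` and the (real-valued) median dispersal
distance is `ln(0.5)/ln(λ)`. λ depends on seed size `S` through a sigmoid,
`λ(S) = 1 − 1/(1 + e^{α + β(S − s_min)})`, rising with `S` when `β > 0`.
Rather than exposing (α, β), kernels are calibrated from the median
distances of the smallest and largest seeds (`d05` at 0.5 mm, `d30` at
30 mm). Two constraints, two unknowns, and the solution is closed-form and
unique:

    α = logit(0.5^(1/d05)),   β = [logit(0.5^(1/d30)) − α] / (s_max − s_min).

Equal medians give `β = 0` (size-independent dispersal), which is the basis
of several degenerate-case tests. Over the studied calibration ranges
(`d05 ∈ [20, 300]`, `d30 ∈ [50, 750]`) α spans ≈ 3.3–6.1 and β ≈ −0.06 to
0.13.

Discrete dispersal distances are geometric, `P(k) = λ^k (1 − λ)` for
`k ≥ 0` — the floor of a continuous exponential with rate `−ln λ` — so the
stochastic model's landing distribution matches the deterministic deposition
weights exactly. Two identities carry much of the test suite:

* the truncated-renormalized deposition vector
  `(λ^d − λ^{d+1})/(1 − λ^{d_max})` telescopes to 1;
* the geometric distribution folded onto a ring of `L` cells equals that
  same vector with `d_max = L`, which links the periodic stochastic model to
  the bounded deterministic one without approximation.

Powers `λ^d` are evaluated in log space (`exp(d ln λ)`) so that distances up
to `d_max = 5000` neither overflow nor lose the normalization; underflow of
astronomically small tail entries to zero is accepted.

## Deterministic single-plant model

One parent sits at the upstream edge of a patch (cell 0; the offset within
the patch is configurable and defaults to 0, since only downstream cells
matter under unidirectional flow) and disperses `n_tot` seeds over a bounded
window of `d_max` cells. Seed production cost is proportional to seed
volume, `c = c1 π S³/6`; the expected deposition is
`N_d = n_tot (1 − c) · pmf(d)` and a habitable cell is colonized with
probability `P⁺ = 1 − (1 − g)^{N_d}`. Fitness is the sum of `P⁺` over
habitable cells among `d = 0 … d_max − 1` (the deposition support; the natal
cell counts). Three deliberate numerical choices:

* `N_d` stays real-valued inside `P⁺` — rounding would create fitness
  plateaus that stall a 0.01-mm adaptive walk;
* `P⁺` is computed as `−expm1(N_d · log1p(−g))` for accuracy at small
  `g·N_d`, with `g ∈ {0, 1}` special-cased;
* seed sizes whose cost reaches 1 (possible above ≈ 26.7 mm at the default
  `c1 = 1e-4`) produce no seeds and are assigned fitness 0, so the walk can
  evaluate the whole trait range; constructing the deposition vector itself
  at such a size is an error.

Seed size evolves by hill climbing on the 0.01-mm grid: compare fitness at
`S`, `S − 0.01`, `S + 0.01` (candidates outside [0.5, 30] excluded), move to
the strictly better neighbour — ties between two improving neighbours break
toward the smaller, cheaper seed — and stop when `S` beats or ties both.
The walk is deterministic, strictly fitness-non-decreasing, and therefore
bounded by the 2951 grid points. Off-grid starting values are snapped with a
logged warning.

Defaults (`n_tot = 10,000`, `g = 0.3`, `c1 = 1e-4`, `d_max = 5000`,
`x_h = 50`, sweep to `x_max = 5000`) are the study conditions of the
headline deterministic runs. The window length follows the stated
5000-cell environment; an alternative reading of 50,000 cells exists in the
source material's parameter table but is inconsistent with its own text and
is treated as a typo.

## Stochastic individual-based model

A population lives on a ring of `n_patches` pattern repeats ("continuous
boundaries" read as periodic wrap — the only reading that conserves seed
mass in a finite world; the original patch count is unstated, default 10).
Each generation: parents are shuffled uniformly; each releases
`N_j = round(n_tot(1 − c))` seeds (half-away-from-zero rounding; budgets
clamp to 0 when `c ≥ 1`, since mutation can legitimately create such
phenotypes); each seed lands `parent + k (mod L)` cells downstream with
geometric `k`; a seed establishes iff its cell is habitable and not yet
claimed by a new-generation seedling, passing an independent Bernoulli(`g`)
trial (a failed trial leaves the cell open for later seeds); established
seedlings inherit the parent's size mutated ±1 mm with probability `μ`,
clamped to [0.5, 30]; dispersal short-circuits once every habitable cell is
claimed; parents die and never block seedlings.

*Vectorization.* A parent's seeds are i.i.d. and exchangeable, so they are
drawn as one batch and a contested cell is claimed by that parent iff at
least one of its seeds passes the germination trial. This is
distributionally identical to strict seed-by-seed processing (the claiming
probability per cell is `1 − (1 − g)^K` either way, and which of a parent's
identical seeds wins is immaterial) while being orders of magnitude faster;
cross-parent ordering, which does matter, remains sequential.

When the sweep changes `x_ipd`, plants keep their (patch index, within-patch
offset) and only the matrix stretches are resized. After an extinction the
remaining sweep levels are recorded as extinct rather than re-founded.

Defaults follow the headline stochastic runs (`n_tot = 10,000`,
`n_gens = 1000` per level, `μ = 0.001`, founders at 20 mm, start at
`x_ipd = 5`, sweep step 5 to `x_max = 1000`). The source material prints two
contradictory (`n_tot`, `n_gens`) pairs — (1000, 10,000) in its parameter
table versus (10,000, 1000) in its headline-figure caption; the defaults
follow the caption and both remain plain config values. Notably, the
low-seed-budget variant (`n_tot = 1000`) is the selectively interesting
regime: with 10,000 seeds per plant a single parent saturates the habitat
each generation and competition becomes nearly neutral.

## Sweeps, hysteresis detection, sensitivity grids

The up sweep visits `x_ipd = x_ipd_min, +step, …, x_max`, seeding each level
with the previous level's evolved state (deterministic: previous `S*`;
stochastic: the surviving population); the down sweep mirrors the same grid
back down, starting from the up sweep's final state, so the two directions
share their endpoint level.

The hysteresis quantification is this package's operationalization (the
original work never defines how its zone sizes were measured): the up sweep
*collapses* at the first level whose evolved median dispersal distance falls
to ≤ 50% of the running maximum of earlier levels; the down sweep *recovers*
at the first level (traversed from `x_max` downward) regaining 50% of the
pre-collapse maximum; `zone_size = up_transition − down_transition` (down to
the grid minimum if recovery never happens), forced to 0 whenever the two
curves never separate by more than `tol` (default: one sweep grid step, in
cells). Extinct levels count as zero dispersal capacity. The detector is
isolated in one function so alternatives can be swapped.

`sensitivity_grid` takes named axes of config values, runs one sweep (per
replicate seed for the stochastic model) per Cartesian combination, and
returns a long-format table of transitions and zone sizes.

## Problem sizes used in tests and the acceptance script

The deterministic reproduction sweeps the full 0–5000-cell fragmentation
range at step 10 (the original used step 1); at step 10 the collapse sits at
x_ipd ≈ 3370–3400 with a zone of ≈ 810–850 cells, and truncating the sweep
at 2000 cells would miss the transition entirely. The stochastic
reproduction uses 5 patches, `n_tot = 1000`, `n_gens = 100` per level, step
25 to `x_max = 500`, 10 replicates — about 1/100th of the original runs'
evolutionary time. Monte-Carlo oracle comparisons use 10⁴ replicates on
100-cell landscapes with per-cell 3-standard-error agreement under a
Bonferroni family-wise bound.

## Known limitations

* **Scaled stochastic sweeps do not show the abrupt collapse.** With ±1-mm
  mutation steps, `μ = 0.001` and ≈ 250 plants, the population median moves
  at most ~1 mm per 100-generation level, so a factor-2 single-level drop in
  median dispersal distance cannot occur at the reduced evolutionary time
  budget above — reproducing the sudden stochastic transition requires
  runs near the original scale (hundreds of levels × 1000+ generations).
  The asymmetry itself is visible at reduced scale: down sweeps remain at
  the lower dispersal capacity evolved under high fragmentation instead of
  retracing the up sweep. Additionally, with `d30 = 700` the largest seeds
  cross every gap up to `x_max = 1000` with substantial probability
  (retention ≈ 0.35 over 1050 cells), so the short-dispersal attractor is
  weak in that kernel; smaller `d30` compresses the dispersal range instead.
* The binomial landing statistics of the stochastic model and the
  expected-count exponent of the deterministic occupancy formula differ at
  order `N p² g²`; oracle-equivalence tests therefore run at `g = 0.01`
  (where the gap is far below Monte-Carlo noise) or `g = 1` (where the
  binomial form is exact and used directly).
* The deterministic model averages nothing over parent positions: the parent
  sits at a configurable single offset (default: patch upstream edge).
* Synthetic landscapes are perfectly regular; none of the tests say anything
  about irregular patch geometry, habitat-quality variation, or real
  dispersal data.
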