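# Methods

## Model

`S` monomer species assemble into rings of size `L` (an integer multiple of
`S`; species bind only with periodically consecutive indices, so a polymer
is fully described by its left-end species and its length) or, in the
square variant, into a `√S×√S` grid with one species per position.  The
state is the vector of occupation numbers: inactive and active monomer
pools per species, polymer counts `n_l^s`, and the completed-target count.
Reactions and propensities:

| reaction | propensity |
|---|---|
| activation of species `s` | `α n_0^s` |
| dimerization `(s, s+1)` | `(μ_1/V) n_1^s n_1^{s+1}` (S ≥ 2); `(μ_1/V) n_1(n_1−1)` for S = 1 |
| attachment to right/left end of `(s, l)` | `(rate_l/V) n_1^{s+l} n_l^s` and `(rate_l/V) n_1^{s−1} n_l^s` |
| decay of `(s, l)`, `l < L_nuc` | `δ_l n_l^s`, monomers return to the *active* pools |
| polymer joining (pp variant) | `(ν/V) n_{l1}^{s1} n_{l2}^{s2}` per ordered fitting pair, `l1+l2 ≤ L` |
| monomer→cluster (square) | `b ν/V n_1^p` for `b ≥ 1` grid contacts |

with `rate_l = μ_l` below the nucleation size and `ν` at or above it.  The
homogeneous `S = 1` dimerization uses `n(n−1)` (not `n(n−1)/2`) so that its
mean-field limit is `μ_1 c_1²`, identical to the heterogeneous reduction.
Completed structures are absorbing; attachment to length `L−1` (or a join
with combined length `L`) closes the ring directly — a length-`L` open
chain never exists.

Units: `ν = 1` and `C = 1` set the time and concentration scales, so the
activation rate enters as the dimensionless `ω = α/(νC)` and the
dimerization rate as `η = μ/ν`.  The volume `V = N/C` converts
concentration-based rate constants to per-pair propensities.

## Stochastic simulator

Exact SSA: exponential waiting times from the total propensity, channel
choice proportional to propensity.  The ring kernel keeps the full
propensity table incrementally — an event touches O(1) occupation numbers
and each changed active-monomer pool touches only the O(L) channels that
consume it — with group/row sums re-derived from scratch every 4096 events
to cancel floating-point drift.  Termination is declared only after an
exact recomputation gives total propensity zero; a selection walk that runs
past its group (possible at the drift noise floor) falls back to a refresh
and redraw.  The polymer–polymer and square kernels recompute all
propensities each event (their channel structure changes globally when
structures join), using per-species cumulative polymer counts to keep the
cost at O(S·L) per event.  A pure-Python channel enumeration implements the
same chemistry by explicit listing; it asserts mass conservation and yield
monotonicity after every event and serves as the independent oracle for the
kernels in the test suite.

For `L_nuc = 2` every trajectory reaches an absorbing state within
`2 S N` events.  For `L_nuc > 2` decay and re-nucleation can cycle
indefinitely, and the churn rate scales like `μ/α` events per activation —
simulations in the deep `α → 0` limit are therefore run at the largest
activation rate that is still far below threshold (the plateau is
`α`-independent), and runs additionally terminate ("plateau" termination,
reported separately from absorption) when the yield has not changed over a
configurable event window after the inactive pool is exhausted.

Ensembles derive per-run seeds from a root seed via NumPy `SeedSequence`
spawning; identical `(config, seed)` reproduce trajectories bit-identically.
Because every propensity is linear in `C` at fixed `N`, rescaling
`(C, α) → (kC, kα)` leaves the embedded jump chain invariant — matched
seeds give identical final yields, which the tests exploit as an exact
master-curve collapse check.

### The `α → 0` plateau

The saturation yield `y_max` is measured by the decade-halving rule:
starting one decade below the deterministic threshold `α_th`, the
activation rate is lowered tenfold until the ensemble mean changes by less
than 0.01 between consecutive decades; the plateau is then re-measured with
the full ensemble.  A cheaper single-point proxy (`α = 10⁻³ α_th`) is used
inside large parameter scans such as the threshold-exponent search, where
the plateau property (trajectory law independent of `α` as `α → 0`) makes
the distinction immaterial.

## Deterministic theory

Mean-field factorization plus the species-relabelling symmetry reduce the
`S(L+1)` rate equations to one Becker–Döring-type ladder for
`c_l = ⟨n_l^s⟩/V`; yield is `c_L L/C`.  The ladder conserves
`c_0 + c_1 + Σ l c_l + L c_L` identically and is integrated with LSODA
(rtol 1e-9, atol 1e-13) on geometrically extended horizons until the free
monomer pools fall below `10⁻⁹ C` (steady-state event), after which nothing
moves.  The full species-resolved system is kept as a verification mode;
its yield must be independent of `S`, which the tests assert to 1e-6.

For `L_nuc = 2` the ladder is equivalent to an advection–diffusion wave in
size space with drift `2νA(t)` and diffusion `νA(t)`, a Robin influx
boundary `μA²` at `x = 2` and absorption at `x = L`.  The wave solver uses
finite volumes with upwind advection and central diffusion (Δx = 0.25
default), coefficients frozen per step under both CFL limits; its boundary
bookkeeping is exact (mass equals the integrated influx to rounding) and
the transported centre of mass reproduces `2ν∫A dt`.  Against the discrete
ladder the continuum profile agrees to ~5% relative L1 error at `L = 60`.

Yield onset requires the travelled distance `2νg`, `g = ∫A dt`, to exceed
`¼(√(1+4(L−2))−1)²` (the solution of `d + √d = L−2`; `≈ L−√L` for large
`L`).  `g(ω, η)` comes from the closed two-component system
`dA/dτ = ωe^{−ωτ} − 2ηA² − 2AB`, `dB/dτ = ηA²` (activation source dropped
and `A(0) = 1` in the dimerization scenario; finite `ω` with `η < 1` gives
the mixed scenario), integrated until `A < 10⁻¹²` with the exponential tail
`A/(2ηA+2B)` added.  Slow-nucleation limits: `2g → (π/√2) η^{−1/2}`
(dimerization) and `2g → 2a (ωη)^{−1/3}` with
`a = 3^{2/3}√π Γ(⅔)/(6Γ(7/6))` (activation), whence the threshold
prefactors `P_α = 8a³ = [Γ(½)Γ(⅔)/Γ(7/6)]³/3 ≈ 5.772` and `P_μ = π²/2`.
(The √π here is Γ(½) from the Euler beta integral `∫₀¹(1−v²)^{−1/3}dv =
½B(½,⅔)`; writing π in its place, as sometimes seen, contradicts the
numeric value 5.77 that the same expression is quoted to have.)

### Accuracy of the closed-form thresholds

The threshold formulas inherit two controlled approximations: the
quasi-steady-state solution of the reduced system (relative error in `g`
of order `(ωη)^{1/3}`, i.e. ~2% at `ω = 10⁻⁶` but ~6% at `L = 40` scales)
and the large-`L` distance `L−√L` (2.7% below the exact form at `L = 60`).
Both enter the inverted threshold cubed: the numerically exact onset rate
sits ~33%/23%/15% above `α_th` at `L = 40/60/100`, converging slowly from
above.  `α_th` is therefore an asymptotic marker of the onset decade, not a
5%-accurate rate; the deterministic yield-0.5 crossing lies within a factor
two of it across `L = 20–60`.

## Operational definitions

* **Nonzero yield** (threshold-exponent search): at least one completed
  structure in ≥5% of ≥32–64 seeded runs; the fit reports the exponent for
  cutoffs 2%/5%/10% from the same cached ensembles so the sensitivity is
  visible (±≲0.3 at the sizes used).
* **Exponent range:** the scaling `N_th ~ L^ξ` is fitted on `L ∈ {20, 30,
  45, 60}` with 48 runs per evaluation — sizes chosen so the whole search
  stays desk-scale; the short lever arm (half a decade in `L`) limits the
  slope accuracy to roughly ±0.3–0.4, which the planted-exponent recovery
  test separates from any machinery error.  Measured: ξ ≈ 2.7 ± 0.15.
* **Double-junction closure:** when two fragments of combined length `L`
  join, both junctions match simultaneously; the default closes at `2ν/V`
  per fitting unordered pair (one `ν` per binding site), with a documented
  switch to `ν/V` (`closure_double_junction=False`).  The saturation yields
  at `S = L = 100` are insensitive to this factor at the Monte-Carlo
  precision used.
* **Homogeneous perfect-yield limit:** attainable only when `N` is a
  multiple of `L` (otherwise up to `L−1` monomers per species are
  necessarily stranded: e.g. `S=1, L=60, N=100` caps at yield 0.6); the
  limit is measured at `N = 120`.
* **Default `δ_l`** for `L_nuc > 2` is `ν` (decay on the growth timescale)
  when not specified — reversibility strong enough to act on the relevant
  timescale, weak enough not to dissolve the wave.

## Known limitations

* At `S = L = 60` and `N = 10⁴` the SSA mean still sits visibly below the
  mean-field yield near threshold (−0.076 at `α = 0.5 α_th`, shrinking to
  −0.0065 at `N = 10⁵`): the demographic-fluctuation deficit decays slowly
  with `N`, so "deterministic agreement" at fixed `N` is necessarily
  approximate for heterogeneous systems; the homogeneous system agrees
  within Monte-Carlo error already at `N = 10⁴`.
* The square kernel's per-event cost grows with the number of live clusters
  (O(clusters·S)); it is comfortable for the grid sizes used here
  (`S ≤ 100`, `N ≤ 100`) but not tuned for much larger grids.
* Incorrect (non-consecutive) binding, cluster–cluster binding in the
  square model, size-dependent polymer-joining rates, spatial diffusion,
  and assembly-time statistics are out of scope.
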