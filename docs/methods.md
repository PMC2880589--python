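# Methods

## Model

The simulator tracks a germinal-center (GC) B-cell population on a binned
axis of antibody–antigen binding free energy. All affinities are offsets
`x = X - X*` from the neutral level `X*` at which birth balances death;
absolute `Ka*` and antigen concentration are never needed because the
model only uses relative binding levels. The conversion between free
energy and association constant uses `kT = 0.59 kcal/mol`, which
consistently reproduces the standard identities (0.5 kcal/mol ≡ 2.3-fold
Ka; 1 kcal/mol ≡ Ka ratio 0.18; a 450-fold gain ≡ 3.6 kcal/mol).

**Growth.** Cells divide `n_div = 4` times/day (`r = n_div ln 2`).
Mutations per daughter are Poisson with mean `mu`, so the observed
fraction of mutated daughters `p` maps to `mu = -ln(1-p)` and a
per-lineage mutation rate `m_total = n_div · mu`. Mutation classes are
50% silent (dropped), 30% lethal (an effective death rate
`m_lethal = 0.3 m_total`), 20% affinity-affecting
(`m_aff = 0.2 m_total`). Selection is a death rate linear in `x` with
slope `b`; since the death rate cannot be negative the net growth law is
`B(x) = min(-b x, r - m_lethal)`, saturating `D = (r - m_lethal)/b`
kcal/mol below neutral. With this mapping `p = 0.5` yields
`m_total = 2.8/day` and `m_aff = 0.55/day/gene`, and net replicative
growth crosses zero near `p ≈ 0.9` (lethal mutagenesis).

**Mutation-effect spectrum.** Affinity changes `δ` upon an
affinity-affecting mutation are drawn from a discrete distribution on a
lattice of width `h = 0.5 kcal/mol`, independent of the current affinity.
The packaged default spectrum is a synthetic reconstruction pinned by the
empirical summary constraints — beneficial mass 4.9%, mass at ≥5-fold
improvement (δ ≤ -kT ln 5) 1.4% — with an exponentially decaying
deleterious side (scale 1 kcal/mol) renormalized to the remaining 95.1%.
The eight weights are packaged constants so every result is reproducible
bit-for-bit. `from_ddg_table` builds a spectrum from any per-mutation
ΔΔG table instead (nearest-center binning; ties round away from zero).

## Analytic solution

In the linear regime the mean-field equation has the exact solution

```
N_tot(t) = N0 e^{B(x_in) t} · Π_i exp{ m_i [ (e^{g_i t} - 1)/g_i - t ] }
```

with one factor per spectrum class (`m_i = m_aff w_i`, `g_i = -b δ_i`);
per class, the number of mutations is Poisson with time-dependent mean
`λ_i(t) = m_i (e^{g_i t} - 1)/g_i`. This product form is implemented
directly (it is numerically stable); the equivalent Fourier-transform
derivation is not separately coded. `g → 0` uses the series
`t + g t²/2`; Poisson tails are truncated at
`ceil(λ + 10 √λ + 20)`. A Gaussian initial profile stays Gaussian with
mean drifting as `x_in - b σ² t`, implemented as the exact product of the
initial Gaussian and the accumulated growth factor.

## Finite-population integrator

The closed form lets arbitrarily small amounts in strong-affinity bins
self-replicate, which is wrong for real GCs of ≤ a few thousand cells.
The integrator therefore freezes any bin holding less than one expected
cell: it neither grows, decays, nor emits mutants, but accumulates
mutation influx until it reaches one cell ("accumulative probability to
emerge"). A switch (`subunity_decay`) applies the growth factor to
sub-unity bins instead, for sensitivity checks. A state in which *every*
bin is sub-unity cannot regrow and is classified extinct.

The time step is `dt = 0.01/(b h)`, well below the selection time
`1/(b h)`. The one-step propagator uses the exact per-class within-step
intensity `λ_i(dt)` (mutants created mid-step get their destination
growth for the remainder of the step) with the mutation-count
distribution truncated at 3 per step and renormalized; composing these
steps reproduces the closed form to ~0.03% on a wide grid, and the
operator conserves cells to machine precision when growth and lethality
are off. The default grid spans `x ∈ [-8, +8]` (33 bins): the upper
(weak) half keeps deleterious multi-mutants on the grid so cumulative
edge losses stay below ~10⁻³ of the initial population; a shorter weak
side visibly distorts the total against the analytic oracle.

**Termination.** Three conventions: `fixed_window_14d` ends at first
recovery of the initial size after the bottleneck or at 14 days,
whichever comes first (pooled-spleen convention); `recovery_unbounded`
waits for recovery, guarded by `t_max` (default 100 days);
`horizon_only` runs to `t_max`. Recovery requires the population to
exceed its running minimum as well as `N0`, so a run sitting at `N0`
does not trivially "recover". The improvement statistic is
`A(t_end)/A(0)` with `A = Σ N_x e^{-x/kT}` (total affinity); extinct
runs report 0.

## Stochastic realizations

Bottleneck survival is a genuinely stochastic question, so the same model
runs as a branching process on the same grid: per step each cell either
divides (probability `∝ r`), dies (`∝ d(x) = max(0, b x + r - m_lethal)`),
or persists; both probabilities are scaled by `(e^{B dt} - 1)/(B dt)` so
the one-step mean is exactly `e^{B dt}` (this removes the O(dt) Euler
bias of plain tau-leaping, and the multinomial fates remove event
overshoot at small occupancies). Each daughter dies of lethal mutations
with probability `ν f_lethal` (with `ν = m_total/2r`, making the
per-capita lethal flux exactly `m_lethal`) and a surviving daughter makes
one spectrum-distributed affinity jump with probability
`ν f_aff / (1 - ν f_lethal)` (per-capita move flux exactly `m_aff`).
Single Bernoulli jumps are used rather than per-daughter Poisson bursts:
bursts would overdisperse the jump-size distribution relative to the
mean-field mutation stream and bias multi-mutant subpopulations upward.
With this calibration, replicate means agree with the cutoff-free
deterministic trajectory within Monte-Carlo error (checked at 200–300
replicates). Survival counts runs that never went extinct: either
recovered after a dip below the initial size or still alive at the
horizon (a run that escapes upward to 10× its initial size is stopped
early as survived). All randomness flows from one explicit seed;
per-replicate seeds are derived deterministically.

## Sweeps and statistics

The improvement landscape is computed over `p ∈ {0.1, …, 0.9}` and 12
log-spaced `Ka_in/Ka* ∈ [0.01, 1]` at fixed `b` (default 0.7; an optional
b-grid exposes the full b-profile — the landscape is shallow in `b` and
no single optimum is asserted). The pooled-spleen (fast-migration) limit
uses `N0 = 1e5` with the 14-day window; an isolated GC uses `N0 = 3000`
with recovery termination. Optimum ties break toward smaller completion
time, then smaller `p` (an artifact convention). Note that the initial
condition is placed in the grid bin containing `X_in`, so nearby `Ka_in`
grid points can share a bin.

The all-or-none statistic `P(F)` is estimated as time-spent-per-F-bin
(20 bins by default) along a single trajectory, the robust discrete
equivalent of `dt(F)/dF` that stays finite where `F` plateaus; it is
invariant under uniform time rescaling, and bimodality is asserted at the
decile scale, which is robust to the bin count.

## Design choices and limitations

- `X*` is defined as the neutral affinity (zero net growth); the
  saturation threshold sits `D` below it. Selection is phenomenological —
  no mechanistic antigen-binding kinetics, no dark/light-zone structure,
  no centroblast/centrocyte distinction, no T-cell help mechanics.
- The synthetic default spectrum reproduces the *summary* constraints of
  the empirical per-mutation ΔΔG histogram, not its bin-by-bin values.
  The finite-population recovery time is sensitive to the depth of the
  beneficial tail and to the severity of the sub-unity cutoff: with this
  minimal reconstruction (beneficial support only at -0.5 and -1.0) the
  pooled-spleen landscape peaks near 120-fold under the 14-day window,
  whereas softer cutoff readings or deeper beneficial support yield
  several-hundred-fold optima at the same parameter point. The optimum
  *locations* (≈50% mutated daughters pooled, ≈60% isolated), the
  isolated-GC magnitude (~60–70-fold), the lethal-mutagenesis band, the
  extinction boundary, and the all-or-none pattern are insensitive to
  this reconstruction.
- Passing tests therefore show internal consistency (numeric ≡ analytic,
  stochastic ≡ mean-field) and robustness of the qualitative structure;
  they do not validate the model against real sequencing or affinity
  data, and real GC responses include migration, antigen depletion and
  T-cell dynamics the model deliberately omits.
- Problem sizes are desk-scale by construction: full landscapes are
  9×12 deterministic runs (seconds), survival maps default to 100
  replicates per cell.
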