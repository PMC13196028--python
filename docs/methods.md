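# Methods

## The model

`viralshunt` models a well-mixed batch co-culture of two *E. coli* lysogen
strains growing on a single limiting carbon source: a wild-type (WT)
lysogen that never lyses under the experimental conditions, and a
temperature-sensitive (TS) lysogen whose prophage is induced at the start of
the experiment, committing the TS subpopulation to lysis. Lysed cells
release material that surviving cells can consume — the microscale analogue
of the viral shunt.

State variables, all in OD600-equivalent units (biomass yield Y = 1 on both
resources, time in hours):

- glucose `C_g`, the externally supplied resource,
- lysate `C_l`, an effective single pool standing in for the mixture of
  amino acids, nucleotides, and other components released by lysis,
- WT biomass `B_WT`,
- TS biomass split across `k` compartments `B_TS,1..k`.

Growth on each resource follows Monod kinetics
`mu_y(C_y) = mu_y,max * C_y / (C_y + K_S,y)`, `y ∈ {g, l}`. WT grows
additively on both resources (a deliberately simple co-limitation choice:
over the short window studied, lysate uptake adds to rather than displaces
glucose-based growth). Induction-to-lysis timing uses the linear-chain
trick: TS biomass advances through the `k` compartments at rate `k*delta`,
so the single-cell induction-to-lysis time is Erlang(k, k*delta) with mean
`1/delta` and variance `1/(k*delta^2)` — `k` tunes lysis synchrony at fixed
mean. Biomass leaving the last compartment lyses; a fraction `epsilon`
(recycling efficiency, the yield on lysate) enters `C_l`, the rest leaves
the system. Optical density is live biomass `B_WT + sum_i B_TS,i`; lysate
does not contribute.

Two variants govern whether TS compartments themselves grow on lysate
(`ModelParams.ts_lysate_growth`). The default (`False`) gives TS cells only
the glucose growth term while total biomass still draws the lysate pool
down, booking TS lysate uptake as a pure sink. We made this the default for
a structural reason: it renders a TS-only culture's biomass trajectory
independent of all three lysate parameters, which makes the staged
parametrization below exactly self-consistent (stage 2 can fit lysis
dynamics before lysate parameters exist). The `True` variant credits TS
compartments with lysate growth and closes the mass balance exactly
(`epsilon = 1` conserves total mass). Both variants are integrated by the
same code path and both pass the conservation audit, which books each
variant's sinks explicitly.

### Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `mu_g_max` | 0.7 | h⁻¹ | max growth rate on glucose |
| `K_S_g` | 0.01 | OD-equiv | glucose half-saturation (≪ C_g: near-exponential growth) |
| `mu_l_max` | 0.8 | h⁻¹ | max growth rate on lysate |
| `K_S_l` | 0.05 | OD-equiv | lysate half-saturation (≫ typical C_l: near-linear uptake) |
| `delta` | 0.9 | h⁻¹ | lysis rate (mean induction-to-lysis time ≈ 1.1 h) |
| `k` | 6 | — | lysis compartments (SD of lysis time ≈ 0.45 h) |
| `epsilon` | 0.4 | — | fraction of lysed biomass recycled into lysate |
| `C_g0` | 0.45 | OD-equiv | initial glucose = saturation OD − inoculum OD |

The best-fit values for the real experiment are not reproducible here
without the raw OD data, so the defaults were fixed once, before any tests
were written, to place the model in the experimentally reported regime: TS
biomass declines within the first hour of induction; the 19WT–81TS mix
shows partial compensation (above its 19WT control, below the 100WT
control); and the WT subpopulation's net growth rate transiently exceeds
the monoculture's by roughly ten percent (the default run peaks at +12.4%
at 2.3 h), of the same order and timing as the reported model-derived boost
(~11% near 3 h). They also coincide with the generating values used by the
parameter-recovery tests.

### Numerics

Integration uses LSODA (scipy `odeint`, stiff-capable, adaptive) at
rtol 1e-8 / atol 1e-10 with a dense default output grid (0.02 h). The
right-hand side clips small negative excursions to zero before evaluating
rates; states themselves are left untouched, so the nonnegativity tests see
the raw solver output. A numba-compiled right-hand side is used when numba
is importable; the pure-numpy implementation is the reference and the two
are kept in lockstep. Fits evaluate the solver directly at the observation
times, so "interpolate the model to the data grid" is exact by
construction. The mass-balance audit recomputes d/dt(total pool) from the
model equations at every stored grid point and adds back the booked sinks
(non-recycled lysis flux, plus TS lysate uptake in the default variant);
the result is zero to floating-point error independent of solver error.

## Staged parametrization

Residuals are log-scale, weighted by the replicate standard deviation with
a floor: `r = [ln(OD_mean) − ln(OD_model)] / max(SD, 1e-3)`. The natural
log is used (any fixed base rescales all residuals uniformly and leaves the
minimizer unchanged). Fitting proceeds in three stages, each freezing its
predecessors:

1. **Glucose kinetics** (`mu_g_max`, `K_S_g`) from the WT-only culture.
   Initial glucose is the saturation OD minus the inoculum OD of that
   culture unless configured explicitly.
2. **Lysis dynamics** (`delta`, integer `k`) from the first four time
   points (t = 0–3 h, including t = 0) of the TS-only culture. `k` is
   scanned exhaustively over {1..50} with a nested bounded 1-D optimization
   of `log10(delta)`; ties break toward smaller `k`.
3. **Lysate dynamics** (`mu_l_max`, `K_S_l`, `epsilon`) from the two mixed
   cultures, pooling residuals, so only populations that experience
   recycling inform lysate parameters.

Continuous parameters are optimized on a log10 scale (ε on its natural
[0, 1] scale) with trust-region-reflective least squares, ftol/xtol 1e-10.
Default bounds: rates ∈ [1e-4, 5] h⁻¹, `K_S_g` ∈ [1e-6, 1],
`K_S_l` ∈ [1e-2, 1], `delta` ∈ [1e-3, 10], `epsilon` ∈ [0, 1]. The raised
lower bound on `K_S_l` excludes the degenerate saturated-uptake mode
(`K_S_l → 0` makes lysate growth switch-like at any lysate level), which
growth curves cannot distinguish from the near-linear regime this system
operates in; bounds exist precisely to wall off such non-identifiable
regions. Within the admissible region, `mu_l_max` and `K_S_l` remain
strongly ridge-correlated (the data mostly constrain their ratio) — their
individual interval estimates are honest but wide.

Goodness of fit is reported as RSS plus AIC/BIC in the known-variance
Gaussian form on the standardized residuals, constants dropped:
`AIC = RSS + 2p`, `BIC = RSS + p ln n`.

Uncertainty comes from a nonparametric bootstrap: replicate columns are
resampled with replacement per mix (independently across mixes), means/SDs
recomputed, and the full three-stage fit re-run warm-started from the point
estimates; 95% CIs are the 2.5th–97.5th percentiles over draws (default
1000; the analysis scripts use 200). Refits may optionally hold the integer
`k` at its point estimate (`fix_k`), the usual treatment of a discrete
structural parameter; the calibration study below uses this mode.

## Single-cell pipeline

Mother-machine tracks are fit by OLS of ln(length) on time (minutes
converted to hours), with intercept; the rate is the slope and R² is the
squared Pearson correlation (equal to the coefficient of determination for
OLS with intercept). A perfectly constant track is assigned rate 0 with
R² = 1 (zero residual) by convention. QC applies, in this fixed order:
crop to the final 6 h of the experiment, drop tracks with fewer than 7
frames, drop tracks whose x-position ever exceeds the chamber-exit
threshold (default 20 µm = 80% of a 25 µm chamber, origin at the closed
end; cells sliding out of the field produce artifactual negative rates),
fit, and drop fits with R² < 0.95. Each rejected track carries exactly its
first-failing reason.

Condition comparisons are replicate-level: a two-way fixed-effects ANOVA
without interaction (condition + biological replicate) on the condition ×
replicate table of mean rates, then Tukey's HSD across conditions using the
ANOVA residual mean square and the studentized range distribution with
(c−1)(r−1) degrees of freedom. Tukey is implemented directly on that
residual MS because off-the-shelf pairwise-Tukey routines use the one-way
(cell-pooled) error term; at two conditions the implementation provably
reduces to the unadjusted t-comparison on the same MS, which a test checks
against scipy's t distribution.

## Synthetic data

The batch generator simulates the six preset inoculum designs — 100WT,
73WT, 19WT (WT-only controls at OD 0.01, 0.0073, 0.0019), 73WT–27TS,
19WT–81TS, 100TS (at total OD 0.01) — and draws four replicate OD
observations per hourly time point as `od * exp(N(0, od_cv))` with
`od_cv = 0.05` (multiplicative lognormal: OD errors scale with signal;
the replicate mean carries a small ~od_cv²/2 bias, noted in the generator
docs). A positivity floor of 1e-5 OD keeps observations of a fully lysed
culture positive for the log-scale residuals; it lies below every time
point the staged fits use.

The track generator emulates the observation process, not imaging physics:
per lineage slot, a cell starting at a geometrically uniform point of its
birth→2× cycle grows exponentially at a rate drawn from the condition's
truncated-at-zero normal (defaults mirror the three measured conditions:
0.54 ± 0.09, 0.61 ± 0.09, 0.62 ± 0.10 h⁻¹), divides at a fixed 4 µm
threshold (length halves, daughter continues under a new track id with a
freshly drawn rate, so between-cell dispersion includes between-generation
variation), and is observed every 5 min over 6 h with 2% multiplicative
length noise; 5% of slots drift past the chamber-exit threshold late in the
run to exercise that filter. Redrawing the rate at division also makes the
sequence of track rates i.i.d. within a condition, so the pooled pipeline
mean is an unbiased estimate of the condition mean (holding the rate fixed
across generations would length-bias the pooled mean upward by
var/mean ≈ 0.015 h⁻¹, since faster lineages contribute more tracks).

What the generators deliberately omit: replicate-level random effects
(between-replicate variation in the real data reflects media batches and
chips; synthetic replicates differ only by sampling noise, so replicate-mean
ANOVAs on synthetic cohorts show much smaller p-values than the real
experiment's), division-size noise, segmentation-error structure, additive
OD instrument noise, and residual non-lysed TS biomass. Passing tests
therefore demonstrate correctness of the estimators and procedures under
the stated noise model, not robustness to every artifact of real data.

## Calibration and problem sizes

The bootstrap calibration study runs 12 independent synthetic experiments
(4 replicates, 5% CV), each with a 200-draw bootstrap, `k` fixed at its
point estimate during refits, and checks that the 95% CIs contain the
generating values; mean per-parameter coverage over the six continuous
parameters is required to be at least 0.85 (the binomial standard error at
12 experiments is ~0.09). The single-cell closure check uses a 5,000-cell
cohort (pooled mean within 0.01 h⁻¹ of the generating 0.54). Monte-Carlo
moment checks use 10⁵ Erlang passage-time samples against a 3-standard-error
band. These sizes were chosen to keep the full suite comfortably
re-runnable on a laptop-class single core.

## Known limitations

- The lysate pool is a single effective resource with one aggregate
  half-saturation constant; real lysate is a mixture with heterogeneous
  uptake kinetics.
- No phage-particle dynamics, superinfection, spatial structure, or
  stochastic birth–death noise: strains are superinfection-immune and
  cultures well mixed, matching the experimental design, but none of this
  transfers to systems with ongoing infection cycles.
- `mu_l_max` and `K_S_l` are individually weakly identified from growth
  curves (ridge in their ratio); treat their point estimates with the
  bootstrap intervals, not alone.
- Stage 2 uses only the early TS-only window, so late-time TS behavior
  (debris, incomplete lysis) is neither modeled nor fit.
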