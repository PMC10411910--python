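# Methods

## Model

The reaction network describes constitutive transcription through a cycle of
`S` sequential promoter states, nuclear export, and degradation through `R`
sequential cytoplasmic intermediates:

```
(U0 <-> U1)   U1 -> U2 -> ... -> US -> U1 + MN
              MN -> MC1 -> MC2 -> ... -> MCR -> 0
```

| symbol | meaning | default / typical |
| --- | --- | --- |
| `S` | promoter states per synthesis cycle | 1–4 |
| `R` | cytoplasmic degradation steps | 1–4 |
| `k_A` | remodeling rate of each `U_i -> U_{i+1}` | free |
| `k_B` | synthesis rate `U_S -> U_1 + MN` | free |
| `k_C` | nuclear export rate `MN -> MC1` | free |
| `k_D` | per-step degradation rate; effective rate is `k_D / R` | `R` in effective units |
| `k_open, k_close` | optional closed-chromatin switching (`U0`) | absent |

Rates are either absolute or in *effective-lifetime units*
(`time_unit="effective_lifetime"`, which pins `k_D = R` so the effective
cytoplasmic degradation rate is 1; `ModelSpec.effective(...)` builds these).
All analysis of noise floors and inference works in effective units, so
fitted rates are interpretable as multiples of the mRNA turnover rate.

Assumptions: exactly one promoter indicator is occupied at any time (the
indicators obey the conservation law `sum_i U_i = 1`); every propensity is
first order (`rate * count(substrate)`); cells are independent and at steady
state. Nascent (transcription-site) transcripts are *outside* the model: `MN`
is mature nuclear mRNA.

Special cases: `S = 1` without chromatin is the single-rate-limiting-step
constitutive model — synthesis wait times are exponential and all mRNA counts
are exactly Poisson (Fano = 1, zero nuclear–cytoplasmic covariance).
`S = 1` with chromatin is the two-state telegraph model (Fano > 1, positive
covariance). `S >= 2` makes the wait times hypoexponential (more regular than
exponential), which is what permits Fano < 1 and negative covariance. The
covariance sign is therefore a model-free discriminator of the noise regime.

## Exact steady-state moments

Because all propensities are linear, the first- and second-moment equations of
the chemical master equation close exactly. One promoter indicator (`U1`) is
eliminated via the conservation law, making the reduced propensities affine:
`a_j(y) = w_j · y + b_j`. The reduced drift matrix `A = sum_j v_j w_j^T` is
Hurwitz for all valid specs; means solve `A mu = -b`, and the stationary
covariance solves the continuous Lyapunov equation `A C + C A^T + D = 0` with
diffusion `D = sum_j a_j(mu) v_j v_j^T`, via
`scipy.linalg.solve_continuous_lyapunov`. The eliminated row/column is
re-embedded from the conservation law. No approximation beyond floating point
is involved; a single solve takes ~0.4 ms, which is what makes analytic-ABC
and optimization loops cheap.

Cytoplasmic quantities always refer to the *total* count `C = sum_i MC_i`,
because the degradation intermediates are experimentally indistinguishable.

Derived quantities:

* `mean_expression` — closed-form means (`lambda = 1/((S-1)/k_A + 1/k_B)`;
  nuclear `lambda/k_C`, cytoplasmic `lambda R/k_D`), used as an independent
  cross-check on the moment solver.
* `min_fano` — multi-start Nelder–Mead minimization of the Fano factor over
  `log10(k_A, k_B, k_C)` in a box (default `[1e-1, 1e3]^3`), effective units;
  12 starts by default, results are box-clipped, and a run where no start
  converges is flagged with a warning.
* `export_crossover` — the export rate where nuclear and cytoplasmic Fano
  factors cross, found by a sign scan over a log grid followed by Brent
  bisection on `log10 k_C` (relative tolerance `1e-6`). Returns `None` when
  no crossing exists (e.g. `S = 1`, where both Fano factors are identically 1).

## Stochastic simulation

Gillespie's direct method, exact for this network. Copy numbers in the regime
of interest are small (means ~2–5), so no tau-leaping is used. The population
sampler runs one independent realization per cell from `(U1, zero mRNA)` and
records a single snapshot after a burn-in of 10 effective lifetimes (warning
below that), matching the snapshot nature of smFISH. The kernel is
numba-compiled and accepts a per-cell rate matrix (used by the synthetic
generator for cell-size scaling); 5×10^4 cells take ~1 s on one CPU.

## smFISH quantification

Input is tabular: one row per detected spot (image, cell, compartment,
position, amplitude) and one row per segmented cell. Spot detection, PSF
fitting and segmentation are upstream and out of scope.

* **Normalization** — amplitudes are divided by the per-image *median
  cytoplasmic* amplitude, so a typical single-molecule spot has value 1 and
  per-image gain differences cancel. Images without cytoplasmic spots cannot
  be normalized and are dropped with a warning.
* **Counting** — `spot`: one molecule per spot; `intensity`: sum of
  normalized intensities; `hybrid`: spots at or below the 95th percentile of
  cytoplasmic intensities in the same sample (replicate when present, else
  image) count as one molecule, brighter spots count as their normalized
  intensity. Hybrid counting is never below spot counting.
* **Nascent classification** — spot-to-transcription-site distances are
  bimodal on a log scale (a tight mode at the TS, a broad nucleoplasmic
  mode). Per image, the cutoff is placed at the two-class variance split
  (Otsu, default) or the KDE minimum between the top two modes; unimodal
  images fall back to a fixed 0.6 µm cutoff with a warning. Transcription
  sites just outside the nuclear mask are handled either by relabeling
  nearby cytoplasmic spots as nascent (`expand`) or by reporting the affected
  cells for exclusion (`filter`).
* **Cell filters** — length outliers beyond 4 SD of the sample mean (applied
  once, per replicate; not recomputed after exclusions); optional absolute
  width bounds (1.5–4 µm) and maximum length (16 µm) for legacy data; TS
  labeling QC (1–2 marker spots per nucleus, no cytoplasmic marker spot).
  Every exclusion is logged with the rule that triggered it.
* **Cell volume** — cylinder with hemispherical caps,
  `V = pi (w/2)^2 (L - w) + (4/3) pi (w/2)^3`.
* **Size-corrected Fano factor** — OLS of count on size gives slope `b`; the
  statistic is `(Var(count) - b^2 Var(size)) / mean(count)`, i.e. total
  variance minus the size-explained component. Invariant to rescaling sizes;
  degenerate size variance falls back to the raw Fano with a warning. CIs and
  SE are nonparametric percentile bootstrap over cells (default 10^4
  resamples; tests use smaller sizes for runtime).
* **Sliding-window Fano profile** — cells are pooled in 1 µm length windows
  moved in 0.1 µm steps. Windows are retained only in runs that satisfy the
  per-stratum thresholds (minimum cells pooled / per replicate, minimum
  consecutive windows): all = (50, 40, 20), mononucleated = (40, 30, 10),
  binucleated = (30, 20, 6).
* **Nuclear–cytoplasmic covariance** — plain sample covariance of paired
  per-cell counts (negative ⇔ sub-Poissonian), with bootstrap CI; when sizes
  are provided a size-partialled covariance (covariance of the residuals of
  both counts on size) is reported alongside, flagged as a distinct
  estimator.

## Inference

Observed data are reduced to four summaries: nuclear and cytoplasmic mean and
Fano factor (size-corrected when sizes are available). The nuclear-to-total
fraction is deliberately left out of the summary set so it remains available
as an independent check on fitted models.

ABC rejection at fixed `(S, R)`: proposals are drawn from independent
log-uniform priors on `(k_A, k_B, k_C)` over `[1e-1, 1e3]` (effective units);
the distance is Euclidean after standardizing each summary by its observed
value (scale-invariant); the smallest-distance quantile (default 1% of 10^4
proposals) is accepted. Model summaries come from the exact analytic moments,
so no per-proposal simulation is needed; an SSA backend exists for
validation. Model selection over candidate `(S, R)` pairs uses acceptance
counts at a *common absolute* tolerance under a uniform model prior; exact
ties are reported, never silently broken.

Identifiability: the export rate `k_C` is the best-identified parameter
(directly constrained by the nuclear/cytoplasmic mean ratio); `k_A` and `k_B`
are only jointly constrained through the synthesis rate and the Fano factors,
so their marginal posteriors remain broad.

## Synthetic data generator

Emulates the statistical structure the estimators assume — nothing more:

* per-cell true counts from the kinetic model at steady state (exact SSA),
  with transcription-cycle rates (`k_A`, `k_B` jointly) scaled linearly with
  cell length relative to the population median (concentration homeostasis);
* cell lengths uniform on 7–14 µm, widths ~ N(3.6, 0.2) µm clipped;
* nascent transcripts drawn separately (Poisson, scaled with size and nucleus
  count), since the kinetic model excludes nascent dynamics;
* log-normal single-molecule intensities with median exactly 1 and
  configurable CV (default 0.3), per-image gains uniform on 0.6–1.8, merged
  transcription-site spots whose intensity is the *sum* of per-molecule
  intensities;
* optional binucleated stratum (phenomenological synthesis-rate multiplier
  plus flag) and a configurable rate of TS spots mislabeled as cytoplasmic
  (nuclear-mask errors).

Not emulated: optics or image formation, spot detection/segmentation errors,
cell-cycle structure, and any specific gene's empirical distributions. The
generator's defaults are fixed study-like conditions and are not tuned to any
estimator.

`roundtrip_check` runs generate → render → count → summarize and reports
per-method counting biases against ground truth plus the size-corrected Fano
of hybrid counts against the analytic value.

## Numerical choices

* Lyapunov solve: `scipy.linalg.solve_continuous_lyapunov`, result
  symmetrized; `numpy.linalg.solve` for means.
* Optimization: Nelder–Mead on log10 rates, 12 random starts (seeded),
  `xatol 1e-5 / fatol 1e-10`, box-clipped; crossover root by `brentq`.
* SSA: numba `njit` direct method; population seeds reduced mod `2^31 - 1`.
* Bootstrap: percentile CIs, default 10^4 resamples (2×10^3 in the
  calibration acceptance test), vectorized in chunks of 2×10^3.
* Seeds: every stochastic entry point takes an explicit seed;
  `numpy.random.default_rng` with seed sequences (`[seed, k]`) separates the
  generator's population and rendering streams. All derived seeds stay below
  `2^31`.
* Default problem sizes (2×10^3-cell populations, 10^4 ABC proposals, 5×10^4
  SSA cells in validation) are package choices balancing precision against a
  single-CPU minute-scale budget.

## Known limitations

* **Photometric inflation of hybrid counting.** With per-molecule counted
  value `X = 1{I <= q95} + I·1{I > q95}` and log-normal intensities, the
  counted Fano factor is `F·E[X] + Var(X)/E[X]`. At intensity CV 0.3 this
  inflates the reference spec's cytoplasmic Fano from 0.620 to a predicted
  0.681 (verified on synthetic data), a systematic ~+3 bootstrap SEs at
  2×10^3 cells. At CV 0 the estimators are exactly calibrated. Counting total
  molecules, the derived biases at CV 0.3 are 0 (spot, cytoplasm), +4.4%
  (intensity, the log-normal mean/median gap) and +4.2% (hybrid, the tail
  above the 95th percentile).
* Spot counting undercounts nuclei wherever several nascent transcripts merge
  into one TS spot; the pipeline therefore classifies and excludes nascent
  spots before counting mature mRNA (`--include-nascent` to disable).
* The moment method requires linear propensities; nonlinear extensions
  (feedback, saturation) would need a different solver and are out of scope.
* ABC posteriors depend on the chosen summaries and tolerance; `k_A`/`k_B`
  are weakly identified (see above), and model probabilities from acceptance
  counts are approximations valid in the small-tolerance limit.
* The SSA records a single snapshot per cell; time-correlation statistics are
  only available through the (slower) trajectory recorder.
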