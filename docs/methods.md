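# Methods

## Decay data and the energy per decay

²¹¹At decays along two branches: direct α emission to ²⁰⁷Bi (branch
fraction 0.4180, Eα = 5.8695 MeV) and electron capture to ²¹¹Po
(0.5820), whose own α to stable ²⁰⁷Pb carries 7.4503 MeV with a 0.516 s
half-life. Because the daughter's half-life is ~5×10⁴ times shorter than
the parent's 7.214 h, ²¹¹Po is treated as in secular equilibrium: its α
is credited to the parent decay, giving a single branching-weighted
energy per decay,

    Ē_α = 0.4180 × 5.8695 + 0.5820 × 7.4503 = 6.79 MeV,

computed by walking the chain and weighting each α by the probability of
reaching it. The constants are implementer-sourced from ENSDF/MIRD decay
schemes and shipped as a one-branch-per-row CSV
(`src/atdosim/data/at211_chain.csv`); a config may point at an
alternative file. Only α energy is tracked — electron, photon and X-ray
emissions contribute negligibly under the short-range dose model and are
out of scope, as is full Bateman chain solving. Units are MeV, hours and
h⁻¹ throughout.

## Decay correction convention

Gamma-counter biodistribution tables are conventionally decay-corrected
to injection time, but the dose integral needs the physically decaying
curve (effective clearance = biological + physical). Every table carries
an explicit `decay_corrected` flag rather than an implicit convention,
and the dosimetry stage always converts to the uncorrected scale
(multiplying by e^(−λt), λ = ln2/7.214 h⁻¹) before fitting. The
conversion is an exact bijection, so data recorded on either scale are
handled identically.

## TAC fitting

- **Criterion.** Unweighted least squares on per-timepoint means by
  default (one curve per organ from the 3-mouse means); fitting all
  animal points is available and, with equal group sizes, yields the
  identical estimate (the pooled objective decomposes into the mean
  objective plus a constant).
- **Initialisation** is deterministic: log-linear regression of the
  positive values for the monoexponential; for the biexponential a
  coarse grid over λ₁ ∈ {0.02, 0.05, 0.1, 0.3} h⁻¹ and λ₂/λ₁ ∈ {5, 10,
  50} with A₁ matched to the observed peak, keeping the grid point with
  the smallest SSE.
- **Constraints.** All parameters are box-bounded in (10⁻⁶, 10⁴); the
  biexponential is fitted in (A₁, λ₁, δ = λ₂ − λ₁) coordinates with
  δ > 0, which enforces λ₂ > λ₁ (hence a non-negative, unimodal curve)
  as a plain bound. The degenerate λ₁ = λ₂ limit (A·t·e^(−λt)) is
  rejected as an invalid parameterisation rather than taken as a limit.
- **Covariance** is the Gauss–Newton estimate σ̂²(JᵀJ)⁻¹ with
  σ̂² = RSS/(n−p), mapped back to model coordinates through the linear
  reparameterisation. Non-convergence sets a flag on the result instead
  of raising.

The time integral runs over [0, ∞) from injection; closed forms A₀/λ and
A₁(1/λ₁ − 1/λ₂) are property-tested against adaptive quadrature.

## Dose and its uncertainty

%ID/g is already per unit tissue mass, so the per-gram AUC maps linearly
to Gy/MBq with no organ-mass table (constant 3.6×10⁹ decays·MBq⁻¹h⁻¹ ×
1.602×10⁻¹³ J/MeV × 10³ g/kg ÷ 100); a whole-organ (%ID + mass) route
exists and is asserted algebraically identical. The neck/thyroid, which
is measured whole-organ, is excluded from per-gram dosimetry.

The SE method behind a dose table is an implementation choice (the
convention in reported tables is typically unstated): the default delta
method propagates the fit covariance through the AUC gradient
(∂AUC/∂A₀ = 1/λ, ∂AUC/∂λ = −A₀/λ², and the biexponential analogues),
then through the linear dose map; the alternative is a seeded residual
bootstrap (resample residuals, refit, SD of the resulting doses;
default 2000 replicates). On the study design the two agree within ~5%.
Reported tables round Gy/MBq and Gy to one decimal; unrounded values are
always retained. Report rounding is applied to the *rounded-last*
product — note that a per-MBq value that was itself rounded to one
decimal can shift the final Gy by ±0.1 relative to rounding the
unrounded intermediate, which is why cross-checks against printed
1-decimal tables carry a ±0.1 Gy tolerance.

## Survival analysis

Kaplan–Meier, median and Mantel–Cox log-rank are implemented from their
defining formulas (the test suite cross-checks against `lifelines`).
Conventions: deaths precede censorings at tied times; the median is the
first t with S(t) ≤ 0.5 and is reported as undefined (not an error) when
the curve never reaches 0.5; no continuity correction in the log-rank;
administrative censoring at study end is an event=0 record;
"undetermined" deaths count as events by default with a config switch.
At very small n the χ² reference distribution is a coarse approximation
to the exact permutation law (granularity 1/C(n, n₁)), so exact-vs-χ²
comparisons in the tests use a loose 0.1 absolute band.

## Toxicity metrics

Baseline is the last sample at day ≤ 0. The nadir is the minimum count
in an analyte-specific window (WBC days 1–7, platelets 5–15, RBC 1–30 —
all configurable), and the decrease 100·(baseline − nadir)/baseline is
floored at 0. Decreases are computed per animal and then averaged (not
on group mean curves). Enzyme normal ranges are pure configuration with
a citation field; none are hard-coded, since published murine reference
intervals vary by strain, kit and fasting state.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *design and first-order statistics* of a
²¹¹At antibody study:

- **Biodistribution** — 6 sacrifice timepoints (0.25, 1, 4, 7, 14, 21 h)
  × 3 mice × 14 tissues; organ truths are mono/biexponential on the
  uncorrected scale with multiplicative log-normal noise (default CV
  0.15, unit mean). Defaults are calibrated so blood ≈ 14.9 %ID/g at
  21 h and liver ≈ 33.0 %ID/g at 15 min on the corrected scale in
  expectation, with the remaining organs set to give truth-implied doses
  of the magnitude typical for such a study (blood ≈ 8, liver ≈ 10,
  kidneys ≈ 3.6 Gy/MBq). These are plausible reconstructions for
  testing, not measured data.
- **Survival** — a cure-fraction mixture per arm: cured animals are
  censored at day 160; the rest draw log-normal event times
  (administratively censored at 160). Defaults: untreated median 45 d
  (n=16), cure fractions 2/16, 0.30, 11/17 and 0 across
  370/555/740/1110 kBq, the highest activity uniformly lethal from
  acute toxicity ~2 weeks post-injection.
- **Hematology** — per-animal log-normal baselines, a piecewise
  log-linear dip to a group nadir fraction (WBC nadir day 3, platelets
  day 10, recovery day 25) and CV-5% measurement noise; WBC nadir
  fractions encode decreases of 53.6/56.1/69.9% at 370/555/740 kBq and
  a 39% platelet drop at 1110 kBq.

Noise is independent across timepoints given the animal (one shared
noise stream per sacrificed animal links its organs); real inter-animal
and inter-organ correlation structure is unknown and not modelled, nor
are mechanistic tumor-growth/cell-kill links between dose and survival.
Passing tests therefore demonstrate correctness of the *estimators and
plumbing* under the assumed noise model, not validity of that model for
any particular dataset.

## Reproducibility and problem sizes

Every generator is a pure function of (truth, seed); the pipeline fans
one global seed out to per-stage substreams via `SeedSequence`, and
reruns are byte-identical. The statistical test problem sizes were
chosen to make each check decisive at modest cost: 100 random parameter
draws for AUC-vs-quadrature, 200 replicates for CI coverage (measured
0.985 for 95% intervals on the AUC; the wide 0.88–0.99 acceptance band
reflects the log-normal noise and small-n normal approximation), 12
replicate studies for full-pipeline dose recovery — a single replicate's
per-organ error at CV 15%, n = 3 is sampling-limited at roughly 5%
(1 SE), so the 10% recovery claim is asserted on the replicate mean,
with the noiseless single-study case checked exactly — and 500/200 seeds
for the survival/hematology calibration means.

## Known limitations

- Self-dose only, single energy per decay: no photon cross-dose,
  bone-marrow cellularity or microdosimetry, no human extrapolation.
- A priori model assignment; no information-criterion model selection.
- Two-sample log-rank only (no trend test, Cox regression or
  competing-risks decomposition; causes of death are descriptive).
- The cure-fraction survival generator ignores any dose–response link
  between arms beyond its per-arm parameters.
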