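# Methods

## Data model and scales

A dataset is a CpG × sample matrix of beta values β ∈ [0, 1] with a binary
phenotype (group 0 = normal/reference, group 1 = at-risk/disease). Missing
entries are `NA`/NaN; each test drops them per feature per group, and a
feature with fewer than 3 non-missing values in either group yields a
missing result (3 is the minimum for a variance) rather than an error.

Two scales are used, following each test's native formulation:

* **beta scale** — Bartlett's test, iEVORA's t re-ranking, and the
  moderated-t differential-mean baseline.
* **M-value scale**, M = log₂(β/(1−β)) — DiffVar, the joint score test, and
  the location-scale LRT scheme. β is clipped to [ε, 1−ε] with ε = 0.001
  before the logit (bounding M at ±≈9.97); the published descriptions are
  silent on saturated values, and this choice avoids infinities while
  perturbing interior values not at all. Direction labels (hyper/hypo) are
  always the sign of the group-1 − group-0 mean *beta* value, so they are
  comparable across algorithms.

## The tests

**Bartlett (BT).** Two-group Bartlett statistic referred to χ²₁; q-values;
rank by ascending P. Zero variance in both groups, or in exactly one group
(which would give an infinite statistic), is reported missing.

**iEVORA.** Same P/q-values as BT; CpGs with q < 0.05 are re-ranked by the
ascending P-value of a two-sample t-test (Welch by default — within-group
variances differ by construction for DVCs; pooled available). BT and iEVORA
therefore select identical feature sets and differ only in ranking, which
the evaluation module asserts.

**DiffVar-style.** Per sample, the absolute deviation of its M-value from
its own group's mean (absolute rather than squared by default, the more
outlier-robust convention of that framework); the deviations are compared
between groups with a moderated two-sample t-test. The variance prior
(d₀, s₀²) is fitted across features by the method of moments on
e = ln s² − ψ(df/2) + ln(df/2): trigamma(d₀/2) = var(e) − trigamma(df/2),
solved by monotone root-finding (d₀ = ∞ when the right side is ≤ 0), then
s₀² = exp(mean(e) + ψ(d₀/2) − ln(d₀/2)). This matches limma's `fitFDist`
to ≈ 4 significant digits on the same input (tested). Moderated P-values
use t with d₀ + df degrees of freedom (normal when d₀ = ∞); a failed prior
fit falls back to d₀ = ∞ with a warning. The deviations use the plain group
mean with no leave-one-out small-sample correction.

**Joint score test (J-DMDV-style).** On M-values, the location-scale model
y = μ + βx + ε, Var(ε) = σ²·exp(γx), x ∈ {0, 1}. The 2-df efficient score
statistic for H₀: β = γ = 0 with (μ, σ²) profiled out decouples into a mean
part n₀n₁(ȳ₁−ȳ₀)²/(Nσ̂²) and a variance part 2N·U_γ²/(n₀n₁) with
U_γ = ½[SS₁/σ̂² − n₁]; their sum is referred to χ²₂. This is a concrete
instantiation of a joint mean/variance score test in a regression framework;
equivalence to any specific published variant is not claimed. Note that the
variance score uses squared residuals, so — unlike a Levene-type test — it
remains highly sensitive to outlier-driven (type-2) DV; the benchmark
reflects this.

**Location-scale LRT scheme (GAMLSS-style).** Three nested Gaussian fits
per feature with closed-form MLEs: M0 common mean/variance, M1 group means/
common variance, M2 group means and variances. LRT1 = 2(ℓ₁−ℓ₀) ~ χ²₁ tests
the mean; LRT2 = 2(ℓ₂−ℓ₁) ~ χ²₁ tests variance given the mean; there is no
variance-only-vs-null comparison. Each P-value set gets its own q-values; a
feature is significant if either q < 0.05, and the significant set is
ranked by the variance (DV) P-value. Closed-form Gaussian MLEs are used
rather than iterative additive fitting — with a single binary covariate the
two coincide.

**Moderated t baseline.** The same empirical-Bayes machinery applied to
group-mean-centered beta values: the differential-*mean* test whose
genome-wide silence on early-stage data motivates DV analysis. Beta values
(not M-values) are used, matching the convention for the Bartlett branch.

## Q-values

π̂₀(λ) = #{p > λ}/(n(1−λ)) on λ = 0.05…0.95 (step 0.05), smoothed by a
degree-3 polynomial in λ and evaluated at λ = 0.95, clamped to [1/n, 1]
(the floor prevents q collapsing to 0 under dense signal; the cubic stands
in for the original spline smoother — the difference is second-order at
these feature counts). q-values are the step-up transform
q₍ᵢ₎ = min_{j≥i} π̂₀·n·p₍ⱼ₎/j; with π̂₀ = 1 this is exactly
Benjamini–Hochberg (tested against statsmodels). Fewer than 100 P-values →
π̂₀ = 1.

## Simulator

Defaults are the benchmark study conditions: 6000 CpGs × (50 + 50) samples;
600 true DVCs, 200 per type; null and normal-group values ~ Beta(10, 90)
(mean 0.1, sd ≈ 0.03); altered disease samples ~ Beta(6, 4) (mean 0.6, sd
≈ 0.15, a mean gain of ≈ 0.5); type-1a alters all 50 disease samples,
type-1b a random 20, type-2 a random 3. Altered subsets are drawn
independently per feature (the neutral reading of a stochastic outlier
process). One `numpy` generator seeded once drives all randomness, so a
dataset is bit-reproducible from its seed. Only hypermethylation is
generated by default — the beta scale is symmetric under β → 1−β, so
nothing is lost — and `direction="hypo"` produces the mirrored datasets for
direction-handling tests. A type-3 pattern (bidirectional discoordinated
outliers) can be requested explicitly; since a base near β = 0.1 leaves no
room for downward outliers, type-3 features sit on a Beta(50, 50) base with
twice the type-2 outlier count deviating up or down at random. It is
excluded from default truth labels and from the benchmark.

What the simulator does *not* emulate: probe-type effects, batch and
cell-composition structure, spatial correlation among CpGs, and realistic
genome-wide distributions of methylation levels. Passing benchmarks on this
generator shows the algorithms' relative operating characteristics under
the stated beta-mixture model, not their absolute performance on arrays.

## Taxonomy

A CpG with Bartlett q below the FDR cut is typed from its t-test P-value:
t_p > 0.05 → type-2; otherwise type-1, subdivided into 1a if t_p < bt_p
(mean dominates) else 1b. Boundaries: t_p exactly at α counts as type-1
(the type-2 rule requires strict non-significance); t_p exactly equal to
bt_p counts as type-1b ("more significant" read strictly). Type-3 has no
published decision rule and is not classified.

## Evaluation

**Benchmark.** Run r uses seed base_seed + r; five measures per algorithm
per run: overall and per-type sensitivity at estimated FDR < 0.05, and the
true FDR (fraction of calls that are ground-truth null; 0/0 → 0 so run
averages stay defined). FDR rather than FPR, since FDR = 1 − PPV is the
confidence that a call is real. The packaged acceptance checks use 25 runs
(the benchmark's means are stable to ±0.01 at that depth); the full design
is 100 runs via `run_benchmark(..., n_runs=100)`.

**Progression PPV.** Top-k ranked discovery features (filtered to the
requested direction, determined by the sign of the discovery mean
difference), two-sample Welch t per feature on validation beta values, and
PPV = fraction with t > 1.96 (hyper) or t < −1.96 (hypo). The 1.96 cut is
deliberately uncorrected for multiple testing: at validation the false
*negative* rate is the greater danger, and the same criterion is applied to
every algorithm. Features absent from the validation matrix are dropped
from numerator and denominator. The packaged two-stage check validates
discovery seeds against independent datasets with the same truth layout
but more altered samples per true CpG (35 of 50 for type-1b, 10 for
type-2) — a synthetic stand-in for profiling a later disease stage.

## Numerical notes and limitations

* Bartlett/t statistics, score statistics, and LRTs are fully vectorized
  over features with NaN-aware group summaries; ties in every ranking are
  broken by input feature order, making all rankings deterministic.
* LRT values are clamped at 0 against floating-point negativity from the
  nesting identity.
* Bartlett's test is anti-conservative under non-normality. Even on
  Beta(10, 90) null data its realized FDR at q < 0.05 runs ≈ 0.09, and a
  minority of all-null datasets yield a handful of false calls; on
  heavy-tailed (t₃) data its null P-values are strongly inflated. This is
  intrinsic to the method — iEVORA inherits the selected set and mitigates
  only the ranking — and is the trade-off against the robust tests' loss of
  type-2 power.
* The comparator implementations are faithful to their published
  *descriptions* (scale, deviation type, nesting structure, significance
  rules) but are independent reimplementations; the joint score test in
  particular is one defensible instantiation, and its outlier sensitivity
  need not match the original software's behavior.
* Two groups only, no covariates, no continuous phenotypes; no array
  preprocessing or probe annotation.
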