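# Methods

## The model

`debipm` implements a dynamic energy budget integral projection model
(DEB-IPM): a length-structured annual projection model for a population of
ectotherm females whose vital-rate functions derive from the Kooijman–Metz
simplification of dynamic energy budget theory. The state variable is body
length L (cm); the projection interval is one year. The number density
N(L, t) evolves as

    N(L', t+1) = ∫_Ω [ D(L', L) R(L) + G(L', L) S(L) ] N(L, t) dL

over the length domain Ω, with four kernel functions built from eight
species-level traits and a feeding environment:

* **Survival** S(L): exp(−μ_j) for juveniles (L < L_p), exp(−μ_a) for
  adults, and 0 above the starvation length L_m·E(Y)/κ, where maintenance
  (∝ L³) outstrips the κ-share of assimilation (∝ L²). At the conventional
  κ = 0.8 the starvation length is exactly 1.25 × the ultimate length
  L_∞ = L_m·E(Y), so at a *constant* feeding level no individual ever
  starves — κ bites only when conditions deteriorate.
* **Growth** G(L', L): Gaussian around a discrete von Bertalanffy step
  toward L_∞, mean L·e^(−r_B) + (1 − e^(−r_B))·L_∞, with variance
  (1 − e^(−r_B))²·L_m²·σ(Y)² induced by among-individual feeding
  stochasticity; individuals above L_∞ neither grow nor shrink.
* **Reproduction** R(L): 0 before puberty; E(Y)·R_m·L²/L_m² for mature
  lengths up to L_∞; between L_∞ and the starvation length the
  reproduction share also absorbs the maintenance deficit,
  (R_m/(1−κ))·[E(Y)·L² − κ·L³/L_m]/L_m², which joins the middle branch
  continuously at L_∞ and reaches zero exactly at the starvation length.
  The division by L_m² in the third branch is required for that continuity
  and for dimensional consistency with the middle branch, and is applied
  throughout.
* **Parent–offspring** D(L', L): offspring lengths are Gaussian around a
  parent-independent mean L_b with a small standard deviation
  (default 1% of L_b).

The adult survival band is allowed to extend above L_m up to the
starvation length. When E(Y) > κ the reproduction function is defined on
(L_∞, L_m·E(Y)/κ], which exceeds L_m; truncating survival at L_m would put
a death cliff inside the reproductive band, so the starvation length is
used as the single upper bound of life.

## Input traits and environment

| symbol | meaning | units | typical range |
|---|---|---|---|
| κ | assimilation fraction to respiration/growth | — | 0.8 by convention |
| L_b, L_p, L_m | length at birth, puberty, maximum | cm | 0 < L_b < L_p < L_m |
| μ_j, μ_a | juvenile / adult mortality rate | yr⁻¹ | 0.02–2 |
| r_B | von Bertalanffy growth rate | yr⁻¹ | 0.02–2 |
| R_m | maximum reproduction rate | yr⁻¹ | 0.5–10⁶ |
| E(Y) | mean experienced feeding level | — | (0, 1]; model feasible iff E(Y) ≥ κ·L_p/L_m |
| σ(Y) | feeding-level s.d. | — | default 0.1 (no published value; all outputs record the value used) |
| σ_Lb | offspring-length s.d. | cm | default 0.01·L_b ("very small") |

## Discretization

Ω = [L_b − 3σ_Lb (floored at a small positive length), max(L_m, L_m·E(Y)/κ)]
is divided into 200 equal-width bins by default (`n_bins` configurable).
Three numerical choices matter:

1. **Bin-integrated Gaussian columns.** G and D columns are Gaussian CDF
   differences at the bin edges rather than midpoint densities. The
   offspring kernel is far narrower than a bin for most species; midpoint
   sampling of such kernels is badly conditioned, bin integration is exact.
2. **Bin-averaged piecewise rates.** S and R are averaged exactly (analytic
   overlap fractions for the piecewise-constant S; Gauss–Legendre on the
   polynomial pieces of R) over each bin, so branch knots are resolved
   below bin width.
3. **Puberty on a bin edge.** The bin width is nudged upward so L_p falls
   exactly on an edge: every bin is purely juvenile or purely adult.
   Without this, the bin straddling L_p carries a mixture of μ_j and μ_a
   and the discretization error in λ is first-order in bin width; with it,
   λ at 200 bins agrees with 400 bins to within 0.5% across the synthetic
   panel (worst case 0.42%).

Columns of G and D are renormalized to unit mass (no eviction of
probability at the domain edges). Because the lower bound truncates the
offspring Gaussian at 3σ, about 0.13% of its mass always lies below Ω; a
`MassEvictionWarning` reports the lost fraction whenever it exceeds 1e-6
before renormalization. Zero-variance growth columns (σ(Y) = 0, or source
lengths above L_∞) are unit point masses at the bin nearest the expected
length, ties resolved to the lower bin.

## Demographic outputs

From A = V + G·S (V = D·R): λ and the stable length distribution w from
the dominant eigenpair (dense eigendecomposition; the dominant eigenvalue
is asserted real to 1e-10), reproductive values v with v·w = 1, damping
ratio λ₁/|λ₂|. The fundamental matrix N = (I − GS)⁻¹ gives expected years
spent per bin; GS is strictly substochastic so N always exists. R0 is the
dominant eigenvalue of the next-generation matrix F = V·N, and
T = log(R0)/log(λ) (undefined and flagged at λ = 1). N is built from GS,
not from S alone: in a length-structured model "years spent in a state"
requires the survival-with-growth transition.

The age-from-stage life table pushes the offspring length distribution
through GS: l_x = Σ n_x, m_x = Σ(V n_x)/l_x, truncated at l_x < 1e-9
(configurable) with a hard cap of 5000 ages. An upper summation bound "at
the mean life expectancy" is not executable for a real-valued expectancy;
tolerance truncation is the operational replacement.

Nine derived traits: generation time T; Keyfitz entropy
H = −Σ log(l_x)l_x / Σ l_x (1 for constant mortality, <1 rising, >1
falling); age at maturity L_α; progressive/retrogressive growth γ/ρ
(w-weighted sub/super-diagonal column mass of G; rows are destinations, so
progressive = below-diagonal); mean recruitment φ (w-weighted column sums
of V); degree of iteroparity S (CV of the age-at-reproduction distribution
weighted by f_x = l_x·m_x; 0 = semelparous); R0; mature life expectancy
L_ω; plus the mean life expectancy η_e.

**Conditional versus unconditional expectancies.** L_α and η_e default to
conditioning on reaching maturity: L_α is the mean first-passage age into
the adult band among individuals that do mature (computed from the
juvenile-restricted fundamental matrix and the maturation probabilities),
and η_e adds the remaining expectancy from the length distribution at
maturation. Under this reading the classical identity η_e = L_α + L_ω is
exact up to the spread of lengths at maturation (≤ 5% across the synthetic
panel; typically ≪ 1%). The unconditional variants
(`conditional=False`) are the raw expected time spent as a juvenile and
the plain life expectancy from the birth bin; they satisfy
η_e = L_α + l_α·L_ω instead, which diverges from the identity whenever
survival to maturity l_α is appreciably below one. The conditional default
also matches the plain reading of "the age at which an average individual
*becomes reproductive*" — individuals that never do are not averaged in.

R0 is reported from the F-matrix eigenvalue, with Σ l_x·m_x from the life
table as an independent cross-check; the two are flagged if they differ by
more than 1% relative with an absolute floor of 1e-6 (a purely relative
test is ill-posed as R0 → 0: species whose survival-to-reproduction falls
below the life-table truncation have R0 of order 1e-7 that the truncated
sum cannot resolve, though both routes agree it is zero to several decimal
places).

## Elasticities, feasibility, sweeps

Elasticities of λ to each of the eight input traits are central finite
differences with the whole model rebuilt at θ(1 ± step), step 1% by
default: e_θ = (λ₊ − λ₋)/(2·step·λ₀). λ is smooth in every trait away from
the feasibility boundary; a perturbation that breaks the trait ordering or
feasibility is flagged rather than evaluated. κ is perturbed only where it
appears explicitly (starvation threshold, post-L_∞ reproduction branch);
L_m and R_m are *not* co-perturbed even though energy-budget theory makes
both proportional to functions of κ — they are measured quantities here,
not derived ones.

A parameter set is feasible at feeding level E(Y) iff the starvation
length is at least the puberty length, i.e. E(Y) ≥ κ·L_p/L_m; below that,
starvation empties the reproductive band. Feasibility is monotone in E(Y),
and λ is non-decreasing in E(Y). Note feasibility does not guarantee a
maturation *path*: when L_∞ < L_p growth tops out below puberty and only
the Gaussian tail (if any) matures; derived traits then carry NaN/flags.

## Validation statistics

Predictions (generation time, longevity L_α + L_ω, age at maturity) are
regressed on caller-supplied observed values through the origin
(y ~ x, predictions on observations): slope Σxy/Σx², slope s.e. with n−1
residual degrees of freedom, 95% CI as slope ± 2 s.e., RMSE, and R² in two
conventions — about the mean of y (default; no-intercept fits can then
have small R² at near-unit slopes) and about zero (`r2_origin`). The error
rate is RMSE divided by the largest observed value; ±2·RMSE is the nominal
95% observation band under Gaussian residuals. Species infeasible at a
feeding level are excluded from that level's fit and counted. Observed
values are never fetched from anywhere; helpers take the median of a
reported range and the mean of a series.

## Closed-form trait estimators

For data-poor species (the elasmobranch workflow):
r_B = −log(1 − 0.95)/t_max (the named constant 0.95 is the fraction of L_∞
assumed reached by the age of longevity); R_m = (c·n)/i with c the mean
clutch size (or the mean of reported min/max pup counts), n litters per
year, i the remigration interval; μ_a = 2/(t_max + a); survival to
maturity l_α = e^(−μ_a(t_max − a)); μ_j = −log(l_α)/a; total-to-fork
length conversion by a caller-supplied scalar. Competing literature values
are combined by taking the median within the highest-priority source tier
(tiers are caller-supplied labels).

## The synthetic species panel

`generate_fixture` emulates the eight-trait schema so every analysis runs
without the deposited dataset: L_m log-uniform over 1–1000 cm, L_b uniform
over 5–30% of L_m, L_p uniform over 1.2–3 × L_b capped below L_m, the
three rates log-uniform over 0.02–2 yr⁻¹, R_m log-uniform over
0.5–10⁶ yr⁻¹, κ fixed at 0.8 (optionally jittered over 0.7–0.9), with
18 order labels mirroring the taxonomic breadth of the real table. These
ranges span fish, reptiles, amphibians and invertebrates, but the draws
are independent across traits; real species show strong trait covariation
(slow growers are long-lived and low-fecund), so panel summaries such as
the fraction of species with λ > 1 characterise the model's behaviour over
the trait space, not any real assemblage. Passing tests therefore
demonstrate internal correctness and the model's qualitative response to
feeding level, not agreement with field observations — that comparison
requires caller-supplied observed values through the validation module.

## Problem sizes and tolerances

Tests and the acceptance script use a 50–60 species panel at 200 mesh bins
(400 for the convergence check), life-table truncation 1e-9 with a 5000-age
cap, elasticity step 1%, and 200 replicates of 30 pairs for regression
coverage. The panel-wide checks they compute: dual-R0 agreement within 1%
(floor 1e-6), η_e decomposition within 5%, λ(200) vs λ(400) within 0.5%,
Keyfitz H within 3% of 1 under constant mortality, λ monotone over
E(Y) ∈ {0.5, 0.7, 0.9}, CI coverage ≥ 90%.

## Known limitations

* No temperature dependence; environmental change is expressed through
  E(Y) only, and only constant (non-stochastic) feeding levels are
  modelled — the regime where κ genuinely matters (feeding time series)
  is out of scope.
* One-sex (female), single life cycle; no size-dependent adult mortality
  other than starvation.
* T = log(R0)/log(λ) is the replacement-time convention, which can differ
  from cohort-based generation-time measurements.
* The iteroparity index uses the l_x·m_x-weighted age distribution; other
  weightings (m_x only) exist in the literature.
* Header alias matching for the trait CSV covers the documented symbol and
  ASCII dialects; genuinely novel headers must be added to the alias map.
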