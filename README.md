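# debipm

Dynamic energy budget integral projection models (DEB-IPMs) for
ectotherm demography.

Most structured population models need long-term individual-level data.
A DEB-IPM instead needs only **eight life-history traits** per species —
the energy-allocation fraction κ, lengths at birth/puberty/maximum
(L_b, L_p, L_m, cm), juvenile and adult mortality rates (μ_j, μ_a,
yr⁻¹), the von Bertalanffy growth rate (r_B, yr⁻¹) and the maximum
reproduction rate (R_m, yr⁻¹) — because its survival, growth,
reproduction and parent–offspring kernels all follow from the
Kooijman–Metz energy budget. That makes it usable for data-poor species
and directly comparable across taxa. This package is for comparative
demographers and conservation ecologists who want to turn such trait
tables into population predictions.

Given a trait record and an experienced feeding level E(Y) ∈ (0, 1],
`debipm` builds the annual projection kernel

    N(L', t+1) = ∫_Ω [ D(L', L) R(L) + G(L', L) S(L) ] N(L, t) dL

discretized as a 200 × 200 matrix **A** = **V** + **GS**, and computes:

* population growth rate λ (dominant eigenvalue) and damping ratio
  λ₁/|λ₂| (demographic resilience);
* nine derived life-history traits: generation time T = log R₀/log λ,
  Keyfitz entropy H, age at maturity L_α, progressive/retrogressive
  growth γ/ρ, mean recruitment φ, degree of iteroparity S, net
  reproductive rate R₀ (eigenvalue of **F** = **V**(**I** − **GS**)⁻¹,
  cross-checked against Σ l_x m_x), mature life expectancy L_ω, plus the
  mean life expectancy η_e = L_α + L_ω;
* elasticities of λ to each of the eight input traits, feeding-level
  sweeps and feasibility checks (the model runs iff E(Y) ≥ κ·L_p/L_m);
* observed-versus-predicted validation statistics (no-intercept
  regression, ±2 SE confidence intervals, RMSE, error rates);
* closed-form trait estimators for data-poor species (growth rate from
  longevity, mortality rates from longevity and age at maturity, R_m
  from clutch data).

Trait tables use a 23-column CSV schema (one species per row, taxonomy +
eight traits + provenance), read with both symbol-style ("κ", "μ_j_")
and ASCII ("kappa", "mu_j") headers. A seeded generator synthesises
schema-valid tables so everything runs without any download.

## Worked example

```python
from debipm import (SpeciesTraits, Environment, build_kernels,
                    core_demography, derived_traits)

turtle = SpeciesTraits(record_id="EX1", kappa=0.8, L_b=30, L_p=100,
                       L_m=200, mu_j=0.2, mu_a=0.1, r_B=0.2, R_m=5)
env = Environment(E_Y=0.9)          # well fed; sigma_Y defaults to 0.1

k = build_kernels(turtle, env)      # 200x200 projection matrix
core = core_demography(k)
res = derived_traits(k, core)
print(f"lambda = {core.lam:.4f}, damping = {core.damping:.4f}")
print(f"R0 = {res.R0:.2f}, T = {res.T:.2f} yr, H = {res.H:.3f}")
print(f"L_alpha = {res.L_alpha:.2f} yr, L_omega = {res.L_omega:.2f} yr, "
      f"eta_e = {res.eta_e:.2f} yr")
```

prints

```
lambda = 1.2830, damping = 1.4179
R0 = 13.62, T = 10.48 yr, H = 1.155
L_alpha = 3.65 yr, L_omega = 10.51 yr, eta_e = 14.16 yr
```

Read: this population grows 28% per year when well fed; a newborn female
that survives to maturity does so at age ~3.6 and can expect ~10.5
further years, leaving R₀ ≈ 13.7 recruits over a ~10.5-year generation;
H > 1 says mortality risk falls with age (high juvenile mortality).

The same analyses are available from the shell:

```sh
debipm validate species.csv
debipm traits species.csv --out traits.csv --e-y 0.9
debipm sweep species.csv --out sweep.csv --grid 0.5,0.7,0.9
debipm elasticity species.csv --out elas.csv --e-y 0.9
debipm derive raw_observations.csv --out derived_rows.csv
debipm regress species.csv observations.csv --out regress.csv
```

Every output embeds the resolved configuration and package version as
`#` comment lines; reruns with the same configuration are byte-identical.

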