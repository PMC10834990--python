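"""Trait elasticities, feeding-level sweeps and feasibility checks.

Because every DEB-IPM shares the same eight-trait structure, the
sensitivity of the population growth rate to each input trait is well
defined across species: the elasticity of lambda to trait theta is the
proportional change in lambda per proportional change in theta,
estimated by a central finite difference with the whole model (mesh
included) rebuilt at theta*(1 +/- step).

A model is *feasible* at feeding level E(Y) when some length can both
survive and reproduce, i.e. the starvation length L_m*E(Y)/kappa is not
below the puberty length; the analytic feasibility boundary is
E(Y) = kappa * L_p / L_m.  Feasibility is monotone in E(Y), and lambda
is non-decreasing in E(Y) (more food never hurts in this model), which
the feeding sweep exposes per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ipm import DEFAULT_N_BINS, build_kernels, core_demography
from .kernels import Environment
from .life_history import LifeHistoryResult, derived_traits
from .traits import SpeciesTraits, validate_traits

__all__ = [
    "TRAIT_NAMES",
    "ElasticityResult",
    "SweepResult",
    "elasticity",
    "all_elasticities",
    "feasibility",
    "feasibility_boundary",
    "feeding_sweep",
]

#: The eight perturbable input traits.
TRAIT_NAMES = ["kappa", "L_b", "L_p", "L_m", "mu_j", "mu_a", "r_B", "R_m"]


@dataclass
class ElasticityResult:
    trait_name: str
    elasticity: float
    step: float
    lam_base: float
    flags: list[str] = field(default_factory=list)


@dataclass
class SweepResult:
    E_Y_grid: list[float]
    lam_values: list[float]            # NaN where infeasible
    feasible_flags: list[bool]
    traits_per_level: list[LifeHistoryResult | None]
    min_feasible_E_Y: float | None


def _lambda_for(t: SpeciesTraits, env: Environment, n_bins: int) -> float:
    return core_demography(build_kernels(t, env, n_bins)).lam


def feasibility(t: SpeciesTraits, env: Environment) -> tuple[bool, str]:
    """Can any length both survive and reproduce at this feeding level?

    Infeasible exactly when the starvation length L_m*E(Y)/kappa falls
    below the puberty length L_p: starvation then kills individuals
    before they can mature, so the reproductive band is empty.
    """
    starv = t.L_m * env.E_Y / t.kappa
    if starv < t.L_p:
        return False, (
            f"starvation length {starv:.4g} < puberty length {t.L_p:.4g} "
            f"(need E(Y) >= kappa*L_p/L_m = {feasibility_boundary(t):.4g})")
    return True, "feasible"


def feasibility_boundary(t: SpeciesTraits) -> float:
    """Smallest feeding level at which the model runs: kappa*L_p/L_m."""
    return t.kappa * t.L_p / t.L_m


def elasticity(t: SpeciesTraits, env: Environment, trait_name: str,
               step: float = 0.01,
               n_bins: int = DEFAULT_N_BINS) -> ElasticityResult:
    """Central-difference elasticity of lambda to one input trait.

    The full model is rebuilt at theta*(1 - step) and theta*(1 + step);
    elasticity = (lambda_+ - lambda_-)/(2 * step * lambda_0).  kappa is
    perturbed only where it appears explicitly (starvation threshold and
    the post-ultimate reproduction branch); L_m and R_m are deliberately
    *not* co-perturbed even though energy-budget theory links them —
    users expecting the proportionality R_m ~ (1 - kappa) must perturb
    those traits themselves.  A perturbation that breaks the trait
    ordering or feasibility is flagged and returns NaN.
    """
    if trait_name not in TRAIT_NAMES:
        raise ValueError(f"unknown trait {trait_name!r}; one of {TRAIT_NAMES}")
    if not 0 < step <= 0.1:
        raise ValueError("step must be in (0, 0.1]")
    lam0 = _lambda_for(t, env, n_bins)
    flags: list[str] = []
    lams = []
    for sign in (+1.0, -1.0):
        tp = replace(t, **{trait_name: getattr(t, trait_name) * (1.0 + sign * step)})
        bad = validate_traits(tp)
        if bad:
            flags.append(f"infeasible_perturbation({sign:+g}): {bad[0]}")
            lams.append(np.nan)
            continue
        ok, reason = feasibility(tp, env)
        if not ok:
            flags.append(f"infeasible_perturbation({sign:+g}): {reason}")
            lams.append(np.nan)
            continue
        lams.append(_lambda_for(tp, env, n_bins))
    el = (lams[0] - lams[1]) / (2.0 * step * lam0)
    return ElasticityResult(trait_name=trait_name, elasticity=float(el),
                            step=step, lam_base=lam0, flags=flags)


def all_elasticities(t: SpeciesTraits, env: Environment, step: float = 0.01,
                     n_bins: int = DEFAULT_N_BINS) -> dict[str, ElasticityResult]:
    """Elasticity of lambda to each of the eight input traits."""
    return {name: elasticity(t, env, name, step=step, n_bins=n_bins)
            for name in TRAIT_NAMES}


def feeding_sweep(t: SpeciesTraits, grid, env_base: Environment,
                  n_bins: int = DEFAULT_N_BINS,
                  with_traits: bool = True) -> SweepResult:
    """Run the model over a grid of feeding levels.

    Per level: feasibility, lambda and (optionally) the full derived
    trait set; infeasible levels carry NaN/None results.  The smallest
    feasible level on the grid is reported.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("feeding-level grid must be non-empty")
    if any(not 0 < g <= 1 for g in grid):
        raise ValueError("feeding levels must lie in (0, 1]")
    lams, feas, results = [], [], []
    for g in sorted(grid):
        env = replace(env_base, E_Y=g)
        ok, _reason = feasibility(t, env)
        feas.append(ok)
        if not ok:
            lams.append(np.nan)
            results.append(None)
            continue
        k = build_kernels(t, env, n_bins)
        core = core_demography(k)
        lams.append(core.lam)
        results.append(derived_traits(k, core) if with_traits else None)
    min_feasible = next((g for g, ok in zip(sorted(grid), feas) if ok), None)
    return SweepResult(E_Y_grid=sorted(grid), lam_values=lams,
                       feasible_flags=feas, traits_per_level=results,
                       min_feasible_E_Y=min_feasible)
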