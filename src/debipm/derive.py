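"""Closed-form trait estimators for data-poor species.

These are the estimators used to populate DEB-IPM input traits for
species (typically elasmobranchs) where only longevity, age at maturity,
clutch data and lengths are reported:

* von Bertalanffy growth rate from longevity, assuming an individual
  reaches 95% of its ultimate length by age t_max:
  r_B = -log(1 - 0.95)/t_max;
* maximum reproduction rate R_m = (c * n)/i from mean clutch size c,
  litters per year n and remigration interval i (years);
* adult mortality as the inverse of the mean of longevity and age at
  maturity: mu_a = 2/(t_max + a);
* survival to maturity l_alpha = exp(-mu_a (t_max - a)) and from it the
  juvenile mortality rate mu_j = -log(l_alpha)/a;
* total-to-fork length conversion by a caller-supplied scalar.

A small priority-tier aggregator reproduces the "take the median of the
values in the highest-priority source group" rule used when several
literature values compete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traits import SpeciesTraits, validate_traits

__all__ = [
    "RawObservations",
    "VB_LENGTH_FRACTION",
    "rB_from_longevity",
    "max_reproduction",
    "adult_mortality",
    "survival_to_maturity",
    "juvenile_mortality",
    "total_to_fork_length",
    "median_by_priority",
    "derive_species_traits",
]

#: Fraction of the ultimate length assumed to be reached by age t_max in
#: the longevity-based growth-rate estimator.
VB_LENGTH_FRACTION = 0.95


@dataclass(frozen=True)
class RawObservations:
    """Field observations feeding the closed-form estimators.

    t_max: longevity (years); a: age at maturity (years); c: mean clutch
    size (offspring); n: litters per year; i: remigration interval
    (years, >= 1); TL: total length (cm); fork_factor: total-to-fork
    length scalar in (0, 1].
    """

    t_max: float
    a: float
    c: float = np.nan
    n: float = np.nan
    i: float = 1.0
    TL: float = np.nan
    fork_factor: float = 1.0

    def __post_init__(self):
        if not self.t_max > self.a > 0:
            raise ValueError(
                f"need t_max > a > 0, got t_max={self.t_max}, a={self.a}")
        if not 0 < self.fork_factor <= 1:
            raise ValueError(f"fork_factor must be in (0,1], got {self.fork_factor}")
        if self.i < 1:
            raise ValueError(f"remigration interval must be >= 1, got {self.i}")


def rB_from_longevity(t_max: float) -> float:
    """Growth rate such that 95% of L_inf is reached by age t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    return -np.log(1.0 - VB_LENGTH_FRACTION) / t_max


def max_reproduction(c: float, n: float, i: float,
                     pups_min: float | None = None,
                     pups_max: float | None = None) -> float:
    """Offspring per year: (c * n)/i.

    When a min/max pup-count range is supplied instead of a mean clutch
    size, their mean is used for c.
    """
    if pups_min is not None and pups_max is not None:
        c = 0.5 * (pups_min + pups_max)
    if not (c > 0 and n > 0):
        raise ValueError("clutch size and litters per year must be > 0")
    if i <= 0:
        raise ValueError("remigration interval must be > 0")
    return (c * n) / i


def adult_mortality(t_max: float, a: float) -> float:
    """Inverse of the mean of longevity and age at maturity."""
    if not t_max > a > 0:
        raise ValueError(f"need t_max > a > 0, got t_max={t_max}, a={a}")
    return 2.0 / (t_max + a)


def survival_to_maturity(mu_a: float, t_max: float, a: float) -> float:
    """l_alpha = exp(-mu_a (t_max - a))."""
    return float(np.exp(-mu_a * (t_max - a)))


def juvenile_mortality(l_alpha: float, a: float) -> float:
    """mu_j = -log(l_alpha^(1/a)) = -log(l_alpha)/a."""
    if not 0 < l_alpha <= 1:
        raise ValueError(f"l_alpha must be in (0,1], got {l_alpha}")
    if a <= 0:
        raise ValueError("a must be > 0")
    return float(-np.log(l_alpha) / a)


def total_to_fork_length(TL: float, fork_factor: float) -> float:
    """Convert total length to fork length by a species-specific scalar."""
    if TL <= 0:
        raise ValueError("TL must be > 0")
    if not 0 < fork_factor <= 1:
        raise ValueError("fork_factor must be in (0,1]")
    return TL * fork_factor


def median_by_priority(candidates: list[tuple[str, float]],
                       priority: list[str]) -> float:
    """Median of the values in the highest-priority tier present.

    ``candidates`` is a list of (tier_label, value); ``priority`` orders
    the tier labels from most to least trusted.  Values in tiers absent
    from ``priority`` are ignored.
    """
    for tier in priority:
        vals = [v for lab, v in candidates if lab == tier and np.isfinite(v)]
        if vals:
            return float(np.median(vals))
    raise ValueError("no candidate value in any prioritised tier")


def derive_species_traits(record_id: str, raw: RawObservations,
                          L_b: float, L_p: float, L_m: float,
                          kappa: float = 0.8,
                          lengths_are_total: bool = False,
                          **metadata) -> SpeciesTraits:
    """Chain the estimators into a full schema record.

    Lengths may be supplied as total lengths (converted to fork lengths
    with ``raw.fork_factor`` when ``lengths_are_total``).  The resulting
    record is checked against the schema invariants; violations raise.
    """
    if lengths_are_total:
        L_b = total_to_fork_length(L_b, raw.fork_factor)
        L_p = total_to_fork_length(L_p, raw.fork_factor)
        L_m = total_to_fork_length(L_m, raw.fork_factor)
    mu_a = adult_mortality(raw.t_max, raw.a)
    l_alpha = survival_to_maturity(mu_a, raw.t_max, raw.a)
    mu_j = juvenile_mortality(l_alpha, raw.a)
    rec = SpeciesTraits(
        record_id=record_id, kappa=kappa, L_b=L_b, L_p=L_p, L_m=L_m,
        mu_j=mu_j, mu_a=mu_a, r_B=rB_from_longevity(raw.t_max),
        R_m=max_reproduction(raw.c, raw.n, raw.i), **metadata)
    violations = validate_traits(rec)
    if violations:
        raise ValueError(f"derived record invalid: {violations}")
    return rec
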