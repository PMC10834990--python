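"""Scalar DEB-IPM kernel functions.

The DEB-IPM projects a length-structured population of females one year
forward through four functions derived from the Kooijman–Metz energy
budget: survival S(L), the Gaussian growth kernel G(L', L) around a
discrete von Bertalanffy mean, per-capita reproduction R(L), and the
parent–offspring size kernel D(L', L).

The environment enters through the experienced feeding level Y, Gaussian
with mean E(Y) in (0, 1] and standard deviation sigma(Y).  Two derived
lengths control the life cycle at a constant feeding level: the ultimate
length L_inf = L_m * E(Y) that growth converges to, and the starvation
length L_m * E(Y) / kappa above which maintenance outstrips assimilation
and survival drops to zero.  With the conventional kappa = 0.8 the
starvation length is exactly 1.25 * L_inf.

All functions here are pure and operate on scalars or numpy arrays of
lengths; discretization over a mesh lives in :mod:`debipm.ipm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traits import SpeciesTraits

__all__ = [
    "Environment",
    "DerivedLengths",
    "derived_lengths",
    "survival",
    "expected_growth",
    "growth_variance",
    "growth_kernel",
    "reproduction",
    "offspring_kernel",
]


@dataclass(frozen=True)
class Environment:
    """Feeding environment and offspring-size dispersion.

    Parameters
    ----------
    E_Y : mean experienced feeding level (dimensionless, 0 < E_Y <= 1);
        0 is an empty gut, 1 a full one.
    sigma_Y : among-individual standard deviation of the feeding level
        (demographic stochasticity in feeding); default 0.1.
    sigma_Lb_frac : offspring-length standard deviation as a fraction of
        L_b; the parent-offspring kernel assumes a "very small" spread
        around a constant mean offspring size, default 1%.
    """

    E_Y: float
    sigma_Y: float = 0.1
    sigma_Lb_frac: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.E_Y <= 1.0:
            raise ValueError(f"E_Y must be in (0, 1], got {self.E_Y}")
        if self.sigma_Y < 0:
            raise ValueError(f"sigma_Y must be >= 0, got {self.sigma_Y}")
        if self.sigma_Lb_frac <= 0:
            raise ValueError(f"sigma_Lb_frac must be > 0, got {self.sigma_Lb_frac}")

    def sigma_Lb(self, t: SpeciesTraits) -> float:
        """Offspring-length standard deviation in cm."""
        return self.sigma_Lb_frac * t.L_b


@dataclass(frozen=True)
class DerivedLengths:
    """Ultimate length L_inf = L_m*E(Y) and starvation length L_inf/kappa."""

    L_inf: float
    L_starv: float


def derived_lengths(t: SpeciesTraits, env: Environment) -> DerivedLengths:
    L_inf = t.L_m * env.E_Y
    return DerivedLengths(L_inf=L_inf, L_starv=L_inf / t.kappa)


def survival(L, t: SpeciesTraits, env: Environment, birth_floor=None):
    """Annual survival probability of an individual of length L.

    Juveniles (birth_floor <= L < L_p) survive with probability
    exp(-mu_j), adults (L >= L_p) with exp(-mu_a); anyone longer than the
    starvation length L_m*E(Y)/kappa dies with certainty, as do lengths
    below the birth floor.  ``birth_floor`` defaults to L_b; the
    discretizer lowers it to the mesh origin so that newborns scattered
    slightly below the nominal birth length by the offspring kernel are
    not evicted.

    Note the adult band is allowed to extend above L_m up to the
    starvation length: when E(Y) > kappa the reproduction function is
    defined on (L_m*E(Y), L_m*E(Y)/kappa], and cutting survival at L_m
    would create an inconsistent death cliff there.
    """
    L = np.asarray(L, dtype=float)
    floor = t.L_b if birth_floor is None else birth_floor
    starv = t.L_m * env.E_Y / t.kappa
    out = np.zeros_like(L)
    alive = (L >= floor) & (L <= starv)
    juv = alive & (L < t.L_p)
    adu = alive & (L >= t.L_p)
    out[juv] = np.exp(-t.mu_j)
    out[adu] = np.exp(-t.mu_a)
    return out if out.ndim else float(out)


def expected_growth(L, t: SpeciesTraits, env: Environment):
    """Mean length next year of a cohort currently at length L.

    Discrete von Bertalanffy step toward the ultimate length
    L_inf = L_m*E(Y):  L' = L*exp(-r_B) + (1 - exp(-r_B))*L_inf for
    L <= L_inf; individuals above L_inf do not shrink and keep length L.
    """
    L = np.asarray(L, dtype=float)
    L_inf = t.L_m * env.E_Y
    grow = L <= L_inf
    decay = np.exp(-t.r_B)
    out = np.where(grow, L * decay + (1.0 - decay) * L_inf, L)
    return out if out.ndim else float(out)


def growth_variance(L, t: SpeciesTraits, env: Environment):
    """Variance (cm^2) in next-year length for a cohort at length L.

    The spread comes from among-individual variation in feeding level:
    (1 - exp(-r_B))^2 * L_m^2 * sigma(Y)^2 below L_inf, zero above.
    """
    L = np.asarray(L, dtype=float)
    L_inf = t.L_m * env.E_Y
    var = (1.0 - np.exp(-t.r_B)) ** 2 * t.L_m ** 2 * env.sigma_Y ** 2
    out = np.where(L <= L_inf, var, 0.0)
    return out if out.ndim else float(out)


def _gauss_pdf(x, mean, var):
    return np.exp(-((x - mean) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def growth_kernel(L_next, L, t: SpeciesTraits, env: Environment):
    """Density (per cm) of growing from length L to L_next in one year.

    Gaussian in L_next with mean :func:`expected_growth` and variance
    :func:`growth_variance`.  A zero-variance source length is a
    deterministic transition; the scalar kernel is undefined there
    (density is a point mass) and the discretizer handles it explicitly,
    so this function returns +inf at the mean and 0 elsewhere.
    """
    L_next = np.asarray(L_next, dtype=float)
    mean = expected_growth(L, t, env)
    var = growth_variance(L, t, env)
    if var == 0.0:
        out = np.where(L_next == mean, np.inf, 0.0)
        return out if out.ndim else float(out)
    out = _gauss_pdf(L_next, mean, var)
    return out if out.ndim else float(out)


def reproduction(L, t: SpeciesTraits, env: Environment):
    """Offspring produced per year by an individual of length L.

    Zero before puberty; E(Y)*R_m*L^2/L_m^2 for mature individuals up to
    the ultimate length; between the ultimate and starvation lengths the
    1-kappa reproduction share also absorbs the maintenance deficit,
    giving (R_m/(1-kappa)) * [E(Y)*L^2 - kappa*L^3/L_m] / L_m^2, which is
    continuous at L_inf and reaches zero exactly at the starvation
    length.
    """
    L = np.asarray(L, dtype=float)
    E, Rm, Lm, k = env.E_Y, t.R_m, t.L_m, t.kappa
    L_inf = Lm * E
    starv = L_inf / k
    out = np.zeros_like(L)
    mid = (L >= t.L_p) & (L <= L_inf)
    out[mid] = E * Rm * L[mid] ** 2 / Lm ** 2
    hi = (L >= t.L_p) & (L > L_inf) & (L <= starv)
    out[hi] = (Rm / (1.0 - k)) * (E * L[hi] ** 2 - k * L[hi] ** 3 / Lm) / Lm ** 2
    return out if out.ndim else float(out)


def offspring_kernel(L_next, L, t: SpeciesTraits, env: Environment):
    """Density (per cm) of offspring length L_next for a parent of length L.

    Zero for pre-pubertal parents; otherwise Gaussian centred on the
    (parent-independent) expected offspring length L_b with the small
    standard deviation ``env.sigma_Lb(t)``.
    """
    L_next = np.asarray(L_next, dtype=float)
    if L < t.L_p:
        out = np.zeros_like(L_next)
        return out if out.ndim else float(out)
    sd = env.sigma_Lb(t)
    out = _gauss_pdf(L_next, t.L_b, sd * sd)
    return out if out.ndim else float(out)
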