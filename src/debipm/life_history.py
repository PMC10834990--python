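"""Derived life-history traits from a discretized DEB-IPM.

From the kernel matrices this module builds an age-from-stage life table
(survivorship l_x and age-specific fertility m_x of a newborn cohort
pushed through the survival-with-growth matrix GS) and computes nine
derived traits: generation time T, Keyfitz entropy H, age at maturity
L_alpha, progressive and retrogressive growth probabilities gamma/rho,
mean recruitment success phi, degree of iteroparity S, net reproductive
rate R0 and mature life expectancy L_omega, plus the mean life
expectancy eta_e, the population growth rate lambda and the damping
ratio.

Age at maturity and life expectancy have a conditional and an
unconditional reading.  The unconditional expected time spent in
juvenile states undercounts whenever juvenile mortality is appreciable,
and then the classical decomposition eta_e = L_alpha + L_omega fails by
(1 - l_alpha) * L_omega.  The default here is therefore the
*conditional* reading — the mean age at maturation of individuals that
do mature, and the mean lifespan of those same individuals — under which
the decomposition is exact up to the spread of lengths at maturation.
Set ``conditional=False`` for the unconditional variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .ipm import CoreDemography, KernelSet, core_demography

__all__ = [
    "LifeTable",
    "LifeHistoryResult",
    "life_table",
    "keyfitz_entropy",
    "age_at_maturity",
    "mature_life_expectancy",
    "mean_life_expectancy",
    "growth_directionality",
    "mean_recruitment",
    "degree_of_iteroparity",
    "derived_traits",
]

DEFAULT_TOL = 1e-9
DEFAULT_MAX_AGE = 5000


@dataclass
class LifeTable:
    """Age-from-stage cohort schedule.

    l_x is the probability of surviving to age at least x (l_0 = 1,
    non-increasing); m_x the average per-capita fertility of age class x.
    The cohort starts from the offspring length distribution.
    """

    ages: np.ndarray
    l_x: np.ndarray
    m_x: np.ndarray
    cohort_init: np.ndarray
    truncated_by: str = "tol"


@dataclass
class LifeHistoryResult:
    """The nine derived traits plus lambda, damping ratio and eta_e."""

    T: float
    H: float
    L_alpha: float
    gamma: float
    rho: float
    phi: float
    S_itero: float
    R0: float
    L_omega: float
    eta_e: float
    lam: float
    damping: float
    R0_lifetable: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "lambda": self.lam, "damping_ratio": self.damping,
            "generation_time_T": self.T, "keyfitz_entropy_H": self.H,
            "age_at_maturity_L_alpha": self.L_alpha,
            "progressive_growth_gamma": self.gamma,
            "retrogressive_growth_rho": self.rho,
            "mean_recruitment_phi": self.phi,
            "iteroparity_S": self.S_itero,
            "net_reproductive_rate_R0": self.R0,
            "mature_life_expectancy_L_omega": self.L_omega,
            "mean_life_expectancy_eta_e": self.eta_e,
            "R0_lifetable": self.R0_lifetable,
            "flags": ";".join(self.flags),
        }


def life_table(k: KernelSet, tol: float = DEFAULT_TOL,
               max_age: int = DEFAULT_MAX_AGE) -> LifeTable:
    """Push a newborn cohort through GS to build l_x and m_x.

    The cohort starts from the adult-averaged offspring-size
    distribution; n_{x+1} = GS n_x, l_x = sum(n_x),
    m_x = sum(V n_x)/l_x.  The table is truncated at the first age with
    l_x < tol (the executable stand-in for an upper summation bound at
    the mean life expectancy) or at ``max_age``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    GS = k.GS
    n = k.offspring_distribution.copy()
    recruits_per_bin = k.V.sum(axis=0)
    l_list, m_list = [], []
    truncated_by = "max_age"
    for _ in range(max_age + 1):
        l = float(n.sum())
        if l < tol:
            truncated_by = "tol"
            break
        l_list.append(l)
        m_list.append(float(recruits_per_bin @ n) / l)
        n = GS @ n
    ages = np.arange(len(l_list), dtype=float)
    return LifeTable(ages=ages, l_x=np.asarray(l_list),
                     m_x=np.asarray(m_list), cohort_init=k.offspring_distribution,
                     truncated_by=truncated_by)


def keyfitz_entropy(lt: LifeTable) -> float:
    """Keyfitz entropy H = -sum(log(l_x) l_x) / sum(l_x).

    H below/above 1 marks mortality rising/falling with age; H = 1 is
    the constant-mortality (exponential survivorship) reference.
    """
    l = lt.l_x[lt.l_x > 0]
    if len(l) < 2:
        return np.nan
    return float(-(np.log(l) * l).sum() / l.sum())


def _juvenile_machinery(k: KernelSet):
    GS = k.GS
    juv = ~k.adult_mask
    U = GS[np.ix_(juv, juv)]
    B = GS[np.ix_(k.adult_mask, juv)]
    N_J = scipy.linalg.solve(np.eye(U.shape[0]) - U, np.eye(U.shape[0]))
    juv_idx = np.flatnonzero(juv)
    b_local = int(np.searchsorted(juv_idx, k.birth_index))
    if b_local >= len(juv_idx) or juv_idx[b_local] != k.birth_index:
        raise ValueError("birth bin is not a juvenile state")
    return juv, U, B, N_J, b_local


def age_at_maturity(k: KernelSet, conditional: bool = True) -> float:
    """Expected years from birth to first entry into the adult band.

    Computed from the juvenile-restricted fundamental matrix
    N_J = (I - (GS)_JJ)^-1 starting in the bin containing L_b.  The
    default conditions on actually maturing (deaths before maturity do
    not drag the mean down); ``conditional=False`` returns the raw
    expected time spent in juvenile states.  Returns NaN when no
    maturation path exists.
    """
    if not np.any(~k.adult_mask):
        return 0.0
    juv, U, B, N_J, b = _juvenile_machinery(k)
    visits = N_J[:, b]                       # expected visits to each juvenile state
    if not conditional:
        return float(visits.sum())
    h = B.sum(axis=0) @ N_J                  # P(mature | start in juvenile state)
    h_b = h[b]
    if h_b <= 0:
        return np.nan
    return float((h * visits).sum() / h_b)


def mature_life_expectancy(k: KernelSet) -> float:
    """Expected further years lived from the bin containing L_p."""
    if k.puberty_index >= k.mesh.n_bins:
        raise ValueError("L_p lies outside the mesh")
    I = np.eye(k.mesh.n_bins)
    Nfund = scipy.linalg.solve(I - k.GS, I)
    return float(Nfund[:, k.puberty_index].sum())


def mean_life_expectancy(k: KernelSet, conditional: bool = True) -> float:
    """Mean life expectancy eta_e from the birth bin.

    Conditional (default): mean lifespan of individuals that reach
    maturity — the age at maturation plus the remaining expectancy from
    the length distribution at maturation, so that
    eta_e = L_alpha + L_omega holds up to the maturation-length spread.
    Unconditional: plain column sum of the fundamental matrix at the
    birth bin.
    """
    I = np.eye(k.mesh.n_bins)
    Nfund = scipy.linalg.solve(I - k.GS, I)
    if not conditional or not np.any(~k.adult_mask):
        return float(Nfund[:, k.birth_index].sum())
    juv, U, B, N_J, b = _juvenile_machinery(k)
    h = B.sum(axis=0) @ N_J
    h_b = h[b]
    if h_b <= 0:
        return np.nan
    entry = (B @ N_J[:, b]) / h_b            # length distribution at maturation
    remaining = Nfund.sum(axis=0)[k.adult_mask]
    visits = N_J[:, b]
    t_juv = float((h * visits).sum() / h_b)
    return t_juv + float(entry @ remaining)


def growth_directionality(k: KernelSet, w: np.ndarray) -> tuple[float, float]:
    """Stable-structure-weighted probabilities of growing vs shrinking.

    gamma sums, per source column j of G, the mass placed in larger
    destination bins (rows i > j); rho the mass in smaller bins; both are
    then averaged over columns with weights w (the stable length
    distribution).  gamma + rho <= 1; the remainder stays on the
    diagonal.
    """
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    below = np.tril(k.G, -1).sum(axis=0)     # destinations larger than source
    above = np.triu(k.G, 1).sum(axis=0)      # destinations smaller than source
    gamma = float(below @ w)
    rho = float(above @ w)
    return gamma, rho


def mean_recruitment(k: KernelSet, w: np.ndarray) -> float:
    """Mean per-capita recruits phi: w-weighted column sums of V."""
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    return float(k.V.sum(axis=0) @ w)


def degree_of_iteroparity(lt: LifeTable) -> float:
    """Coefficient of variation of the age-at-reproduction distribution.

    Ages are weighted by f_x = l_x * m_x (expected offspring produced at
    age x by a newborn).  S = 0 is the semelparous extreme (all
    reproduction at one age); spreading reproduction over ages raises S.
    Returns NaN when the cohort never reproduces.
    """
    f = lt.l_x * lt.m_x
    tot = f.sum()
    if tot <= 0:
        return np.nan
    a_bar = float((lt.ages * f).sum() / tot)
    a2_bar = float((lt.ages ** 2 * f).sum() / tot)
    var = max(a2_bar - a_bar ** 2, 0.0)
    if a_bar == 0:
        return np.nan
    return float(np.sqrt(var) / a_bar)


def derived_traits(k: KernelSet, core: CoreDemography | None = None,
                   tol: float = DEFAULT_TOL, max_age: int = DEFAULT_MAX_AGE,
                   conditional: bool = True,
                   r0_check_rel: float = 0.01) -> LifeHistoryResult:
    """Assemble the full trait set for one species x environment.

    R0 is reported from the next-generation-matrix eigenvalue; the
    life-table sum of l_x * m_x is computed as an independent
    cross-check and a flag is raised if the two disagree by more than
    ``r0_check_rel`` (default 1%).
    """
    if core is None:
        core = core_demography(k)
    lt = life_table(k, tol=tol, max_age=max_age)
    flags = list(core.flags)
    if lt.truncated_by == "max_age":
        flags.append(f"life_table_truncated_at_max_age={max_age}")

    R0_lt = float((lt.l_x * lt.m_x).sum())
    if core.R0 > 0 and abs(R0_lt - core.R0) > r0_check_rel * core.R0:
        flags.append(
            f"R0_mismatch: eigen={core.R0:.6g} lifetable={R0_lt:.6g}")

    gamma, rho = growth_directionality(k, core.w)
    L_alpha = age_at_maturity(k, conditional=conditional)
    L_omega = mature_life_expectancy(k)
    eta_e = mean_life_expectancy(k, conditional=conditional)

    return LifeHistoryResult(
        T=core.T, H=keyfitz_entropy(lt), L_alpha=L_alpha, gamma=gamma,
        rho=rho, phi=mean_recruitment(k, core.w),
        S_itero=degree_of_iteroparity(lt), R0=core.R0, L_omega=L_omega,
        eta_e=eta_e, lam=core.lam, damping=core.damping,
        R0_lifetable=R0_lt, flags=flags)
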