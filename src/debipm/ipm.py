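"""Discretization of the DEB-IPM and core demographic quantities.

The projection equation

    N(L', t+1) = \\int_Omega [ D(L', L) R(L) + G(L', L) S(L) ] N(L, t) dL

is approximated on an equal-width length mesh (200 bins by default) with
the midpoint rule, giving the matrices S (diagonal survival), G (growth,
columns = source length, rows = destination), R (diagonal fecundity),
D (offspring size), V = D R and the projection matrix A = V + G S.  The
dominant eigenvalue of A is the annual population growth rate lambda; the
ratio of the dominant to the second-largest eigenvalue modulus is the
damping ratio (demographic resilience).  The net reproductive rate R0 is
the dominant eigenvalue of the next-generation matrix F = V (I - G S)^-1,
and generation time T = log(R0)/log(lambda).

Discretization follows standard IPM practice for narrow kernels: the
Gaussian growth and offspring kernels are integrated exactly over each
destination bin (CDF differences at the bin edges), and the piecewise
survival and reproduction functions are averaged exactly over each
source bin, so the juvenile/adult and starvation thresholds are not
quantized to bin midpoints.  Columns of G and D are then renormalized
to unit mass — the standard guard against probability-mass eviction at
the domain edges; without it the narrow offspring kernel (sd ~ 1% of
L_b) would leak newborns below the mesh and bias lambda low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kernels import (Environment, expected_growth, growth_variance,
                      reproduction, survival)
from .traits import SpeciesTraits

__all__ = [
    "Mesh",
    "KernelSet",
    "CoreDemography",
    "MassEvictionWarning",
    "DEFAULT_N_BINS",
    "build_mesh",
    "discretize",
    "build_kernels",
    "core_demography",
    "generation_time",
    "export_kernels",
]

DEFAULT_N_BINS = 200


class MassEvictionWarning(RuntimeWarning):
    """More than 1e-6 of a kernel column's mass fell outside the mesh."""


@dataclass(frozen=True)
class Mesh:
    """Equal-width discretization of the length domain Omega (cm)."""

    n_bins: int
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return (self.upper - self.lower) / self.n_bins

    @property
    def midpoints(self) -> np.ndarray:
        h = self.width
        return self.lower + h * (np.arange(self.n_bins) + 0.5)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_bins + 1)

    def index_of(self, L: float) -> int:
        """Index of the bin containing length L (clipped to the mesh)."""
        i = int(np.floor((L - self.lower) / self.width))
        return min(max(i, 0), self.n_bins - 1)


@dataclass
class KernelSet:
    """Discretized DEB-IPM matrices on one mesh.

    ``G[i, j]`` is the probability of growing from bin j to bin i
    conditional on survival; ``D[:, j]`` the offspring-size distribution
    of a parent in adult bin j; ``V = D @ diag(R)``; ``A = V + G @ diag(S)``.
    """

    mesh: Mesh
    S_diag: np.ndarray
    G: np.ndarray
    R_diag: np.ndarray
    D: np.ndarray
    adult_mask: np.ndarray
    birth_index: int
    puberty_index: int
    V: np.ndarray = field(init=False)
    A: np.ndarray = field(init=False)

    def __post_init__(self):
        self.V = self.D * self.R_diag[np.newaxis, :]
        self.A = self.V + self.G * self.S_diag[np.newaxis, :]

    @property
    def GS(self) -> np.ndarray:
        """Survival-with-growth transition matrix G @ diag(S)."""
        return self.G * self.S_diag[np.newaxis, :]

    @property
    def offspring_distribution(self) -> np.ndarray:
        """Adult-averaged offspring-size column of D, normalized to sum 1."""
        fecund = self.D.sum(axis=0) > 0
        cols = self.D[:, fecund]
        if cols.size == 0 or cols.sum() == 0:
            out = np.zeros(self.mesh.n_bins)
            out[self.birth_index] = 1.0
            return out
        d = cols.mean(axis=1)
        return d / d.sum()


@dataclass
class CoreDemography:
    """Eigen-structure of one projection matrix.

    lam: population growth rate (dominant eigenvalue of A, per year);
    w: stable length distribution (right eigenvector, sums to 1);
    v: reproductive values (left eigenvector, scaled so v @ w = 1);
    damping: damping ratio lambda1/|lambda2| >= 1;
    Nfund: fundamental matrix (I - GS)^-1 (expected years spent in each
    bin per starting bin); F: next-generation matrix V @ Nfund;
    R0: net reproductive rate (dominant eigenvalue of F);
    T: generation time log(R0)/log(lam), NaN-flagged when lam == 1.
    """

    lam: float
    w: np.ndarray
    v: np.ndarray
    damping: float
    Nfund: np.ndarray
    F: np.ndarray
    R0: float
    T: float
    flags: list[str] = field(default_factory=list)


def build_mesh(t: SpeciesTraits, env: Environment,
               n_bins: int = DEFAULT_N_BINS) -> Mesh:
    """Mesh covering births through the starvation band.

    Lower bound L_b - 3*sigma_Lb (floored at a small positive length) so
    the offspring kernel is representable; upper bound at least
    max(L_m, L_m*E(Y)/kappa) so the adult band and, when E(Y) > kappa,
    the starvation band are covered.  The bin width is then nudged
    (upward, widening the domain slightly) so that the puberty length
    L_p falls exactly on a bin edge: every bin is then purely juvenile
    or purely adult, which removes the dominant O(width) discretization
    error in lambda from quantizing the mortality switch.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    for name in ("L_b", "L_p", "L_m", "kappa"):
        if not np.isfinite(getattr(t, name)):
            raise ValueError(f"non-finite trait {name}")
    lower = max(t.L_b - 3.0 * env.sigma_Lb(t), 1e-6 * t.L_b)
    upper = max(t.L_m, t.L_m * env.E_Y / t.kappa)
    h0 = (upper - lower) / n_bins
    m = int(np.floor((t.L_p - lower) / h0))
    if 1 <= m < n_bins:
        upper = lower + n_bins * (t.L_p - lower) / m
    return Mesh(n_bins=n_bins, lower=lower, upper=upper)


def _point_mass_column(mesh: Mesh, target: float) -> np.ndarray:
    """Unit point mass at the bin whose midpoint is nearest ``target``.

    Ties between two midpoints resolve to the lower bin (argmin returns
    the first minimum).
    """
    col = np.zeros(mesh.n_bins)
    col[int(np.argmin(np.abs(mesh.midpoints - target)))] = 1.0
    return col


def _interval_overlap(a, b, lo, hi):
    """Length of [a, b] ∩ [lo, hi] for vector bin edges a, b."""
    return np.clip(np.minimum(b, hi) - np.maximum(a, lo), 0.0, None)


def _bin_averaged_survival(t, env, mesh):
    """Exact per-bin average of the piecewise-constant survival function."""
    e = mesh.edges
    a, b = e[:-1], e[1:]
    starv = t.L_m * env.E_Y / t.kappa
    juv = _interval_overlap(a, b, mesh.lower, min(t.L_p, starv))
    adu = _interval_overlap(a, b, t.L_p, starv)
    return (juv * np.exp(-t.mu_j) + adu * np.exp(-t.mu_a)) / mesh.width


def _bin_averaged_reproduction(t, env, mesh, npts: int = 8):
    """Per-bin average of R(L) by Gauss–Legendre quadrature.

    R is polynomial on each of its branches, so quadrature is exact away
    from the branch knots; the few bins containing a knot (L_p, the
    ultimate length, the starvation length) are integrated piecewise.
    """
    e = mesh.edges
    gx, gw = np.polynomial.legendre.leggauss(npts)
    a, b = e[:-1], e[1:]
    mid, rad = 0.5 * (a + b), 0.5 * (b - a)
    X = mid[:, None] + rad[:, None] * gx[None, :]
    R = (reproduction(X.ravel(), t, env).reshape(X.shape) @ gw) / 2.0

    knots = np.array([t.L_p, t.L_m * env.E_Y, t.L_m * env.E_Y / t.kappa])
    has_knot = ((a[:, None] < knots[None, :])
                & (knots[None, :] < b[:, None])).any(axis=1)
    for j in np.flatnonzero(has_knot):
        pts = sorted({a[j], b[j], *[k for k in knots if a[j] < k < b[j]]})
        acc = 0.0
        for lo, hi in zip(pts, pts[1:]):
            xm, xr = 0.5 * (lo + hi), 0.5 * (hi - lo)
            acc += xr * (gw * reproduction(xm + xr * gx, t, env)).sum()
        R[j] = acc / mesh.width
    return R


def discretize(t: SpeciesTraits, env: Environment, mesh: Mesh) -> KernelSet:
    """Discretize the four kernels on ``mesh``.

    Growth columns with positive variance integrate the Gaussian kernel
    exactly over each destination bin (CDF differences at the edges) and
    are renormalized to sum 1; zero-variance columns (sigma(Y) = 0, or
    source lengths already past the ultimate length) become unit point
    masses at the bin nearest the expected length.  The offspring column
    is built the same way and attached to every fecund source bin.
    Survival and reproduction are averaged over each source bin so the
    branch thresholds are resolved below bin width.  If more than 1e-6
    of the raw offspring mass lies outside the mesh a
    :class:`MassEvictionWarning` reports the lost fraction (it is then
    restored by renormalization).
    """
    from scipy.stats import norm

    x = mesh.midpoints
    e = mesh.edges
    n = mesh.n_bins

    S_diag = _bin_averaged_survival(t, env, mesh)
    R_diag = _bin_averaged_reproduction(t, env, mesh)
    adult_mask = x >= t.L_p

    G = np.zeros((n, n))
    mu = expected_growth(x, t, env)
    var = growth_variance(x, t, env)
    stoch = var > 0.0
    if np.any(stoch):
        sd = np.sqrt(var[stoch])
        cdf = norm.cdf((e[:, None] - mu[stoch][None, :]) / sd[None, :])
        cols = np.diff(cdf, axis=0)
        sums = cols.sum(axis=0)
        for jj, j in enumerate(np.flatnonzero(stoch)):
            if sums[jj] > 0:
                G[:, j] = cols[:, jj] / sums[jj]
            else:  # kernel entirely outside the mesh: collapse to point mass
                G[:, j] = _point_mass_column(mesh, mu[j])
    for j in np.flatnonzero(~stoch):
        G[:, j] = _point_mass_column(mesh, mu[j])

    sd_b = env.sigma_Lb(t)
    d_raw = np.diff(norm.cdf((e - t.L_b) / sd_b))
    lost = 1.0 - d_raw.sum()
    if lost > 1e-6:
        warnings.warn(
            f"offspring kernel loses {lost:.3e} probability mass outside "
            f"the mesh [{mesh.lower:.4g}, {mesh.upper:.4g}] before "
            "renormalization",
            MassEvictionWarning, stacklevel=2)
    d_col = (d_raw / d_raw.sum()) if d_raw.sum() > 0 else _point_mass_column(mesh, t.L_b)
    D = np.zeros((n, n))
    D[:, R_diag > 0] = d_col[:, np.newaxis]

    return KernelSet(
        mesh=mesh, S_diag=S_diag, G=G, R_diag=R_diag, D=D,
        adult_mask=adult_mask, birth_index=mesh.index_of(t.L_b),
        puberty_index=int(np.argmax(adult_mask)) if adult_mask.any()
        else mesh.n_bins - 1,
    )


def build_kernels(t: SpeciesTraits, env: Environment,
                  n_bins: int = DEFAULT_N_BINS) -> KernelSet:
    """Convenience: :func:`build_mesh` then :func:`discretize`."""
    return discretize(t, env, build_mesh(t, env, n_bins))


def _dominant_pair(A: np.ndarray):
    vals, vl, vr = scipy.linalg.eig(A, left=True, right=True)
    order = np.argsort(-np.abs(vals))
    return vals[order], vl[:, order], vr[:, order]


def core_demography(k: KernelSet, lam_one_tol: float = 1e-12) -> CoreDemography:
    """Eigen-analysis of the projection matrix.

    By Perron–Frobenius the dominant eigenvalue of the non-negative A is
    real; it is asserted so to an imaginary tolerance of 1e-10.  The
    fundamental matrix (I - GS)^-1 exists because GS is strictly
    substochastic (survival < 1 everywhere).
    """
    A = k.A
    if not np.all(np.isfinite(A)) or np.any(A < 0):
        raise ValueError("projection matrix must be non-negative and finite")
    vals, vl, vr = _dominant_pair(A)
    lam_c = vals[0]
    if abs(lam_c.imag) > 1e-10 * max(1.0, abs(lam_c)):
        raise ArithmeticError(f"dominant eigenvalue not real: {lam_c}")
    lam = float(lam_c.real)
    if lam <= 0:
        raise ArithmeticError(f"dominant eigenvalue non-positive: {lam}")

    w = np.real(vr[:, 0])
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    v = np.real(vl[:, 0])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    vw = v @ w
    v = v / vw if vw > 0 else v

    sub = np.abs(vals[1]) if len(vals) > 1 else 0.0
    damping = float(lam / sub) if sub > 0 else np.inf

    GS = k.GS
    I = np.eye(k.mesh.n_bins)
    Nfund = scipy.linalg.solve(I - GS, I)
    F = k.V @ Nfund
    fvals = scipy.linalg.eigvals(F)
    R0 = float(np.real(fvals[np.argmax(np.abs(fvals))]))

    flags: list[str] = []
    if abs(lam - 1.0) < lam_one_tol:
        T = np.nan
        flags.append("generation_time_undefined: lambda == 1")
    else:
        T = generation_time(R0, lam) if R0 > 0 else np.nan
        if R0 <= 0:
            flags.append("generation_time_undefined: R0 <= 0")
    return CoreDemography(lam=lam, w=w, v=v, damping=damping, Nfund=Nfund,
                          F=F, R0=R0, T=T, flags=flags)


def generation_time(R0: float, lam: float) -> float:
    """Years for the population to grow by its net reproductive rate.

    T = log(R0)/log(lambda): the time over which growth at rate lambda
    multiplies the population by R0, i.e. one full replacement.
    """
    if R0 <= 0 or lam <= 0:
        raise ValueError("R0 and lambda must be positive")
    if lam == 1.0:
        raise ValueError("generation time undefined at lambda == 1")
    return float(np.log(R0) / np.log(lam))


def export_kernels(k: KernelSet, out_dir, record_id: str, E_Y: float):
    """Write S, G, R, D, A as plain-text files keyed by species and E(Y)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    key = f"{record_id}_EY{E_Y:.3f}"
    np.savetxt(out / f"{key}_mesh.txt", k.mesh.midpoints)
    np.savetxt(out / f"{key}_S.txt", k.S_diag)
    np.savetxt(out / f"{key}_R.txt", k.R_diag)
    for name, M in (("G", k.G), ("D", k.D), ("A", k.A)):
        np.savetxt(out / f"{key}_{name}.txt", M)
    return out
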