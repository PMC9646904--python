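"""Bivariate sine-model von Mises densities on the torus.

The sine model is the periodic analogue of a correlated bivariate Gaussian
for a pair of angles (phi, psi):

    p(phi, psi) = exp(W(phi - phi0, psi - psi0)) / T
    W(u, v)     = kappa1*cos(u) + kappa2*cos(v) + lambda*sin(u)*sin(v)

with concentrations kappa1, kappa2 >= 0 and coupling lambda constrained by
lambda**2 < kappa1*kappa2.  The normalization constant T is an infinite
series in modified Bessel functions of the first kind,

    T = 4*pi**2 * sum_m C(2m, m) * (lambda**2 / (4*kappa1*kappa2))**m
                  * I_m(kappa1) * I_m(kappa2),

which this module evaluates in log space together with its derivatives.
Modes are parameterized by (kappa1, kappa2, rho) with the normalized
coupling rho = lambda / sqrt(kappa1*kappa2), so that the validity
constraint is simply rho**2 < 1.

For small angular variances the sine model approximates a bivariate
Gaussian with variances (sigma1^2, sigma2^2) and correlation rho; the
conversions between the two parameterizations are exact algebraic maps
and mutual inverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ive

__all__ = [
    "BivariateSineParams",
    "GaussianTorsionParams",
    "Covariance2x2",
    "log_partition",
    "log_density",
    "density",
    "grad_log_density",
    "gaussian_to_sine",
    "sine_to_gaussian",
    "covariance_to_gaussian",
]

_LN2 = math.log(2.0)
_LOG_4PI2 = math.log(4.0 * math.pi**2)


def _lse(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Log-sum-exp along an axis; tolerates all -inf slices."""
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    with np.errstate(divide="ignore"):
        return np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis)


def wrap_angle(theta):
    """Wrap an angle (radians) to the interval (-pi, pi]."""
    return -np.remainder(-np.asarray(theta) + np.pi, 2.0 * np.pi) + np.pi


@dataclass(frozen=True)
class BivariateSineParams:
    """One mode of the bivariate sine model.

    Angles are radians; ``phi0``/``psi0`` are wrapped to (-pi, pi] on
    construction.  ``rho`` is the normalized coupling, |rho| < 1.
    """

    phi0: float
    psi0: float
    kappa1: float
    kappa2: float
    rho: float

    def __post_init__(self):
        for name in ("phi0", "psi0", "kappa1", "kappa2", "rho"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("concentrations kappa1, kappa2 must be >= 0")
        if not abs(self.rho) < 1:
            raise ValueError("normalized coupling rho must satisfy rho**2 < 1")
        object.__setattr__(self, "phi0", float(wrap_angle(self.phi0)))
        object.__setattr__(self, "psi0", float(wrap_angle(self.psi0)))

    @property
    def lam(self) -> float:
        """Coupling lambda = rho * sqrt(kappa1*kappa2); lambda**2 < kappa1*kappa2."""
        return self.rho * math.sqrt(self.kappa1 * self.kappa2)


@dataclass(frozen=True)
class GaussianTorsionParams:
    """Local Gaussian description of a torsional basin: variances and correlation."""

    sigma1_sq: float
    sigma2_sq: float
    rho: float

    def __post_init__(self):
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise ValueError("variances must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("correlation must satisfy rho**2 < 1")


@dataclass(frozen=True)
class Covariance2x2:
    """Symmetric positive-definite 2x2 covariance of (phi, psi), radians^2."""

    c11: float
    c12: float
    c22: float

    def __post_init__(self):
        if self.c11 <= 0 or self.c22 <= 0 or self.c11 * self.c22 - self.c12**2 <= 0:
            raise ValueError("covariance matrix must be positive definite")


def _log_f_batch(orders: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """ln(I_m(kappa)/kappa**m) on an orders x kappas grid, stable at kappa=0.

    The ratio tends to (1/2)**m / m! in the kappa -> 0 limit; that closed
    form is also used whenever the exponentially scaled Bessel value
    underflows (large m, moderate kappa), where the correction factor is
    negligible.
    """
    m = orders[:, None]
    k = kappa[None, :]
    limit = np.broadcast_to(-m * _LN2 - gammaln(m + 1.0), (orders.size, kappa.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(ive(m, k)) + k - m * np.log(k)
    return np.where(np.isfinite(out), out, limit)


def _partition_series_batch(
    kappa1,
    kappa2,
    lam,
    rel_tol: float = 1e-12,
    max_terms: int = 500,
    grad: bool = False,
):
    """Vectorized log partition function ln(T) over arrays of modes,
    optionally with derivatives (d lnT / d kappa1, d kappa2, d lambda).

    Terms are accumulated in log space (all terms are nonnegative); the
    series is truncated once the latest term of every mode contributes
    less than ``rel_tol`` relative to its running sum, with a hard cap of
    ``max_terms`` terms.
    """
    k1 = np.atleast_1d(np.asarray(kappa1, dtype=float))
    k2 = np.atleast_1d(np.asarray(kappa2, dtype=float))
    lm = np.atleast_1d(np.asarray(lam, dtype=float))
    if not (np.all(np.isfinite(k1)) and np.all(np.isfinite(k2)) and np.all(np.isfinite(lm))):
        raise ValueError("non-finite sine-model parameter")
    if np.any(k1 < 0) or np.any(k2 < 0):
        raise ValueError("concentrations must be >= 0")
    if np.any((lm != 0) & (lm**2 >= k1 * k2)):
        raise ValueError("coupling violates lambda**2 < kappa1*kappa2")

    with np.errstate(divide="ignore"):
        log_r4 = np.where(lm == 0, -np.inf, 2.0 * np.log(np.abs(lm)) - 2.0 * _LN2)

    chunk = 16
    lt_parts, lf1_parts, lf2_parts = [], [], []
    running = np.full(k1.shape, -np.inf)
    m_start = 0
    log_tol = math.log(rel_tol)
    while m_start < max_terms:
        m = np.arange(m_start, min(m_start + chunk, max_terms), dtype=float)
        lf1 = _log_f_batch(m, k1)
        lf2 = _log_f_batch(m, k2)
        lbinom = (gammaln(2.0 * m + 1.0) - 2.0 * gammaln(m + 1.0))[:, None]
        # m * ln(lam^2/4) with the m = 0 term fixed at 0 even when lam = 0
        with np.errstate(invalid="ignore"):
            mlog = np.where(m[:, None] == 0, 0.0, m[:, None] * log_r4[None, :])
        lt = lbinom + mlog + lf1 + lf2
        lt_parts.append(lt)
        lf1_parts.append(lf1)
        lf2_parts.append(lf2)
        running = np.logaddexp(running, _lse(lt, axis=0))
        m_start += chunk
        if np.all(lt[-1] - running < log_tol):
            break

    lt = np.concatenate(lt_parts, axis=0)
    lf1 = np.concatenate(lf1_parts, axis=0)
    lf2 = np.concatenate(lf2_parts, axis=0)
    n_terms = lt.shape[0]
    log_sum = _lse(lt, axis=0)
    log_t = _LOG_4PI2 + log_sum
    if not grad:
        return log_t

    # d f_m / d kappa = kappa * f_{m+1}(kappa): shift the f arrays by one order.
    extra = np.array([float(n_terms)])
    lf1_next = np.vstack([lf1[1:], _log_f_batch(extra, k1)])
    lf2_next = np.vstack([lf2[1:], _log_f_batch(extra, k2)])
    with np.errstate(divide="ignore", invalid="ignore"):
        dk1 = np.exp(_lse(lt + lf1_next - lf1, axis=0) - log_sum) * k1
        dk2 = np.exp(_lse(lt + lf2_next - lf2, axis=0) - log_sum) * k2
        orders = np.arange(n_terms, dtype=float)
        log_m = np.where(orders > 0, np.log(np.maximum(orders, 1.0)), -np.inf)
        ratio = np.exp(_lse(lt + log_m[:, None], axis=0) - log_sum)
        dlam = np.where(lm == 0, 0.0, 2.0 * ratio / np.where(lm == 0, 1.0, lm))
    return log_t, dk1, dk2, dlam


def _partition_series(
    kappa1: float,
    kappa2: float,
    lam: float,
    rel_tol: float = 1e-12,
    max_terms: int = 500,
    grad: bool = False,
):
    """Scalar wrapper around :func:`_partition_series_batch`."""
    out = _partition_series_batch(
        kappa1, kappa2, lam, rel_tol=rel_tol, max_terms=max_terms, grad=grad
    )
    if not grad:
        return float(out[0])
    return tuple(float(a[0]) for a in out)


def log_partition(kappa1: float, kappa2: float, lam: float, rel_tol: float = 1e-12) -> float:
    """ln(T): log normalization constant of the sine model.

    Parameters
    ----------
    kappa1, kappa2
        Nonnegative concentrations.
    lam
        Coupling; must satisfy ``lam**2 < kappa1*kappa2`` unless zero.
    rel_tol
        Relative contribution below which the Bessel series is truncated.
    """
    return _partition_series(kappa1, kappa2, lam, rel_tol=rel_tol)


def log_density(phi, psi, p: BivariateSineParams):
    """Log density of the sine model at angles (radians); 2*pi-periodic.

    Accepts scalars or broadcastable arrays.
    """
    lam = p.lam
    log_t = _partition_series(p.kappa1, p.kappa2, lam)
    dphi = np.asarray(phi) - p.phi0
    dpsi = np.asarray(psi) - p.psi0
    w = (
        p.kappa1 * np.cos(dphi)
        + p.kappa2 * np.cos(dpsi)
        + lam * np.sin(dphi) * np.sin(dpsi)
    )
    return w - log_t


def density(phi, psi, p: BivariateSineParams):
    """Sine-model probability density exp(log_density)."""
    return np.exp(log_density(phi, psi, p))


def grad_log_density(phi, psi, p: BivariateSineParams):
    """Analytic gradient of ``log_density`` in (phi0, psi0, kappa1, kappa2, rho).

    Returns an array of shape ``(5,) + broadcast(phi, psi).shape``.  The
    partition-function derivatives are obtained by term-wise
    differentiation of the Bessel series.
    """
    k1, k2, rho = p.kappa1, p.kappa2, p.rho
    lam = p.lam
    _, dt_dk1, dt_dk2, dt_dlam = _partition_series(k1, k2, lam, grad=True)
    sqrt_kk = math.sqrt(k1 * k2)
    # lambda = rho*sqrt(k1*k2) couples the partition derivatives.
    dlam_dk1 = 0.0 if rho == 0.0 else 0.5 * rho * math.sqrt(k2 / k1)
    dlam_dk2 = 0.0 if rho == 0.0 else 0.5 * rho * math.sqrt(k1 / k2)

    dphi = np.asarray(phi, dtype=float) - p.phi0
    dpsi = np.asarray(psi, dtype=float) - p.psi0
    sin_p, cos_p = np.sin(dphi), np.cos(dphi)
    sin_s, cos_s = np.sin(dpsi), np.cos(dpsi)
    cross = sin_p * sin_s

    g_phi0 = k1 * sin_p - lam * cos_p * sin_s
    g_psi0 = k2 * sin_s - lam * sin_p * cos_s
    g_k1 = cos_p + dlam_dk1 * cross - (dt_dk1 + dt_dlam * dlam_dk1)
    g_k2 = cos_s + dlam_dk2 * cross - (dt_dk2 + dt_dlam * dlam_dk2)
    g_rho = sqrt_kk * (cross - dt_dlam)
    return np.stack(np.broadcast_arrays(g_phi0, g_psi0, g_k1, g_k2, g_rho))


def gaussian_to_sine(
    g: GaussianTorsionParams, phi0: float = 0.0, psi0: float = 0.0
) -> BivariateSineParams:
    """Periodize a Gaussian torsional basin into sine-model parameters.

    kappa_i = 1 / (sigma_i^2 * (1 - rho^2)); the correlation and the mode
    location carry over unchanged.  Accurate when the variances are small
    relative to (2*pi)^2.
    """
    scale = 1.0 - g.rho**2
    return BivariateSineParams(
        phi0=phi0,
        psi0=psi0,
        kappa1=1.0 / (g.sigma1_sq * scale),
        kappa2=1.0 / (g.sigma2_sq * scale),
        rho=g.rho,
    )


def sine_to_gaussian(p: BivariateSineParams) -> GaussianTorsionParams:
    """Inverse of :func:`gaussian_to_sine`.

    sigma1^2 = kappa2 / (kappa1*kappa2 - lambda^2) and symmetrically for
    sigma2^2; requires strictly positive concentrations.
    """
    if p.kappa1 <= 0 or p.kappa2 <= 0:
        raise ValueError("conversion requires kappa1, kappa2 > 0")
    det = p.kappa1 * p.kappa2 - p.lam**2
    if det <= 0:
        raise ValueError("kappa1*kappa2 - lambda**2 must be positive")
    return GaussianTorsionParams(
        sigma1_sq=p.kappa2 / det, sigma2_sq=p.kappa1 / det, rho=p.rho
    )


def covariance_to_gaussian(c: Covariance2x2) -> GaussianTorsionParams:
    """Read variances and correlation off a 2x2 dihedral covariance matrix."""
    return GaussianTorsionParams(
        sigma1_sq=c.c11,
        sigma2_sq=c.c22,
        rho=c.c12 / math.sqrt(c.c11 * c.c22),
    )
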