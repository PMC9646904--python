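"""Finite mixture of sine-model densities fitted to Ramachandran maps.

Each of Q candidate conformations contributes, at every residue n, one
bivariate von Mises (sine-model) mode; the observed per-residue
Ramachandran probability map is modeled as the population-weighted
mixture

    p^n(phi, psi) = sum_q gamma_q * p_q^n(phi, psi),

with a single population vector gamma shared across residues.  Since the
data are probability maps rather than angle samples, the log-likelihood
is the voxel-weighted sum

    L = sum_n sum_m w^n_m * ln p^n(phi_m, psi_m)

over the 324 voxel centers, with weights w^n_m equal to the normalized
map values — maximizing L is equivalent to minimizing the summed
Kullback-Leibler divergence between data and model up to a constant.

Optimization uses bounded quasi-Newton iteration (L-BFGS-B) with an
analytic gradient.  The simplex constraint on gamma is handled by a
softmax reparameterization; mode centers are box-constrained within a
configurable drift limit of their initial (conformation-derived) values;
concentrations and the coupling rho carry box bounds.  The multi-start
protocol repeats the fit from random Dirichlet population draws and
reports mean +/- SD of gamma over converged runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .map_io import RamachandranGrid, grid_to_weights
from .torus_model import (
    _lse,
    BivariateSineParams,
    Covariance2x2,
    _partition_series_batch,
    covariance_to_gaussian,
    gaussian_to_sine,
)

__all__ = [
    "MixtureModel",
    "FitConfig",
    "FitRun",
    "FitResult",
    "initialize_from_ensemble",
    "model_log_likelihood",
    "model_gradient",
    "fit_once",
    "fit_multistart",
]

_LOG_FLOOR = -745.0  # ln of the smallest positive double

#: Default basin width used when no covariance is supplied: sigma = 20 degrees.
DEFAULT_SIGMA_RAD = math.radians(20.0)


@dataclass
class MixtureModel:
    """Q conformations x N residues of sine-model modes plus populations.

    Parameter arrays have shape (Q, N); ``valid[q, n]`` is False where a
    conformation has no defined dihedrals at residue n, in which case that
    conformation is excluded from the mixture at that residue (the
    remaining populations are renormalized there).  ``init_phi0`` /
    ``init_psi0`` snapshot the starting mode centers for the drift
    constraint.
    """

    gamma: np.ndarray
    phi0: np.ndarray
    psi0: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray
    rho: np.ndarray
    residue_ids: np.ndarray
    valid: np.ndarray = None
    init_phi0: np.ndarray = None
    init_psi0: np.ndarray = None

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        for name in ("phi0", "psi0", "kappa1", "kappa2", "rho"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))
        self.residue_ids = np.asarray(self.residue_ids)
        if self.valid is None:
            self.valid = np.ones(self.phi0.shape, dtype=bool)
        if self.init_phi0 is None:
            self.init_phi0 = self.phi0.copy()
        if self.init_psi0 is None:
            self.init_psi0 = self.psi0.copy()
        if np.any(self.gamma < -1e-12) or abs(self.gamma.sum() - 1.0) > 1e-9:
            raise ValueError("gamma must be nonnegative and sum to 1")
        v = self.valid
        if np.any(self.kappa1[v] < 0) or np.any(self.kappa2[v] < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.abs(self.rho[v]) >= 1):
            raise ValueError("rho must satisfy rho**2 < 1")

    @property
    def n_conformations(self) -> int:
        return self.phi0.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi0.shape[1]

    def params(self, q: int, n: int) -> BivariateSineParams:
        """Sine-model parameters of conformation q at residue index n."""
        if not self.valid[q, n]:
            raise ValueError(f"conformation {q} has no mode at residue index {n}")
        return BivariateSineParams(
            self.phi0[q, n], self.psi0[q, n],
            self.kappa1[q, n], self.kappa2[q, n], self.rho[q, n],
        )


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings for the mixture fit.

    ``kappa_bounds`` defaults to (2, 100), i.e. basin widths sigma between
    roughly 6 and 41 degrees: without a positive lower bound a single mode
    can flatten into a uniform density and absorb any background mass in
    the map, and without a moderate upper bound a mode can collapse onto a
    single voxel center — both degenerate likelihood optima that destroy
    the population estimates on noisy maps.
    """

    drift_limit: float = 15.0  # degrees
    n_starts: int = 100
    seed: int = 0
    max_iterations: int = 5000
    gradient_tolerance: float = 1e-6
    #: relative objective-improvement tolerance; overlapping modes create
    #: long flat population ridges that are pointless to polish further
    ftol: float = 1e-7
    kappa_bounds: tuple = (2.0, 100.0)
    rho_bound: float = 0.99
    optimize_shapes: bool = True

    def __post_init__(self):
        if self.drift_limit <= 0:
            raise ValueError("drift_limit must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitRun:
    """Outcome of a single optimization run."""

    status: str  # "converged" or "failed"
    gamma: np.ndarray
    log_likelihood: float
    model: MixtureModel | None = None


@dataclass
class FitResult:
    """Aggregate over a multi-start fit: per-run records plus mean +/- SD
    of the populations over converged runs (renormalized to sum 1)."""

    runs: list
    mean_gamma: np.ndarray
    sd_gamma: np.ndarray
    n_failed: int
    best: FitRun

    @property
    def converged_runs(self):
        return [r for r in self.runs if r.status == "converged"]


def initialize_from_ensemble(
    dihedrals_deg: np.ndarray,
    covariances=None,
    residue_ids=None,
) -> MixtureModel:
    """Build a starting mixture model from ensemble dihedrals.

    Parameters
    ----------
    dihedrals_deg
        Array of shape (Q, N, 2) of (phi, psi) in degrees; NaN marks
        residues (termini, missing atoms) without defined dihedrals.
    covariances
        Optional (Q, N) nested sequence of :class:`Covariance2x2` (or None
        entries) in radians^2, e.g. from a torsional elastic-network
        normal-mode analysis.  Missing entries fall back to an isotropic
        basin of sigma = 20 degrees, rho = 0.
    residue_ids
        Sequence positions matching the second axis; defaults to 1..N.
    """
    dihedrals_deg = np.asarray(dihedrals_deg, dtype=float)
    if dihedrals_deg.ndim != 3 or dihedrals_deg.shape[2] != 2:
        raise ValueError("dihedrals must have shape (Q, N, 2)")
    q_count, n_count = dihedrals_deg.shape[:2]
    if q_count == 0:
        raise ValueError("need at least one conformation")
    if residue_ids is None:
        residue_ids = np.arange(1, n_count + 1)

    phi0 = np.deg2rad(dihedrals_deg[:, :, 0])
    psi0 = np.deg2rad(dihedrals_deg[:, :, 1])
    valid = np.isfinite(phi0) & np.isfinite(psi0)
    kappa_default = 1.0 / DEFAULT_SIGMA_RAD**2
    kappa1 = np.full((q_count, n_count), kappa_default)
    kappa2 = np.full((q_count, n_count), kappa_default)
    rho = np.zeros((q_count, n_count))
    if covariances is not None:
        for q in range(q_count):
            for n in range(n_count):
                cov = covariances[q][n]
                if cov is None:
                    continue
                if not isinstance(cov, Covariance2x2):
                    try:
                        cov = Covariance2x2(*cov)
                    except ValueError as err:
                        raise ValueError(
                            f"covariance at conformation {q}, residue index {n}: {err}"
                        ) from err
                p = gaussian_to_sine(covariance_to_gaussian(cov))
                kappa1[q, n], kappa2[q, n], rho[q, n] = p.kappa1, p.kappa2, p.rho
    phi0 = np.where(valid, phi0, 0.0)
    psi0 = np.where(valid, psi0, 0.0)
    return MixtureModel(
        gamma=np.full(q_count, 1.0 / q_count),
        phi0=phi0, psi0=psi0, kappa1=kappa1, kappa2=kappa2, rho=rho,
        residue_ids=residue_ids, valid=valid,
    )


class _Objective:
    """Negative voxel-weighted log-likelihood and gradient over packed
    optimization variables (softmax populations, then per-mode parameters)."""

    def __init__(self, model: MixtureModel, grids, config: FitConfig):
        self.q_count = model.n_conformations
        self.n_count = model.n_residues
        self.config = config
        self.valid = model.valid
        self.model = model

        by_id = {g.residue_id: g for g in grids}
        self.res_idx = []
        weights = []
        for n, rid in enumerate(model.residue_ids):
            g = by_id.pop(int(rid), None)
            if g is None:
                continue  # residue without a map: skipped in the likelihood
            phi_m, psi_m, w = grid_to_weights(g)
            weights.append(w)
            self.res_idx.append(n)
        if by_id:
            raise ValueError(f"grids for unknown residues: {sorted(by_id)}")
        if not self.res_idx:
            raise ValueError("no residue in common between model and grids")
        self.phi_m, self.psi_m = phi_m, psi_m  # identical lattice for all grids
        self.weights = np.array(weights)
        self.clamped = False

        # Packed layout: alpha (Q), then per valid (q, n): phi0, psi0 and,
        # if shapes are optimized, kappa1, kappa2, rho.
        self.n_modes = int(self.valid.sum())
        self.mode_qn = np.argwhere(self.valid)
        self.shapes = config.optimize_shapes

    def pack(self, gamma, model: MixtureModel) -> np.ndarray:
        alpha = np.log(np.clip(gamma, 1e-12, None))
        parts = [alpha]
        v = self.valid
        parts += [model.phi0[v], model.psi0[v]]
        if self.shapes:
            lo, hi = self.config.kappa_bounds
            parts += [
                np.clip(model.kappa1[v], lo, hi),
                np.clip(model.kappa2[v], lo, hi),
                np.clip(model.rho[v], -self.config.rho_bound, self.config.rho_bound),
            ]
        return np.concatenate(parts)

    def bounds(self):
        drift = math.radians(self.config.drift_limit)
        v = self.valid
        bnds = [(None, None)] * self.q_count
        for center in (self.model.init_phi0[v], self.model.init_psi0[v]):
            bnds += [(c - drift, c + drift) for c in center]
        if self.shapes:
            lo, hi = self.config.kappa_bounds
            rb = self.config.rho_bound
            bnds += [(lo, hi)] * (2 * self.n_modes) + [(-rb, rb)] * self.n_modes
        return bnds

    def unpack(self, x):
        q_count, nm = self.q_count, self.n_modes
        alpha = x[:q_count]
        fields = {}
        offset = q_count
        names = ["phi0", "psi0"] + (["kappa1", "kappa2", "rho"] if self.shapes else [])
        for name in names:
            full = getattr(self.model, name).copy()
            full[self.valid] = x[offset:offset + nm]
            fields[name] = full
            offset += nm
        if not self.shapes:
            for name in ("kappa1", "kappa2", "rho"):
                fields[name] = getattr(self.model, name)
        return alpha, fields

    def value_and_grad(self, x):
        alpha, f = self.unpack(x)
        alpha = alpha - alpha.max()
        log_gamma = alpha - _lse(alpha)
        gamma = np.exp(log_gamma)
        phi0, psi0 = f["phi0"], f["psi0"]
        k1, k2, rho = f["kappa1"], f["kappa2"], f["rho"]

        total = 0.0
        # e_q accumulates gamma_q * dL/dgamma_q, which stays bounded even
        # when a population underflows (responsibilities are <= 1).
        e_gamma = np.zeros(self.q_count)
        d_phi0 = np.zeros_like(phi0)
        d_psi0 = np.zeros_like(psi0)
        d_k1 = np.zeros_like(k1)
        d_k2 = np.zeros_like(k2)
        d_rho = np.zeros_like(rho)

        for w, n in zip(self.weights, self.res_idx):
            qs = self.valid[:, n]
            s_n = gamma[qs].sum()
            k1v, k2v, rv = k1[qs, n], k2[qs, n], rho[qs, n]
            lamv = rv * np.sqrt(k1v * k2v)
            logt, dt_dk1, dt_dk2, dt_dlam = _partition_series_batch(
                k1v, k2v, lamv, grad=True
            )
            dphi = self.phi_m[None, :] - phi0[qs, n][:, None]
            dpsi = self.psi_m[None, :] - psi0[qs, n][:, None]
            sp, cp = np.sin(dphi), np.cos(dphi)
            ss, cs = np.sin(dpsi), np.cos(dpsi)
            cross = sp * ss
            log_p = (
                k1v[:, None] * cp + k2v[:, None] * cs + lamv[:, None] * cross
                - logt[:, None]
            )

            z = log_gamma[qs][:, None] + log_p
            lse = _lse(z, axis=0)
            log_mix = lse - math.log(s_n)
            if np.any(log_mix < _LOG_FLOOR):
                self.clamped = True
                log_mix = np.maximum(log_mix, _LOG_FLOOR)
            total += w @ log_mix

            resp = np.exp(z - lse)  # responsibilities among valid modes
            wr = w * resp
            w_q = wr.sum(axis=1)
            e_gamma[qs] += w_q - gamma[qs] / s_n
            d_phi0[qs, n] += (wr * (k1v[:, None] * sp - lamv[:, None] * cp * ss)).sum(1)
            d_psi0[qs, n] += (wr * (k2v[:, None] * ss - lamv[:, None] * sp * cs)).sum(1)
            if self.shapes:
                sqrt_kk = np.sqrt(k1v * k2v)
                dl_dk1 = np.where(rv == 0, 0.0, 0.5 * rv * np.sqrt(k2v / k1v))
                dl_dk2 = np.where(rv == 0, 0.0, 0.5 * rv * np.sqrt(k1v / k2v))
                d_k1[qs, n] += (wr * (cp + dl_dk1[:, None] * cross)).sum(1) - w_q * (
                    dt_dk1 + dt_dlam * dl_dk1
                )
                d_k2[qs, n] += (wr * (cs + dl_dk2[:, None] * cross)).sum(1) - w_q * (
                    dt_dk2 + dt_dlam * dl_dk2
                )
                d_rho[qs, n] += sqrt_kk * ((wr * cross).sum(1) - w_q * dt_dlam)

        d_alpha = e_gamma - gamma * e_gamma.sum()
        parts = [d_alpha, d_phi0[self.valid], d_psi0[self.valid]]
        if self.shapes:
            parts += [d_k1[self.valid], d_k2[self.valid], d_rho[self.valid]]
        grad = np.concatenate(parts)
        return -total, -grad

    def rebuild(self, x, gamma) -> MixtureModel:
        _, f = self.unpack(x)
        return MixtureModel(
            gamma=gamma,
            phi0=f["phi0"], psi0=f["psi0"],
            kappa1=f["kappa1"], kappa2=f["kappa2"], rho=f["rho"],
            residue_ids=self.model.residue_ids,
            valid=self.valid,
            init_phi0=self.model.init_phi0, init_psi0=self.model.init_psi0,
        )


def _check_grids(grids):
    for g in grids:
        if not g.normalized:
            raise ValueError(f"grid for residue {g.residue_id} is not normalized")


def model_log_likelihood(model: MixtureModel, grids) -> float:
    """Voxel-weighted mixture log-likelihood L (nats) of the model."""
    _check_grids(grids)
    obj = _Objective(model, grids, FitConfig())
    value, _ = obj.value_and_grad(obj.pack(model.gamma, model))
    return -value


def model_gradient(model: MixtureModel, grids) -> dict:
    """Analytic gradient of the log-likelihood.

    Returned as a dict with key ``"alpha"`` (gradient in the softmax
    population parameterization, length Q) and keys ``"phi0"``, ``"psi0"``,
    ``"kappa1"``, ``"kappa2"``, ``"rho"`` of shape (Q, N) (zero where a
    mode is invalid).
    """
    _check_grids(grids)
    obj = _Objective(model, grids, FitConfig())
    _, grad = obj.value_and_grad(obj.pack(model.gamma, model))
    grad = -grad
    out = {"alpha": grad[: obj.q_count]}
    offset = obj.q_count
    for name in ("phi0", "psi0", "kappa1", "kappa2", "rho"):
        full = np.zeros_like(model.phi0)
        full[obj.valid] = grad[offset:offset + obj.n_modes]
        out[name] = full
        offset += obj.n_modes
    return out


def fit_once(grids, init: MixtureModel, config: FitConfig, gamma_init) -> FitRun:
    """One bounded quasi-Newton maximization from a given population start.

    Mode centers start at ``init``'s current values and are constrained
    within +/- ``config.drift_limit`` degrees of the snapshot in
    ``init.init_phi0`` / ``init.init_psi0``.  Non-convergence is reported
    via the run status, never raised.
    """
    _check_grids(grids)
    gamma_init = np.asarray(gamma_init, dtype=float)
    if np.any(gamma_init < 0) or abs(gamma_init.sum() - 1.0) > 1e-9:
        raise ValueError("gamma_init must lie on the simplex")
    obj = _Objective(init, grids, config)
    x0 = obj.pack(gamma_init, init)
    try:
        res = minimize(
            obj.value_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=obj.bounds(),
            options={
                "maxiter": config.max_iterations,
                "gtol": config.gradient_tolerance,
                "ftol": config.ftol,
            },
        )
    except (FloatingPointError, ValueError):
        return FitRun("failed", gamma_init, -np.inf)
    if not np.all(np.isfinite(res.x)) or not math.isfinite(res.fun):
        return FitRun("failed", gamma_init, -np.inf)
    alpha = res.x[: obj.q_count]
    gamma = np.exp(alpha - _lse(alpha))
    gamma /= gamma.sum()
    status = "converged" if res.success else "failed"
    return FitRun(status, gamma, -res.fun, obj.rebuild(res.x, gamma))


def fit_multistart(grids, init: MixtureModel, config: FitConfig) -> FitResult:
    """Multi-start protocol: ``config.n_starts`` fits from flat-Dirichlet
    population draws; failed runs are discarded; mean +/- SD of gamma over
    converged runs is reported, renormalized to sum 1."""
    rng = np.random.default_rng(config.seed)
    q_count = init.n_conformations
    runs = []
    for _ in range(config.n_starts):
        gamma0 = rng.dirichlet(np.ones(q_count))
        runs.append(fit_once(grids, init, config, gamma0))
    good = [r for r in runs if r.status == "converged"]
    if not good:
        raise RuntimeError("all multi-start runs failed to converge")
    gammas = np.array([r.gamma for r in good])
    mean = gammas.mean(axis=0)
    mean = mean / mean.sum()
    sd = gammas.std(axis=0, ddof=1) if len(good) > 1 else np.zeros(q_count)
    best = max(good, key=lambda r: r.log_likelihood)
    return FitResult(
        runs=runs,
        mean_gamma=mean,
        sd_gamma=sd,
        n_failed=len(runs) - len(good),
        best=best,
    )
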