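import math

import numpy as np
import pytest

from ramamix.torus_model import BivariateSineParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_sine_params(rng, n=1, kappa_max=50.0, rho_max=0.95):
    """Random valid sine-model parameter sets for property checks."""
    out = []
    for _ in range(n):
        out.append(
            BivariateSineParams(
                phi0=rng.uniform(-math.pi, math.pi),
                psi0=rng.uniform(-math.pi, math.pi),
                kappa1=rng.uniform(0.0, kappa_max),
                kappa2=rng.uniform(0.0, kappa_max),
                rho=rng.uniform(-rho_max, rho_max),
            )
        )
    return out


def quadrature_log_partition(kappa1, kappa2, lam, n=400):
    """Independent oracle: ln of the 2D trapezoid quadrature of exp(W)
    over the torus (the integrand is periodic, so the trapezoid rule
    converges spectrally)."""
    theta = np.linspace(-math.pi, math.pi, n, endpoint=False)
    phi, psi = np.meshgrid(theta, theta, indexing="ij")
    w = kappa1 * np.cos(phi) + kappa2 * np.cos(psi) + lam * np.sin(phi) * np.sin(psi)
    wmax = w.max()
    step = 2.0 * math.pi / n
    return wmax + math.log(np.exp(w - wmax).sum() * step * step)
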