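"""Generative pSFT model: log-Gaussian SF response, gamma HIRF, predicted BOLD.

The population response to a spatial frequency ``f`` is a Gaussian in
log-SF, peaking at the preferred frequency ``mu`` with bandwidth ``sigma``::

    R(f) = exp(-(log f - log mu)^2 / (2 sigma^2))

The predicted BOLD percent signal change is the response track convolved
with a gamma-shaped hemodynamic impulse response (shape ``n_phase``, scale
``tau``, onset delay ``delta``), scaled and offset::

    B(t) = beta0 + beta * (R[f(t)] * h)(t)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

# optimizer bounds on (mu, sigma, beta, beta0)
MU_BOUNDS = (0.009, 6.0)
SIGMA_BOUNDS = (0.1, 4.0)
BETA_BOUNDS = (-25.0, 25.0)
BETA0_BOUNDS = (-10.0, 10.0)


@dataclass(frozen=True)
class PSFTParams:
    """One voxel-condition tuning parameter set.

    mu     : preferred SF (cpd), the frequency of maximal response
    sigma  : tuning bandwidth, the SD of the Gaussian in log-SF
    beta   : BOLD scaling coefficient (percent signal change units)
    beta0  : baseline offset
    """

    mu: float
    sigma: float
    beta: float = 1.0
    beta0: float = 0.0

    def in_bounds(self) -> bool:
        return (
            MU_BOUNDS[0] <= self.mu <= MU_BOUNDS[1]
            and SIGMA_BOUNDS[0] <= self.sigma <= SIGMA_BOUNDS[1]
            and BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]
            and BETA0_BOUNDS[0] <= self.beta0 <= BETA0_BOUNDS[1]
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma, self.beta, self.beta0])


@dataclass(frozen=True)
class HIRFSpec:
    """Hemodynamic impulse response parameters (fixed, not fitted)."""

    tau: float = 1.08
    n_phase: int = 3
    onset_delay: float = 2.05

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_phase != int(self.n_phase) or self.n_phase < 1:
            raise ValueError("n_phase must be a positive integer")


def sf_response(f, mu: float, sigma: float) -> np.ndarray:
    """Log-Gaussian response in [0, 1]; maximal (=1) at ``f == mu``."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or mu <= 0 or sigma <= 0:
        raise ValueError("f, mu and sigma must all be positive")
    z = (np.log(f) - math.log(mu)) / sigma
    return np.exp(-0.5 * z * z)


def hirf_kernel(
    spec: HIRFSpec | None = None,
    tr: float = 1.0,
    length: float = 32.0,
) -> np.ndarray:
    """Gamma HIRF sampled at TR midpoints over ``length`` seconds.

    h(t) = ((t - d)/tau)^(n-1) exp(-(t - d)/tau) / (tau (n-1)!) for t >= d,
    i.e. a gamma density with shape ``n_phase`` and scale ``tau`` shifted by
    the onset delay, so the continuous kernel integrates to one.  Warns if
    the sampled window captures < 99% of the kernel mass.
    """
    spec = spec or HIRFSpec()
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(tr / 2, length, tr)
    h = gamma_dist.pdf(t, a=spec.n_phase, scale=spec.tau, loc=spec.onset_delay)
    if h.sum() * tr < 0.99:
        import warnings

        warnings.warn(
            f"HIRF window of {length} s captures only {h.sum() * tr:.3f} of "
            "the kernel mass; increase `length`",
            stacklevel=2,
        )
    return h * tr


def predict_bold(
    sf_per_tr,
    params: PSFTParams,
    spec: HIRFSpec | None = None,
    tr: float = 1.0,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted BOLD percent signal change for an SF track.

    Causal discrete convolution of the log-Gaussian response track with the
    gamma HIRF, truncated to the input length.  A precomputed ``kernel``
    (from `hirf_kernel`) may be passed to avoid recomputation in fitting
    loops.
    """
    sf = np.asarray(sf_per_tr, dtype=float)
    if sf.size == 0:
        raise ValueError("empty SF track")
    if not np.all(np.isfinite(sf)):
        raise ValueError("SF track contains non-finite values")
    if kernel is None:
        kernel = hirf_kernel(spec, tr=tr)
    r = sf_response(sf, params.mu, params.sigma)
    conv = signal.fftconvolve(r, kernel)[: sf.size]
    return params.beta0 + params.beta * conv
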