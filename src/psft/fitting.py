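"""Per-voxel pSFT estimation.

The measured series for one voxel and attention condition is built by
splicing the matching task blocks (each with its trailing blank) across
runs.  Estimation then proceeds in three stages, mirroring the standard
coarse-to-fine pRF-style pipeline:

1. coarse grid: 10 log-spaced ``mu`` x 10 linear ``sigma`` over the full
   parameter box, with ``beta=1, beta0=0`` fixed;
2. fine grid: 100 x 100 between half and double the coarse optimum
   (clipped to the global bounds), ties averaged;
3. bounded nonlinear least squares over ``(mu, sigma, beta, beta0)`` from
   the fine-grid start, minimizing the sum of squared errors.

`PSFTRegressor` packages the three stages as a scikit-learn estimator
(``fit(X, y)`` with ``X`` the SF-per-TR track, ``y`` the measured BOLD
percent signal change); the module-level functions expose the stages
individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from sklearn.base import BaseEstimator, RegressorMixin

from .design import RunDesign, SFSequence
from .model import (
    BETA0_BOUNDS,
    BETA_BOUNDS,
    MU_BOUNDS,
    SIGMA_BOUNDS,
    HIRFSpec,
    PSFTParams,
    hirf_kernel,
    predict_bold,
)

__all__ = [
    "SplicedData",
    "PSFTFit",
    "GridResult",
    "PSFTRegressor",
    "concatenate_condition_blocks",
    "percent_signal_change",
    "coarse_grid_search",
    "fine_grid_search",
    "fit_psft",
    "r_squared",
]


@dataclass(frozen=True)
class SplicedData:
    """Condition-spliced series: matching blocks (plus trailing blanks)
    concatenated in run order."""

    sf_per_tr: np.ndarray = field(repr=False)
    series: np.ndarray | None = field(repr=False)
    boundaries: tuple[int, ...]  # start index of each spliced block
    n_blocks: int

    def split_blocks(self) -> list[np.ndarray]:
        """Recover the individual spliced blocks of the series."""
        if self.series is None:
            raise ValueError("no measured series attached")
        edges = list(self.boundaries) + [len(self.series)]
        return [self.series[a:b] for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class PSFTFit:
    """Result of fitting one voxel x condition."""

    params: PSFTParams
    sse: float
    r2: float
    converged: bool
    init: PSFTParams
    voxel_id: object = None
    condition: str | None = None


@dataclass(frozen=True)
class GridResult:
    mu: float
    sigma: float
    sse: float
    mu_grid: np.ndarray = field(repr=False)
    sigma_grid: np.ndarray = field(repr=False)
    sse_surface: np.ndarray = field(repr=False)  # shape (len(mu), len(sigma))


def concatenate_condition_blocks(runs, condition: str) -> SplicedData:
    """Splice the blocks of one condition across runs.

    ``runs`` is an iterable of ``(series, design, sfseq)`` triples (``series``
    may be None to splice the stimulus track alone).  Each matching block
    contributes its TRs plus the trailing blank, in run order; the SF track
    is spliced identically, blanks carrying the sentinel SF.
    """
    sf_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []
    boundaries: list[int] = []
    have_series = True
    pos = 0
    n_blocks = 0
    for i, (series, design, sfseq) in enumerate(runs):
        if not isinstance(design, RunDesign) or not isinstance(sfseq, SFSequence):
            raise TypeError("each run must be a (series, RunDesign, SFSequence) triple")
        blocks = design.condition_blocks(condition)
        if not blocks:
            raise ValueError(f"condition {condition!r} absent from run {i}")
        for b in blocks:
            sl = design.block_tr_slice(b)
            sf_parts.append(sfseq.sf_per_tr[sl])
            if series is None:
                have_series = False
            else:
                series = np.asarray(series, dtype=float)
                if series.size != design.n_trs:
                    raise ValueError(
                        f"run {i} series has {series.size} TRs, design expects {design.n_trs}"
                    )
                y_parts.append(series[sl])
            boundaries.append(pos)
            pos += sl.stop - sl.start
            n_blocks += 1
    return SplicedData(
        sf_per_tr=np.concatenate(sf_parts),
        series=np.concatenate(y_parts) if (have_series and y_parts) else None,
        boundaries=tuple(boundaries),
        n_blocks=n_blocks,
    )


def percent_signal_change(series, blank_mask=None) -> np.ndarray:
    """Convert a raw-intensity series to percent signal change.

    The normalizer is the mean over blank TRs (``blank_mask``), falling
    back to the grand mean when no blanks are flagged.
    """
    x = np.asarray(series, dtype=float)
    if blank_mask is not None and np.any(blank_mask):
        m = x[np.asarray(blank_mask, bool)].mean()
    else:
        m = x.mean()
    if m == 0:
        raise ValueError("zero baseline; cannot form percent signal change")
    return 100.0 * (x - m) / m


def r_squared(predicted, measured) -> float:
    """Percent variance explained: 100 * (1 - SSE / TSS about the mean).

    Negative when the prediction is worse than the mean; 0 (with a warning)
    for a zero-variance measured series.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if p.shape != y.shape or y.size < 2:
        raise ValueError("predicted and measured must have equal length >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        warnings.warn("zero-variance measured series; R^2 defined as 0", stacklevel=2)
        return 0.0
    sse = float(np.sum((y - p) ** 2))
    return 100.0 * (1.0 - sse / tss)


# ---------------------------------------------------------------------------
# grid search


def _grid_sse(y, sf, mus, sigmas, kernel) -> np.ndarray:
    """SSE surface over a (mu, sigma) grid with beta=1, beta0=0.

    Vectorized: responses for all cells are formed as one matrix and
    convolved with the HIRF in a single batched FFT.
    """
    y = np.asarray(y, float)
    logf = np.log(np.asarray(sf, float))
    n = logf.size
    d = logf[None, :] - np.log(mus)[:, None]  # (M, n)
    z = d[:, None, :] / sigmas[None, :, None]  # (M, S, n)
    r = np.exp(-0.5 * z * z).reshape(-1, n)
    conv = signal.fftconvolve(r, kernel[None, :], axes=1)[:, :n]
    sse = np.sum((y[None, :] - conv) ** 2, axis=1)
    return sse.reshape(len(mus), len(sigmas))


def _round_sig(a: np.ndarray, digits: int = 12) -> np.ndarray:
    """Round to ``digits`` significant figures (tie detection tolerance)."""
    a = np.asarray(a, float)
    out = a.copy()
    nz = a != 0
    mag = np.floor(np.log10(np.abs(a[nz])))
    factor = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(a[nz] * factor) / factor
    return out


def _best_cell(mus, sigmas, sse) -> tuple[float, float, float]:
    """Minimizing (mu, sigma); exact ties (after 12-significant-digit
    rounding) are averaged."""
    rounded = _round_sig(sse)
    lo = rounded.min()
    ii, jj = np.nonzero(rounded == lo)
    return float(mus[ii].mean()), float(sigmas[jj].mean()), float(sse[ii, jj].min())


def coarse_grid_search(
    y,
    sf,
    kernel: np.ndarray | None = None,
    shape: tuple[int, int] = (10, 10),
) -> GridResult:
    """Stage 1: log-spaced mu x linear sigma over the full bounds."""
    if kernel is None:
        kernel = hirf_kernel()
    mus = np.logspace(np.log10(MU_BOUNDS[0]), np.log10(MU_BOUNDS[1]), shape[0])
    sigmas = np.linspace(SIGMA_BOUNDS[0], SIGMA_BOUNDS[1], shape[1])
    sse = _grid_sse(y, sf, mus, sigmas, kernel)
    mu, sigma, best = _best_cell(mus, sigmas, sse)
    return GridResult(mu, sigma, best, mus, sigmas, sse)


def fine_grid_search(
    y,
    sf,
    coarse_best: tuple[float, float] | GridResult,
    kernel: np.ndarray | None = None,
    shape: tuple[int, int] = (100, 100),
) -> GridResult:
    """Stage 2: refine between half and double the coarse optimum,
    clipped to the global bounds."""
    if kernel is None:
        kernel = hirf_kernel()
    if isinstance(coarse_best, GridResult):
        mu_c, sig_c = coarse_best.mu, coarse_best.sigma
    else:
        mu_c, sig_c = coarse_best
    mu_lo = max(mu_c / 2, MU_BOUNDS[0])
    mu_hi = min(mu_c * 2, MU_BOUNDS[1])
    sig_lo = max(sig_c / 2, SIGMA_BOUNDS[0])
    sig_hi = min(sig_c * 2, SIGMA_BOUNDS[1])
    mus = np.logspace(np.log10(mu_lo), np.log10(mu_hi), shape[0])
    sigmas = np.linspace(sig_lo, sig_hi, shape[1])
    sse = _grid_sse(y, sf, mus, sigmas, kernel)
    mu, sigma, best = _best_cell(mus, sigmas, sse)
    return GridResult(mu, sigma, best, mus, sigmas, sse)


# ---------------------------------------------------------------------------
# nonlinear stage


def _sse_at(y, sf, params: PSFTParams, kernel) -> float:
    pred = predict_bold(sf, params, kernel=kernel)
    return float(np.sum((y - pred) ** 2))


def fit_psft(
    y,
    sf,
    init: PSFTParams,
    kernel: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    voxel_id=None,
    condition: str | None = None,
) -> PSFTFit:
    """Stage 3: bounded least squares on (mu, sigma, beta, beta0) from ``init``.

    The returned fit never has SSE above the initializer's: if the local
    optimizer fails or regresses, the init parameters are returned with
    ``converged=False``.
    """
    y = np.asarray(y, float)
    sf = np.asarray(sf, float)
    if kernel is None:
        kernel = hirf_kernel()
    if not init.in_bounds():
        raise ValueError(f"init {init} outside the parameter bounds")

    logf = np.log(sf)

    def residual(p):
        z = (logf - np.log(p[0])) / p[1]
        r = np.exp(-0.5 * z * z)
        conv = signal.fftconvolve(r, kernel)[: y.size]
        return y - (p[3] + p[2] * conv)

    lb = [MU_BOUNDS[0], SIGMA_BOUNDS[0], BETA_BOUNDS[0], BETA0_BOUNDS[0]]
    ub = [MU_BOUNDS[1], SIGMA_BOUNDS[1], BETA_BOUNDS[1], BETA0_BOUNDS[1]]
    x0 = np.clip(init.as_array(), lb, ub)
    init_sse = _sse_at(y, sf, init, kernel)
    try:
        res = optimize.least_squares(
            residual,
            x0,
            bounds=(lb, ub),
            method="trf",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=max_iter * 5,
        )
        fitted = PSFTParams(*res.x)
        fitted_sse = float(2 * res.cost)
        ok = bool(res.success)
    except Exception:  # optimizer blow-up: fall back to the initializer
        fitted, fitted_sse, ok = init, init_sse, False

    if fitted_sse > init_sse:
        fitted, fitted_sse, ok = init, init_sse, False
    pred = predict_bold(sf, fitted, kernel=kernel)
    return PSFTFit(
        params=fitted,
        sse=fitted_sse,
        r2=r_squared(pred, y),
        converged=ok,
        init=init,
        voxel_id=voxel_id,
        condition=condition,
    )


class PSFTRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for one voxel-condition pSFT fit.

    Parameters
    ----------
    hirf : HIRFSpec, optional
        Hemodynamic kernel parameters (tau, phase delay, onset delay).
    tr : float
        Sampling interval of the series, seconds.
    kernel_length : float
        Support of the sampled HIRF, seconds.
    coarse_shape, fine_shape : (int, int)
        Grid sizes of the two initialization stages.
    tol : float
        ftol/xtol/gtol of the bounded least-squares stage.
    max_iter : int
        Iteration cap of the least-squares stage.

    Attributes
    ----------
    mu_, sigma_, beta_, beta0_ : float
        Fitted tuning peak (cpd), bandwidth, scaling and baseline.
    sse_, r2_ : float
        Sum of squared errors and percent variance explained.
    init_ : PSFTParams
        Grid-search starting point.
    converged_ : bool

    Examples
    --------
    >>> est = PSFTRegressor().fit(sf_track, bold)   # doctest: +SKIP
    >>> est.mu_, est.sigma_                         # doctest: +SKIP
    """

    def __init__(
        self,
        hirf: HIRFSpec | None = None,
        tr: float = 1.0,
        kernel_length: float = 32.0,
        coarse_shape: tuple[int, int] = (10, 10),
        fine_shape: tuple[int, int] = (100, 100),
        tol: float = 1e-10,
        max_iter: int = 500,
    ):
        self.hirf = hirf
        self.tr = tr
        self.kernel_length = kernel_length
        self.coarse_shape = coarse_shape
        self.fine_shape = fine_shape
        self.tol = tol
        self.max_iter = max_iter

    def _validate_sf(self, X) -> np.ndarray:
        sf = np.asarray(X, dtype=float)
        if sf.ndim == 2:
            if sf.shape[1] != 1:
                raise ValueError("X must be the SF track: shape (n,) or (n, 1)")
            sf = sf[:, 0]
        if sf.ndim != 1 or sf.size == 0:
            raise ValueError("X must be a non-empty 1-d SF track")
        if np.any(sf <= 0):
            raise ValueError("SF values must be positive (blanks use the sentinel SF)")
        return sf

    def _kernel(self) -> np.ndarray:
        return hirf_kernel(self.hirf or HIRFSpec(), tr=self.tr, length=self.kernel_length)

    def fit(self, X, y):
        sf = self._validate_sf(X)
        y = np.asarray(y, dtype=float)
        if y.shape != sf.shape:
            raise ValueError("X and y lengths differ")
        kernel = self._kernel()
        coarse = coarse_grid_search(y, sf, kernel, self.coarse_shape)
        fine = fine_grid_search(y, sf, coarse, kernel, self.fine_shape)
        init = PSFTParams(fine.mu, fine.sigma, 1.0, 0.0)
        fit = fit_psft(y, sf, init, kernel, tol=self.tol, max_iter=self.max_iter)
        self.mu_ = fit.params.mu
        self.sigma_ = fit.params.sigma
        self.beta_ = fit.params.beta
        self.beta0_ = fit.params.beta0
        self.sse_ = fit.sse
        self.r2_ = fit.r2
        self.init_ = fit.init
        self.converged_ = fit.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mu_")
        sf = self._validate_sf(X)
        params = PSFTParams(self.mu_, self.sigma_, self.beta_, self.beta0_)
        return predict_bold(sf, params, kernel=self._kernel())

    def fit_result(self, voxel_id=None, condition=None) -> PSFTFit:
        """The fit repackaged as a `PSFTFit` record."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mu_")
        return PSFTFit(
            params=PSFTParams(self.mu_, self.sigma_, self.beta_, self.beta0_),
            sse=self.sse_,
            r2=self.r2_,
            converged=self.converged_,
            init=self.init_,
            voxel_id=voxel_id,
            condition=condition,
        )
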