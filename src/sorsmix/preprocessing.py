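"""Analysis-window restriction and iterative polynomial baseline removal.

The fluorescence background underlying Raman spectra is broad and smooth;
a single unconstrained polynomial fit would be pulled up by the Raman
peaks, so the fit is iterated with clipping: after each fit the working
vector is replaced by the elementwise minimum of itself and the fit, which
progressively excludes peaks until the polynomial tracks only the smooth
background (the "ModPoly" scheme).  The corrected spectrum is the input
minus the converged fit; small negative residuals are retained -- they are
handled downstream when spectra are converted to probability vectors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, NumericalError
from .synthetic_data import SORSDataset, WavenumberGrid

_TINY = 1e-300


@dataclass(frozen=True)
class BaselineFitConfig:
    """Polynomial order, iteration cap, stopping rule and peak masking.

    ``refine_passes`` controls a final peak-masked re-fit: after the
    clipped iteration converges, channels whose residual exceeds
    ``mask_z`` robust standard deviations (MAD-based) are treated as peaks
    and excluded, and the polynomial is re-fit on the remaining baseline
    channels.  The clipped iteration alone systematically drags the
    polynomial below the true background near strong peaks (the clipping
    acts only downward), which biases corrected peak heights; the masked
    re-fit removes that bias.  Set ``refine_passes=0`` for the plain
    clipped fit.
    """

    poly_order: int = 5
    max_iter: int = 100
    tol: float = 1e-3
    refine_passes: int = 3
    mask_z: float = 3.0

    def __post_init__(self) -> None:
        if self.poly_order < 1:
            raise InvalidArgumentError("poly_order must be >= 1")
        if self.max_iter < 1:
            raise InvalidArgumentError("max_iter must be >= 1")
        if self.tol <= 0:
            raise InvalidArgumentError("tol must be positive")
        if self.refine_passes < 0:
            raise InvalidArgumentError("refine_passes must be >= 0")
        if self.mask_z <= 0:
            raise InvalidArgumentError("mask_z must be positive")


def restrict_window(dataset: SORSDataset, lo: float, hi: float) -> SORSDataset:
    """Keep only channels with ``lo <= nu <= hi``; offsets unchanged."""
    if not lo < hi:
        raise InvalidArgumentError(f"need lo < hi, got [{lo}, {hi}]")
    idx = dataset.grid.window_indices(lo, hi)
    if idx.size == 0:
        raise InvalidArgumentError(
            f"window [{lo}, {hi}] retains no channels of grid "
            f"[{dataset.grid.lo}, {dataset.grid.hi}]")
    grid = WavenumberGrid(dataset.grid.values[idx])
    metadata = dict(dataset.metadata, window=[float(lo), float(hi)])
    return dataclasses.replace(dataset, grid=grid,
                               intensities=dataset.intensities[:, idx],
                               metadata=metadata)


def _fit_basis(grid: WavenumberGrid, order: int):
    # Chebyshev basis on the grid mapped to [-1, 1]: well conditioned, and
    # a fixed design matrix lets all rows of a dataset share one pseudo-
    # inverse.
    x = 2.0 * (grid.values - grid.lo) / (grid.hi - grid.lo) - 1.0
    vander = np.polynomial.chebyshev.chebvander(x, order)
    pinv = np.linalg.pinv(vander)
    if not np.all(np.isfinite(pinv)):
        raise NumericalError("baseline fit design matrix is ill-conditioned")
    return vander, pinv


def baseline_correct_matrix(matrix: np.ndarray, grid: WavenumberGrid,
                            config: BaselineFitConfig | None = None
                            ) -> np.ndarray:
    """Baseline-correct every row of ``matrix`` (rows share the grid).

    Equivalent to calling :func:`baseline_correct` per row; rows converge
    independently (a converged row's fit is frozen while others iterate).
    """
    config = config or BaselineFitConfig()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise InvalidArgumentError("expected a 2-D spectral matrix")
    if matrix.shape[1] <= config.poly_order + 1:
        raise InvalidArgumentError(
            f"need more than poly_order + 1 = {config.poly_order + 1} "
            f"channels, got {matrix.shape[1]}")
    vander, pinv = _fit_basis(grid, config.poly_order)
    working = matrix.copy()
    fit = working @ pinv.T @ vander.T
    if not np.all(np.isfinite(fit)):
        raise NumericalError("baseline polynomial fit produced non-finite "
                             "values (degenerate spectra)")
    active = np.ones(matrix.shape[0], dtype=bool)
    final_fit = fit.copy()
    for _ in range(config.max_iter - 1):
        working[active] = np.minimum(working[active], fit[active])
        new_fit = working[active] @ pinv.T @ vander.T
        scale = np.maximum(np.abs(fit[active]).max(axis=1), _TINY)
        change = np.abs(new_fit - fit[active]).max(axis=1) / scale
        fit[active] = new_fit
        final_fit[active] = new_fit
        done = change < config.tol
        if np.any(done):
            idx = np.nonzero(active)[0][done]
            active[idx] = False
        if not np.any(active):
            break
    if config.refine_passes:
        for i in range(matrix.shape[0]):
            final_fit[i] = _masked_refit(matrix[i], final_fit[i], vander,
                                         config)
    return matrix - final_fit


def _masked_refit(spectrum: np.ndarray, fit: np.ndarray, vander: np.ndarray,
                  config: BaselineFitConfig) -> np.ndarray:
    """Re-fit the polynomial on channels classified as baseline.

    Peak channels are those whose residual exceeds ``mask_z`` robust
    (MAD-based) standard deviations above the median residual.
    """
    min_keep = vander.shape[1] + 2
    for _ in range(config.refine_passes):
        resid = spectrum - fit
        med = np.median(resid)
        mad = 1.4826 * np.median(np.abs(resid - med))
        keep = resid <= med + config.mask_z * (mad + _TINY)
        if keep.sum() < min_keep:
            break
        coef, *_ = np.linalg.lstsq(vander[keep], spectrum[keep], rcond=None)
        new_fit = vander @ coef
        if not np.all(np.isfinite(new_fit)):
            raise NumericalError("peak-masked baseline re-fit failed")
        fit = new_fit
    return fit


def baseline_correct(spectrum: np.ndarray, grid: WavenumberGrid,
                     config: BaselineFitConfig | None = None) -> np.ndarray:
    """Remove the smooth background from one spectrum.

    Iterative clipped polynomial fitting: fit, clip the working vector to
    the fit from above, refit; stop when the fit's maximum relative change
    drops below ``config.tol`` or after ``config.max_iter`` fits.  Returns
    ``spectrum - final_fit`` (not clipped at zero).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise InvalidArgumentError("expected a 1-D spectrum")
    return baseline_correct_matrix(spectrum[None, :], grid, config)[0]


def baseline_correct_dataset(dataset: SORSDataset,
                             config: BaselineFitConfig | None = None
                             ) -> SORSDataset:
    """Baseline-correct every spectrum of a dataset."""
    config = config or BaselineFitConfig()
    corrected = baseline_correct_matrix(dataset.intensities, dataset.grid,
                                        config)
    metadata = dict(dataset.metadata,
                    baseline=dataclasses.asdict(config))
    return dataclasses.replace(dataset, intensities=corrected,
                               metadata=metadata)


def preprocess(dataset: SORSDataset, lo: float = 500.0, hi: float = 2000.0,
               config: BaselineFitConfig | None = None) -> SORSDataset:
    """Standard preprocessing: restrict to the analysis window, then
    baseline-correct each spectrum."""
    return baseline_correct_dataset(restrict_window(dataset, lo, hi), config)


def normalize(spectrum: np.ndarray, mode: str = "max") -> np.ndarray:
    """Scale a spectrum: ``max`` -> peak 1, ``area`` -> sum 1, ``none``.

    Display aid only -- the analysis pipeline runs on unnormalized,
    background-corrected spectra.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if mode == "none":
        return spectrum
    if mode == "max":
        denom = spectrum.max() if spectrum.size else 0.0
    elif mode == "area":
        denom = spectrum.sum()
    else:
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        raise InvalidArgumentError(
            f"cannot {mode}-normalize a spectrum with zero {mode}")
    return spectrum / denom
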