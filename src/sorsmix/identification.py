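"""Spectral matching by information divergence and depth-profile diagnostics.

Resolved pure component spectra are matched against a reference library by
spectral information divergence (SID): both spectra are normalized to
probability vectors and the two Kullback-Leibler relative entropies are
summed, ``SID = D(p||q) + D(q||p)``.  SID is symmetric, non-negative and
zero only for identical probability vectors; the library entry with the
smallest SID is the assigned label.

The module also computes the depth-profiling diagnostics of an offset
scan: the spatial profile of a single wavenumber, the windowed peak
intensity, the powder/capsule peak-intensity ratio as a function of
offset, and an SNR-based per-offset detectability flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .exceptions import GridMismatchError, InvalidArgumentError
from .sma import SMAResult
from .synthetic_data import (KEY_PEAKS, ReferenceLibrary, SORSDataset,
                             WavenumberGrid)

#: Default probability floor, as a fraction of total spectrum mass.
DEFAULT_FLOOR_EPS = 1e-12
#: Default peak window half-width: half the instrument FWHM, cm^-1.
DEFAULT_HALF_WINDOW = 7.0
#: Peak-free region used to estimate the noise scale from data, cm^-1.
NOISE_REGION = (1700.0, 1900.0)


# ---------------------------------------------------------------------------
# SID
# ---------------------------------------------------------------------------

def to_probability(spectrum: np.ndarray,
                   floor_eps: float = DEFAULT_FLOOR_EPS) -> np.ndarray:
    """Convert a spectrum to a probability vector.

    Negative intensities (baseline-correction residuals) are clipped to
    zero, a floor of ``floor_eps`` times the remaining total mass is added
    to every channel, and the vector is normalized to sum 1.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    clipped = np.clip(spectrum, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise InvalidArgumentError(
            "spectrum has no positive intensity; cannot form a "
            "probability vector")
    p = clipped + floor_eps * total
    return p / p.sum()


def sid(x: np.ndarray, y: np.ndarray, floor_eps: float = DEFAULT_FLOOR_EPS,
        base: str = "e") -> float:
    """Spectral information divergence between two spectra.

    ``SID = D(p||q) + D(q||p)`` with ``D(p||q) = sum p ln(p/q)``; reported
    in nats (``base='e'``, default) or bits (``base='2'``).  With
    ``floor_eps=0`` a channel where exactly one vector vanishes makes the
    divergence infinite; +inf is returned with a warning.
    """
    p = to_probability(x, floor_eps)
    q = to_probability(y, floor_eps)
    value = float(rel_entr(p, q).sum() + rel_entr(q, p).sum())
    if math.isinf(value):
        warnings.warn("SID is infinite: a zero channel faces positive mass "
                      "(raise floor_eps to avoid this)", stacklevel=2)
    if base == "2":
        value /= math.log(2.0)
    elif base != "e":
        raise InvalidArgumentError(f"unknown log base {base!r}")
    return value


@dataclass
class IdentificationReport:
    """Per-resolved-spectrum SID tables, labels and margins."""

    entries: list[dict]

    @property
    def labels(self) -> list[str]:
        return [e["best_label"] for e in self.entries]

    def to_dict(self) -> dict:
        return {"components": self.entries}


def identify_components(result: SMAResult, library: ReferenceLibrary,
                        grid: WavenumberGrid | None = None,
                        floor_eps: float = DEFAULT_FLOOR_EPS,
                        base: str = "e") -> IdentificationReport:
    """Label each resolved spectrum with its minimum-SID library entry.

    The library references are evaluated on the result's grid; the grids
    must be identical (no silent resampling).
    """
    grid = grid or result.grid
    if grid is None:
        raise GridMismatchError("no wavenumber grid attached to the result")
    if result.grid is not None and not np.array_equal(grid.values,
                                                      result.grid.values):
        raise GridMismatchError("result grid differs from requested grid")
    references = library.spectra(grid)
    entries = []
    for idx, spectrum in enumerate(result.S):
        sids = {name: sid(spectrum, ref, floor_eps, base)
                for name, ref in references.items()}
        ranked = sorted(sids, key=sids.get)
        best = ranked[0]
        margin = (sids[ranked[1]] - sids[best]) if len(ranked) > 1 else math.inf
        entries.append({
            "component_index": idx,
            "pure_wavenumber": (result.pure_wavenumbers[idx]
                                if result.pure_wavenumbers else None),
            "sid": sids,
            "best_label": best,
            "best_sid": sids[best],
            "margin": margin,
        })
    return IdentificationReport(entries=entries)


# ---------------------------------------------------------------------------
# Depth-profiling diagnostics
# ---------------------------------------------------------------------------

def extract_spatial_profile(dataset: SORSDataset, nu: float) -> np.ndarray:
    """Intensity versus offset at the channel nearest ``nu`` cm^-1."""
    return dataset.intensities[:, dataset.grid.index_of(nu)]


def peak_intensity(grid: WavenumberGrid, spectrum: np.ndarray, center: float,
                   half_window: float = DEFAULT_HALF_WINDOW) -> float:
    """Maximum intensity within ``center +/- half_window`` cm^-1.

    A windowed maximum (default half-window = half the instrument FWHM)
    tolerates one-channel discretization shifts of the peak position.
    """
    idx = grid.window_indices(center - half_window, center + half_window)
    if idx.size == 0:
        raise InvalidArgumentError(
            f"window {center} +/- {half_window} cm^-1 contains no channel")
    return float(np.max(np.asarray(spectrum, dtype=float)[idx]))


def ratio_profile(dataset: SORSDataset, chem_center: float,
                  capsule_center: float = KEY_PEAKS["capsule"],
                  half_window: float = DEFAULT_HALF_WINDOW,
                  capsule_floor: float = 1e-12) -> pd.DataFrame:
    """Powder/capsule peak-intensity ratio at every offset.

    Expects a background-corrected dataset.  Rows where the capsule peak
    intensity falls below ``capsule_floor`` get ratio ``+inf`` and a
    ``capsule_floored`` flag instead of a division blow-up.
    """
    ratios, flags = [], []
    for row in dataset.intensities:
        chem = peak_intensity(dataset.grid, row, chem_center, half_window)
        cap = peak_intensity(dataset.grid, row, capsule_center, half_window)
        if cap < capsule_floor:
            ratios.append(math.inf)
            flags.append(True)
        else:
            ratios.append(chem / cap)
            flags.append(False)
    return pd.DataFrame({"offset_mm": dataset.offsets, "ratio": ratios,
                         "capsule_floored": flags})


def estimate_noise_scale(dataset: SORSDataset,
                         region: tuple[float, float] = NOISE_REGION
                         ) -> np.ndarray:
    """Per-offset noise estimate: std of a peak-free spectral region."""
    idx = dataset.grid.window_indices(*region)
    if idx.size < 2:
        raise InvalidArgumentError(
            f"noise region {region} contains fewer than 2 channels")
    return dataset.intensities[:, idx].std(axis=1)


def detectability(dataset: SORSDataset, center: float,
                  snr_threshold: float = 3.0,
                  half_window: float = DEFAULT_HALF_WINDOW,
                  noise_scale: float | np.ndarray | None = None) -> np.ndarray:
    """Per-offset boolean: is the peak at ``center`` above the noise floor?

    True where ``peak_intensity / noise_scale >= snr_threshold``.  The
    noise scale defaults to the per-offset standard deviation of the
    1700-1900 cm^-1 region, which is peak-free for the default library.
    """
    if noise_scale is None:
        noise_scale = estimate_noise_scale(dataset)
    noise = np.broadcast_to(np.maximum(np.asarray(noise_scale, dtype=float),
                                       1e-300), dataset.offsets.shape)
    peaks = np.array([peak_intensity(dataset.grid, row, center, half_window)
                      for row in dataset.intensities])
    return peaks / noise >= snr_threshold
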