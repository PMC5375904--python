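"""Seeded, parametric generator of spatially offset Raman scans.

Spatially offset Raman spectroscopy (SORS) collects Raman scattering at a
series of lateral offsets from the laser spot.  As the offset grows, the
collected signal is weighted increasingly toward deeper layers: the surface
contribution is attenuated faster than the subsurface one.  This module
emulates point-scan SORS acquisitions of a chemical powder (urea, ibuprofen
or acetaminophen) packed inside one to eight nested gelatin-capsule layers:

* a uniform wavenumber grid covering the instrument range 107-2560 cm^-1,
  with 1595 channels so that the 500-2000 cm^-1 analysis window holds
  exactly 975 channels;
* reference spectra built from per-component peak lists (Gaussian lines,
  instrument-limited 14 cm^-1 FWHM), normalized so the key peak of each
  component has unit height (urea 1009, ibuprofen 833, acetaminophen 859,
  gelatin capsule 644 cm^-1);
* a two-exponential mixing model giving the surface (capsule) and
  subsurface (powder) weights as functions of offset distance and layer
  count, calibrated so the 3-layer urea sample reproduces the measured
  powder/capsule peak-ratio endpoints (about 2 at 0 mm and 15 at 3 mm);
* a smooth, exponentially decaying fluorescence baseline and seeded
  heteroscedastic detector noise.

Every scan is reproducible bit-for-bit from an integer seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import InvalidArgumentError

logger = logging.getLogger("sorsmix.synthetic_data")

# ---------------------------------------------------------------------------
# Study-wide constants
# ---------------------------------------------------------------------------

#: Instrument wavenumber range, cm^-1.
FULL_RANGE = (107.0, 2560.0)
#: Channels of the default full grid; chosen so the analysis window below
#: contains exactly 975 channels.
N_CHANNELS = 1595
#: Analysis window, cm^-1; only this region is carried into the analysis.
ANALYSIS_WINDOW = (500.0, 2000.0)
#: Instrument-limited line width, cm^-1 full width at half maximum.
DEFAULT_FWHM = 14.0
#: Chemicals packed inside the capsule layers.
CHEMICALS = ("urea", "ibuprofen", "acetaminophen")
#: Capsule layer counts in the study design.
LAYER_COUNTS = tuple(range(1, 9))
#: Key (unit-height) peak position of each component, cm^-1.
KEY_PEAKS = {"urea": 1009.0, "ibuprofen": 833.0, "acetaminophen": 859.0,
             "capsule": 644.0}

# Peak tables: (center cm^-1, relative height).  Key peaks follow the
# component assignments above; minor-band positions/heights are synthetic
# stand-ins giving each component realistic multi-band structure, NOT
# literature band assignments.
_PEAK_TABLE: Mapping[str, tuple[tuple[float, float], ...]] = {
    "urea": ((1009.0, 1.0), (1646.0, 0.12), (1541.0, 0.08), (1175.0, 0.10)),
    "ibuprofen": ((833.0, 1.0), (746.0, 0.30), (1182.0, 0.22), (1608.0, 0.28)),
    "acetaminophen": ((859.0, 1.0), (797.0, 0.35), (1236.0, 0.28),
                      (1323.0, 0.30), (1648.0, 0.25)),
    "capsule": ((644.0, 1.0), (920.0, 0.25), (1270.0, 0.20), (1450.0, 0.35),
                (1670.0, 0.22)),
}


# ---------------------------------------------------------------------------
# Wavenumber grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberGrid:
    """Ordered, uniformly spaced Raman-shift axis in cm^-1.

    Shared by every spectrum of a dataset; strictly increasing and uniform
    to 1e-9 relative tolerance.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise InvalidArgumentError("grid must be a non-empty 1-D array")
        if values.size > 1:
            diffs = np.diff(values)
            if np.any(diffs <= 0):
                raise InvalidArgumentError("grid must be strictly increasing")
            spacing = diffs[0]
            if not np.allclose(diffs, spacing, rtol=1e-9, atol=0.0):
                raise InvalidArgumentError("grid spacing must be uniform")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    @property
    def spacing(self) -> float:
        if self.values.size < 2:
            raise InvalidArgumentError("spacing undefined for 1-channel grid")
        return float(self.values[1] - self.values[0])

    def index_of(self, nu: float) -> int:
        """Index of the channel nearest wavenumber ``nu`` (must lie in range)."""
        if nu < self.lo or nu > self.hi:
            raise InvalidArgumentError(
                f"wavenumber {nu} cm^-1 outside grid range "
                f"[{self.lo}, {self.hi}]")
        return int(np.argmin(np.abs(self.values - nu)))

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of channels with ``lo <= nu <= hi`` (possibly empty)."""
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]


def build_grid(lo: float, hi: float, n_channels: int) -> WavenumberGrid:
    """Uniform grid with first channel ``lo``, last ``hi``.

    Parameters
    ----------
    lo, hi
        Wavenumber bounds in cm^-1; ``hi`` must exceed ``lo``.
    n_channels
        Number of channels, at least 2.
    """
    if not hi > lo:
        raise InvalidArgumentError(f"need hi > lo, got [{lo}, {hi}]")
    if n_channels < 2:
        raise InvalidArgumentError("need at least 2 channels")
    return WavenumberGrid(np.linspace(lo, hi, int(n_channels)))


def default_full_grid() -> WavenumberGrid:
    """The default 1595-channel instrument grid over 107-2560 cm^-1."""
    return build_grid(*FULL_RANGE, N_CHANNELS)


def default_analysis_grid() -> WavenumberGrid:
    """Default full grid restricted to the 500-2000 cm^-1 analysis window."""
    grid = default_full_grid()
    idx = grid.window_indices(*ANALYSIS_WINDOW)
    return WavenumberGrid(grid.values[idx])


# ---------------------------------------------------------------------------
# Components and reference spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """One Raman line: center (cm^-1), FWHM (cm^-1), relative height, shape."""

    center: float
    fwhm: float = DEFAULT_FWHM
    height: float = 1.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise InvalidArgumentError("fwhm must be positive")
        if self.height <= 0:
            raise InvalidArgumentError("height must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise InvalidArgumentError(f"unknown peak shape {self.shape!r}")

    def profile(self, nu: np.ndarray) -> np.ndarray:
        delta = np.asarray(nu, dtype=float) - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * math.log(2.0)
                                        * (delta / self.fwhm) ** 2)
        gamma = self.fwhm / 2.0
        return self.height * gamma**2 / (delta**2 + gamma**2)


@dataclass(frozen=True)
class ComponentModel:
    """Named pure component defined by its peak list.

    Exactly one peak must have height 1.0 -- the key peak used for
    normalization and depth profiling.
    """

    name: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        key = [p for p in self.peaks if p.height == 1.0]
        if len(key) != 1:
            raise InvalidArgumentError(
                f"component {self.name!r} needs exactly one height-1.0 key "
                f"peak, found {len(key)}")

    @property
    def key_peak(self) -> PeakSpec:
        return next(p for p in self.peaks if p.height == 1.0)


def _component(name: str, shape: str = "gaussian") -> ComponentModel:
    peaks = tuple(PeakSpec(center=c, height=h, shape=shape)
                  for c, h in _PEAK_TABLE[name])
    return ComponentModel(name=name, peaks=peaks)


def reference_spectrum(model: ComponentModel, grid: WavenumberGrid) -> np.ndarray:
    """Evaluate a component's reference spectrum, normalized to max 1.0.

    The returned vector is non-negative with its global maximum at the
    channel nearest the key peak center.  If the grid does not cover a
    peak's center +/- 3 FWHM the peak is truncated and a warning is issued.
    """
    for peak in model.peaks:
        if (peak.center - 3 * peak.fwhm < grid.lo
                or peak.center + 3 * peak.fwhm > grid.hi):
            warnings.warn(
                f"grid [{grid.lo}, {grid.hi}] truncates the "
                f"{model.name} peak at {peak.center} cm^-1", stacklevel=2)
    spectrum = np.zeros(len(grid))
    for peak in model.peaks:
        spectrum += peak.profile(grid.values)
    peak_max = spectrum.max()
    if peak_max <= 0:
        raise InvalidArgumentError(
            f"no peak of component {model.name!r} falls on the grid")
    return spectrum / peak_max


@dataclass(frozen=True)
class ReferenceLibrary:
    """Pure-component models keyed by name, with spectrum evaluation."""

    components: Mapping[str, ComponentModel]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", dict(self.components))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.components)

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def model(self, name: str) -> ComponentModel:
        try:
            return self.components[name]
        except KeyError:
            raise LookupError(
                f"unknown component {name!r}; library has "
                f"{sorted(self.components)}") from None

    def spectrum(self, name: str, grid: WavenumberGrid) -> np.ndarray:
        return reference_spectrum(self.model(name), grid)

    def spectra(self, grid: WavenumberGrid) -> dict[str, np.ndarray]:
        return {name: self.spectrum(name, grid) for name in self.components}


def default_library(shape: str = "gaussian") -> ReferenceLibrary:
    """Library of the four study components (three powders + capsule)."""
    names = CHEMICALS + ("capsule",)
    return ReferenceLibrary({name: _component(name, shape) for name in names})


def measure_fwhm(grid: WavenumberGrid, spectrum: np.ndarray) -> float:
    """Full width at half maximum of the dominant peak, cm^-1.

    Locates the half-maximum crossings on each side of the global maximum
    by linear interpolation between adjacent channels.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    m = int(np.argmax(spectrum))
    half = spectrum[m] / 2.0
    if half <= 0:
        raise InvalidArgumentError("spectrum has no positive peak")
    nu = grid.values

    def crossing(step: int) -> float:
        i = m
        while 0 <= i + step < len(spectrum) and spectrum[i + step] >= half:
            i += step
        j = i + step
        if not 0 <= j < len(spectrum):
            raise InvalidArgumentError("half-maximum not reached on grid")
        frac = (spectrum[i] - half) / (spectrum[i] - spectrum[j])
        return float(nu[i] + frac * (nu[j] - nu[i]))

    return crossing(+1) - crossing(-1)


# ---------------------------------------------------------------------------
# Sample, scan, and mixing-model configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleConfig:
    """One capsule-chemical sample: which powder, under how many layers."""

    chemical: str
    n_layers: int
    wall_thickness_per_layer: float = 0.11  # mm, single capsule wall

    def __post_init__(self) -> None:
        if not 1 <= self.n_layers <= 8:
            raise InvalidArgumentError("n_layers must be between 1 and 8")
        if self.wall_thickness_per_layer <= 0:
            raise InvalidArgumentError("wall thickness must be positive")

    @property
    def total_wall_thickness(self) -> float:
        """Total surface-layer thickness in mm."""
        return self.n_layers * self.wall_thickness_per_layer


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry and the seed of one scan.

    Defaults reproduce the study design: offsets 0-10 mm in 0.1 mm steps,
    i.e. 101 spectra per sample.
    """

    offset_start: float = 0.0
    offset_stop: float = 10.0
    step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidArgumentError("step must be positive")
        if self.offset_stop < self.offset_start:
            raise InvalidArgumentError("offset_stop must be >= offset_start")

    @property
    def n_offsets(self) -> int:
        span = self.offset_stop - self.offset_start
        return int(math.floor(span / self.step + 1e-9)) + 1

    def offsets(self) -> np.ndarray:
        return self.offset_start + self.step * np.arange(self.n_offsets)


@dataclass(frozen=True)
class MixingParams:
    """Parametric surface/subsurface mixing, baseline, and noise model.

    The surface (capsule) weight is ``n * exp(-d / ell_s)`` and the
    subsurface (powder) weight ``A0 * exp(-kappa * n) * exp(-d / ell_p)``
    for offset ``d`` (mm) and layer count ``n``; because ``ell_p > ell_s``
    the subsurface/surface ratio grows as ``exp(d (1/ell_s - 1/ell_p))``,
    the defining qualitative behaviour of an offset scan.  Defaults are
    calibrated so the 3-layer urea sample has powder/capsule peak ratio
    2.00 at 0 mm and 15.0 at 3 mm, and so the 5-layer powder weight at
    0 mm is ~0.10 of the capsule weight (sub-noise at the default noise
    scale, matching the visibility pattern of the study).
    """

    ell_s: float = 1.0        # surface decay length, mm
    ell_p: float = 3.045      # subsurface decay length, mm
    A0: float = 249.5         # subsurface amplitude scale
    kappa: float = 1.2425     # per-layer subsurface attenuation, 1/layer
    c_s: float = 20.0         # baseline amplitude per unit surface weight
    c_p: float = 2.0          # baseline amplitude per unit subsurface weight
    tau_nu: float = 800.0     # baseline spectral decay constant, cm^-1
    sigma_read: float = 0.2   # additive read-noise std, key-peak units
    eta: float = 0.05         # shot-noise factor: var += eta * Raman signal

    def __post_init__(self) -> None:
        if not self.ell_p > self.ell_s > 0:
            raise InvalidArgumentError("need ell_p > ell_s > 0")
        if self.A0 <= 0 or self.kappa <= 0:
            raise InvalidArgumentError("A0 and kappa must be positive")
        if self.sigma_read < 0 or self.eta < 0:
            raise InvalidArgumentError("noise parameters must be >= 0")
        if self.tau_nu <= 0:
            raise InvalidArgumentError("tau_nu must be positive")

    def noiseless(self) -> "MixingParams":
        """Copy with all noise disabled (deterministic forward model)."""
        return dataclasses.replace(self, sigma_read=0.0, eta=0.0)


def mixing_weights(d, n: int, params: MixingParams):
    """Surface and subsurface weights at offset ``d`` mm under ``n`` layers.

    Returns ``(w_surface, w_subsurface)``; both strictly positive, and
    their ratio ``w_subsurface / w_surface`` strictly increasing in ``d``.
    Vectorized over ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidArgumentError("offset d must be >= 0")
    if n < 1:
        raise InvalidArgumentError("layer count n must be >= 1")
    w_surface = n * np.exp(-d / params.ell_s)
    w_subsurface = params.A0 * math.exp(-params.kappa * n) * np.exp(-d / params.ell_p)
    return w_surface, w_subsurface


def fluorescence_baseline(grid: WavenumberGrid, d: float, n: int,
                          params: MixingParams) -> np.ndarray:
    """Smooth fluorescence background at one offset.

    ``(c_s * w_surface + c_p * w_subsurface) * exp(-(nu - nu_min)/tau_nu)``:
    positive, monotonically decaying toward higher Raman shift, and decaying
    with offset because both mixing weights do.
    """
    w_s, w_p = mixing_weights(d, n, params)
    amplitude = params.c_s * w_s + params.c_p * w_p
    return amplitude * np.exp(-(grid.values - grid.lo) / params.tau_nu)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SORSDataset:
    """One offset scan: rows = offsets (mm), columns = wavenumber channels."""

    grid: WavenumberGrid
    offsets: np.ndarray
    intensities: np.ndarray
    sample_config: SampleConfig | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if intensities.shape != (offsets.size, len(self.grid)):
            raise InvalidArgumentError(
                f"intensity matrix shape {intensities.shape} inconsistent "
                f"with {offsets.size} offsets x {len(self.grid)} channels")
        if not np.all(np.isfinite(intensities)):
            raise InvalidArgumentError("intensities must be finite")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "intensities", intensities)

    @property
    def n_offsets(self) -> int:
        return self.offsets.size

    @property
    def n_channels(self) -> int:
        return len(self.grid)

    def row_at_offset(self, d: float) -> np.ndarray:
        """Spectrum at the offset nearest ``d`` mm."""
        return self.intensities[int(np.argmin(np.abs(self.offsets - d)))]


def dataset_seed(master_seed: int, chemical: str, n_layers: int) -> int:
    """Stable per-dataset sub-seed: CRC-32 of ``"{master}|{chem}|{n}"``.

    CRC-32 is stable across platforms and Python versions; the result is
    masked to 31 bits.
    """
    token = f"{master_seed}|{chemical}|{n_layers}".encode()
    return zlib.crc32(token) & 0x7FFFFFFF


def simulate_scan(sample: SampleConfig, scan: ScanConfig,
                  library: ReferenceLibrary,
                  params: MixingParams | None = None) -> SORSDataset:
    """Simulate one offset scan of a capsule-chemical sample.

    Row ``i`` is ``w_surface(d_i) * capsule + w_subsurface(d_i) * chemical
    + baseline(d_i) + noise`` where the per-channel noise is
    ``Normal(0, sqrt(sigma_read^2 + eta * raman_signal))``, seeded by
    ``scan.seed``.  With both noise parameters zero the output equals the
    deterministic model exactly.
    """
    params = params or MixingParams()
    grid = _grid_of(scan)
    capsule = library.spectrum("capsule", grid)
    chemical = library.spectrum(sample.chemical, grid)
    offsets = scan.offsets()
    w_s, w_p = mixing_weights(offsets, sample.n_layers, params)
    raman = np.outer(w_s, capsule) + np.outer(w_p, chemical)
    decay = np.exp(-(grid.values - grid.lo) / params.tau_nu)
    amplitude = params.c_s * w_s + params.c_p * w_p
    baseline = np.outer(amplitude, decay)
    clean = raman + baseline
    if params.sigma_read > 0 or params.eta > 0:
        rng = np.random.default_rng(scan.seed)
        sigma = np.sqrt(params.sigma_read ** 2
                        + params.eta * np.clip(raman, 0.0, None))
        noise = rng.standard_normal(clean.shape) * sigma
    else:
        noise = 0.0
    metadata = {
        "seed": scan.seed,
        "chemical": sample.chemical,
        "n_layers": sample.n_layers,
        "total_wall_thickness_mm": sample.total_wall_thickness,
        "mixing_params": dataclasses.asdict(params),
        "scan_config": dataclasses.asdict(scan),
    }
    return SORSDataset(grid=grid, offsets=offsets, intensities=clean + noise,
                       sample_config=sample, metadata=metadata)


def _grid_of(scan: ScanConfig) -> WavenumberGrid:
    # One scan grid per acquisition; the study uses the default instrument
    # grid throughout.  Kept as a function so a custom grid can be threaded
    # through later without touching simulate_scan's call sites.
    return default_full_grid()


def generate_study(seed: int,
                   scan: ScanConfig | None = None,
                   params: MixingParams | None = None,
                   library: ReferenceLibrary | None = None,
                   chemicals: Sequence[str] = CHEMICALS,
                   layer_counts: Iterable[int] = LAYER_COUNTS,
                   ) -> tuple[list[SORSDataset], ReferenceLibrary]:
    """Generate the full study: one scan per (chemical, layer count).

    With the default 3 chemicals x 8 layer counts this yields 24 datasets.
    Each dataset gets a distinct sub-seed derived deterministically from
    ``seed`` via :func:`dataset_seed`, so noise realizations are independent
    across datasets but bit-reproducible across runs.
    """
    scan = scan or ScanConfig()
    params = params or MixingParams()
    library = library or default_library()
    datasets = []
    for chemical in chemicals:
        for n_layers in layer_counts:
            sub_seed = dataset_seed(seed, chemical, n_layers)
            sample = SampleConfig(chemical=chemical, n_layers=n_layers)
            scan_i = dataclasses.replace(scan, seed=sub_seed)
            ds = simulate_scan(sample, scan_i, library, params)
            ds.metadata["master_seed"] = seed
            datasets.append(ds)
    logger.info("generated %d datasets (master seed %d)", len(datasets), seed)
    return datasets, library
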