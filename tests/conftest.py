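"""Shared fixtures: grids, library, and the two full synthetic studies.

The study fixtures are session-scoped because generating, preprocessing
and unmixing 24 datasets is the expensive part of the suite; every test
that needs study-level results shares one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import sorsmix as sx

STUDY_SEED = 1  # master seed used by all study-level fixtures


@pytest.fixture(scope="session")
def full_grid() -> sx.WavenumberGrid:
    return sx.default_full_grid()


@pytest.fixture(scope="session")
def analysis_grid() -> sx.WavenumberGrid:
    return sx.default_analysis_grid()


@pytest.fixture(scope="session")
def library() -> sx.ReferenceLibrary:
    return sx.default_library()


@dataclass
class SampleRun:
    """One sample pushed through the full analysis chain."""

    dataset: sx.SORSDataset
    preprocessed: sx.SORSDataset
    result: sx.SMAResult
    report: sx.IdentificationReport

    @property
    def chemical(self) -> str:
        return self.dataset.sample_config.chemical

    @property
    def n_layers(self) -> int:
        return self.dataset.sample_config.n_layers

    def best_cosines(self, library: sx.ReferenceLibrary) -> dict[str, float]:
        refs = library.spectra(self.preprocessed.grid)
        out = {}
        for name in ("capsule", self.chemical):
            ref = refs[name]
            out[name] = max(
                float(row @ ref / (np.linalg.norm(row) * np.linalg.norm(ref)
                                   + 1e-300))
                for row in self.result.S)
        return out


def _run_study(seed: int, params: sx.MixingParams | None,
               library: sx.ReferenceLibrary) -> list[SampleRun]:
    datasets, _ = sx.generate_study(seed, params=params, library=library)
    runs = []
    for ds in datasets:
        pre = sx.preprocess(ds)
        result = sx.unmix_dataset(pre, k=2)
        report = sx.identify_components(result, library)
        runs.append(SampleRun(ds, pre, result, report))
    return runs


@pytest.fixture(scope="session")
def noisy_study(library) -> list[SampleRun]:
    """All 24 samples, default noise, full analysis chain."""
    return _run_study(STUDY_SEED, None, library)


@pytest.fixture(scope="session")
def noisefree_study(library) -> list[SampleRun]:
    """All 24 samples with noise disabled (deterministic forward model)."""
    return _run_study(STUDY_SEED, sx.MixingParams().noiseless(), library)


@pytest.fixture(scope="session")
def urea3_noisefree(library) -> tuple[sx.SORSDataset, sx.SORSDataset]:
    """The calibration sample (urea under 3 layers), raw and preprocessed."""
    ds = sx.simulate_scan(sx.SampleConfig("urea", 3), sx.ScanConfig(seed=0),
                          library, sx.MixingParams().noiseless())
    return ds, sx.preprocess(ds)
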