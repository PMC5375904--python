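"""CSV/JSON readers and writers for spectral matrices and reports.

Dataset CSV layout: header row is ``offset_mm`` followed by the wavenumber
of every channel (full float precision); each data row is the offset in mm
followed by the intensities.  Values are written with ``%.17g`` so a
round-trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SpectralParseError
from .synthetic_data import (MixingParams, SORSDataset, SampleConfig,
                             ScanConfig, WavenumberGrid)

_FMT = "%.17g"


def _format_row(values) -> str:
    return ",".join(_FMT % v for v in values)


def write_dataset(dataset: SORSDataset, csv_path, json_path=None) -> None:
    """Write a dataset to CSV, optionally with a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    lines = ["offset_mm," + _format_row(dataset.grid.values)]
    for offset, row in zip(dataset.offsets, dataset.intensities):
        lines.append((_FMT % offset) + "," + _format_row(row))
    csv_path.write_text("\n".join(lines) + "\n")
    if json_path is not None:
        meta = dict(dataset.metadata)
        if dataset.sample_config is not None:
            meta["sample_config"] = dataclasses.asdict(dataset.sample_config)
        Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_dataset(csv_path, json_path=None) -> SORSDataset:
    """Read a dataset CSV (and optional JSON sidecar) back into memory.

    Malformed headers (non-numeric or non-monotone wavenumbers) raise
    :class:`SpectralParseError` naming the offending column.
    """
    csv_path = Path(csv_path)
    try:
        frame = pd.read_csv(csv_path, header=None, skiprows=1,
                            float_precision="round_trip")
        header = csv_path.open().readline().rstrip("\n").split(",")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectralParseError(f"cannot read {csv_path}: {exc}") from exc
    if header[0] != "offset_mm":
        raise SpectralParseError(
            f"{csv_path}: first header cell must be 'offset_mm', "
            f"got {header[0]!r}")
    try:
        wavenumbers = np.array([float(h) for h in header[1:]])
    except ValueError:
        bad = next(i for i, h in enumerate(header[1:], start=2)
                   if not _is_float(h))
        raise SpectralParseError(
            f"{csv_path}: non-numeric wavenumber in header column {bad}")
    if np.any(np.diff(wavenumbers) <= 0):
        bad = int(np.nonzero(np.diff(wavenumbers) <= 0)[0][0]) + 2
        raise SpectralParseError(
            f"{csv_path}: non-monotone wavenumber grid at header column {bad}")
    values = frame.to_numpy(dtype=float)
    if values.shape[1] != wavenumbers.size + 1:
        raise SpectralParseError(
            f"{csv_path}: row width {values.shape[1]} does not match "
            f"header width {wavenumbers.size + 1}")
    metadata, sample = {}, None
    if json_path is not None and Path(json_path).exists():
        metadata = json.loads(Path(json_path).read_text())
        if "sample_config" in metadata:
            sample = SampleConfig(**metadata.pop("sample_config"))
    return SORSDataset(grid=WavenumberGrid(wavenumbers), offsets=values[:, 0],
                       intensities=values[:, 1:], sample_config=sample,
                       metadata=metadata)


def _is_float(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def write_matrix_csv(path, grid_or_header, matrix, first_column=None,
                     first_name: str | None = None) -> None:
    """Write a numeric matrix with a wavenumber (or named) header row."""
    path = Path(path)
    if isinstance(grid_or_header, WavenumberGrid):
        header_text = _format_row(grid_or_header.values)
    else:
        header_text = ",".join(
            h if isinstance(h, str) else _FMT % h for h in grid_or_header)
    matrix = np.asarray(matrix, dtype=float)
    if first_column is not None:
        lines = [f"{first_name}," + header_text]
        for lead, row in zip(first_column, matrix):
            lines.append((_FMT % lead) + "," + _format_row(row))
    else:
        lines = [header_text]
        for row in matrix:
            lines.append(_format_row(row))
    path.write_text("\n".join(lines) + "\n")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def scan_config_from_dict(d: dict) -> ScanConfig:
    return ScanConfig(**d)


def mixing_params_from_dict(d: dict) -> MixingParams:
    return MixingParams(**d)
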