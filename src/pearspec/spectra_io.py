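"""Read/write spectra tables and median-filter smoothing.

The on-disk layout keeps the spectra file a pure numeric matrix: a wide CSV
whose first column is ``wavelength_nm`` and remaining columns are one sample
each, plus a companion labels CSV with ``sample_id,direction,spad``. Field
spectroradiometer exports are assumed already averaged per leaf; smoothing
(a running median, the standard treatment for dust-spike noise) is applied
to the stored spectrum.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import SpectraSet, check_uniform_grid

__all__ = ["SmoothingParams", "read_spectra", "write_spectra", "smooth", "labels_path_for"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"  # >= 10 significant digits survive a round-trip


@dataclass(frozen=True)
class SmoothingParams:
    """Running-median window width (in bands) and edge policy.

    ``reflect`` mirrors the series at the boundary (edge value included);
    ``truncate`` shrinks the window to the available samples.
    """

    window_bands: int = 5
    edge_mode: str = "reflect"

    def __post_init__(self):
        if self.window_bands < 1 or self.window_bands % 2 == 0:
            raise ValueError(f"window_bands must be an odd positive integer, got {self.window_bands}")
        if self.edge_mode not in ("reflect", "truncate"):
            raise ValueError(f"edge_mode must be 'reflect' or 'truncate', got {self.edge_mode!r}")


def labels_path_for(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_labels.csv")


def write_spectra(dataset: SpectraSet, path: str | Path,
                  labels_path: str | Path | None = None) -> Path:
    """Write the wide spectra CSV and its companion labels CSV.

    Returns the spectra path; the labels file lands next to it as
    ``<stem>_labels.csv`` unless ``labels_path`` overrides that.
    """
    if dataset.n_samples == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    wide = pd.DataFrame(
        dataset.reflectance.T, columns=dataset.sample_ids,
        index=pd.Index(dataset.wavelengths_nm, name="wavelength_nm"),
    )
    wide.to_csv(path, float_format=_FLOAT_FMT)
    labels = pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "direction": dataset.directions,
        "spad": np.full(dataset.n_samples, np.nan) if dataset.spad is None else dataset.spad,
    })
    labels.to_csv(labels_path or labels_path_for(path), index=False, float_format=_FLOAT_FMT)
    return path


def _read_header_ids(path: Path) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm', got {header[:1]}")
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample_id column(s): {dupes}")
    return ids


def read_spectra(path: str | Path, spad_path: str | Path | None = None) -> SpectraSet:
    """Load a wide spectra CSV; optionally join SPAD labels by sample_id.

    Rejects non-uniform wavelength grids (naming the offending rows),
    non-numeric cells (with their coordinates), duplicate sample ids, and —
    when ``spad_path`` is given — sample ids missing from the labels file.
    """
    path = Path(path)
    sample_ids = _read_header_ids(path)
    df = pd.read_csv(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        spots = [f"(row {int(i) + 2}, column {df.columns[int(j)]!r})" for i, j in zip(r[:5], c[:5])]
        raise ValueError(f"{path}: non-numeric or missing cell(s) at {', '.join(spots)}")
    wl = numeric["wavelength_nm"].to_numpy()
    check_uniform_grid(wl, name=f"{path}: wavelength grid")
    reflectance = numeric[sample_ids].to_numpy().T

    directions = ["unknown"] * len(sample_ids)
    spad = None
    if spad_path is not None:
        labels = pd.read_csv(spad_path)
        required = {"sample_id", "spad"}
        if not required <= set(labels.columns):
            raise ValueError(f"{spad_path}: labels file needs columns {sorted(required)}")
        labels = labels.set_index(labels["sample_id"].astype(str))
        missing = [s for s in sample_ids if s not in labels.index]
        if missing:
            raise ValueError(f"{spad_path}: no SPAD label for sample_id(s): {missing}")
        spad = labels.loc[sample_ids, "spad"].to_numpy(dtype=float)
        if "direction" in labels.columns:
            directions = [str(d) for d in labels.loc[sample_ids, "direction"]]

    return SpectraSet(
        wavelengths_nm=wl, reflectance=reflectance,
        sample_ids=sample_ids, directions=directions, spad=spad,
    )


def _truncate_median(row: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(row)
    if row.size > window:
        from numpy.lib.stride_tricks import sliding_window_view

        out[half:row.size - half] = np.median(sliding_window_view(row, window), axis=-1)
    for i in range(min(half, row.size)):
        out[i] = np.median(row[: i + half + 1])
        out[row.size - 1 - i] = np.median(row[row.size - 1 - i - half:])
    return out


def smooth(dataset: SpectraSet, params: SmoothingParams = SmoothingParams()) -> SpectraSet:
    """Per-sample running median over ``window_bands``; labels untouched.

    A median never leaves the input's [min, max] envelope and passes
    constant spectra through unchanged.
    """
    if params.window_bands > dataset.n_bands:
        raise ValueError(
            f"window of {params.window_bands} bands exceeds grid length {dataset.n_bands}"
        )
    if params.window_bands == 1:
        return dataset.with_reflectance(dataset.reflectance.copy())
    if params.edge_mode == "reflect":
        smoothed = ndimage.median_filter(
            dataset.reflectance, size=(1, params.window_bands), mode="reflect"
        )
    else:
        smoothed = np.vstack([
            _truncate_median(row, params.window_bands) for row in dataset.reflectance
        ])
    return dataset.with_reflectance(smoothed)
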