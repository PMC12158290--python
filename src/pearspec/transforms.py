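"""Spectral transforms: inverse, log10, first derivative, and Haar DWT.

Twelve representations of a reflectance spectrum are produced here. The six
"mathematical" ones — R, 1/R, log10(R), and their central-difference first
derivatives — keep the native wavelength axis (derivatives drop the two
endpoints). The discrete wavelet transform splits the spectrum into
low-frequency approximation series L1-L3 and high-frequency detail series
H1-H3 using the orthonormal Haar basis: at each level neighbouring values
are combined as (x[2i]+x[2i+1])/sqrt(2) and (x[2i]-x[2i+1])/sqrt(2), so the
spectral resolution halves per level and Parseval's identity holds exactly.
Each wavelet coefficient is assigned a nominal wavelength: the mean of the
original grid positions in its dyadic support (boundary pads excluded),
which keeps "sensitive band (nm)" reporting meaningful at every scale.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    Spectrum,
    TransformedMatrix,
    TransformedSeries,
    WaveletDecomposition,
)

__all__ = [
    "CLIP_FLOOR_DEFAULT",
    "inverse_reflectance",
    "log_reflectance",
    "first_derivative",
    "haar_dwt",
    "apply_transform",
    "MATH_TAGS",
    "DWT_TAGS",
]

log = logging.getLogger(__name__)

CLIP_FLOOR_DEFAULT = 1e-4

MATH_TAGS = ("R", "invR", "logR", "dR", "d_invR", "d_logR")
DWT_TAGS = ("L1", "L2", "L3", "H1", "H2", "H3")

_DERIV_TAG = {"R": "dR", "invR": "d_invR", "logR": "d_logR"}


def _clipped(values: np.ndarray, clip_floor: float, what: str) -> np.ndarray:
    clipped = np.maximum(values, clip_floor)
    n_clip = int(np.sum(values < clip_floor))
    if n_clip:
        log.warning("%s: clipped %d band value(s) below %g", what, n_clip, clip_floor)
    return clipped


def inverse_reflectance(s: Spectrum, clip_floor: float = CLIP_FLOOR_DEFAULT) -> TransformedSeries:
    """1/R, with reflectance floored at ``clip_floor`` so zeros stay finite."""
    r = _clipped(s.reflectance, clip_floor, f"invR[{s.sample_id}]")
    return TransformedSeries("invR", s.wavelengths_nm, 1.0 / r, s.sample_id)


def log_reflectance(s: Spectrum, clip_floor: float = CLIP_FLOOR_DEFAULT) -> TransformedSeries:
    """log10(R), with the same floor; base 10 is the spectroscopy convention."""
    r = _clipped(s.reflectance, clip_floor, f"logR[{s.sample_id}]")
    return TransformedSeries("logR", s.wavelengths_nm, np.log10(r), s.sample_id)


def first_derivative(t: TransformedSeries) -> TransformedSeries:
    """Central-difference first derivative; endpoints dropped, axis shortened by 2."""
    if t.values.size < 3:
        raise ValueError("first derivative needs a series of length >= 3")
    axis, values = _central_diff(t.axis_nm, t.values)
    tag = _DERIV_TAG.get(t.transform_tag, f"d_{t.transform_tag}")
    return TransformedSeries(tag, axis, values, t.sample_id)


def _central_diff(axis_nm: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    step = axis_nm[1] - axis_nm[0]
    dv = (values[..., 2:] - values[..., :-2]) / (2.0 * step)
    return axis_nm[1:-1], dv


def _haar_step(values: np.ndarray, wsum: np.ndarray, wcount: np.ndarray):
    """One Haar analysis level along the last axis.

    Odd lengths are padded by duplicating the final value (half-sample
    symmetric reflection — the convention of pywt's ``symmetric`` mode for a
    length-2 filter). Pad positions carry no wavelength support.
    """
    n = values.shape[-1]
    padded = n % 2
    if padded:
        values = np.concatenate([values, values[..., -1:]], axis=-1)
        wsum = np.concatenate([wsum, [0.0]])
        wcount = np.concatenate([wcount, [0]])
    a = (values[..., 0::2] + values[..., 1::2]) / np.sqrt(2.0)
    d = (values[..., 0::2] - values[..., 1::2]) / np.sqrt(2.0)
    new_wsum = wsum[0::2] + wsum[1::2]
    new_wcount = wcount[0::2] + wcount[1::2]
    return a, d, new_wsum, new_wcount, padded


def haar_dwt(values, axis_nm=None, levels: int = 3,
             sample_ids: list[str] | None = None) -> WaveletDecomposition:
    """Multi-level Haar decomposition of one series or a sample-by-band matrix.

    Parameters
    ----------
    values
        1-D series or 2-D array (samples on rows); decomposed along bands.
    axis_nm
        Wavelength per input value; defaults to the sample index.
    levels
        Decomposition depth (default 3); input must span ``2**levels`` values.

    Returns a :class:`WaveletDecomposition` whose level-``j`` approximation
    (tag ``Lj``) and detail (tag ``Hj``) hold ``ceil(len/2**j)`` coefficients
    located at the support-midpoint wavelengths.
    """
    vals = np.asarray(values, dtype=float)
    matrix_input = vals.ndim == 2
    if not matrix_input:
        vals = vals[None, :]
    m = vals.shape[-1]
    if axis_nm is None:
        axis_nm = np.arange(m, dtype=float)
    axis_nm = np.asarray(axis_nm, dtype=float)
    if axis_nm.size != m:
        raise ValueError("axis_nm length does not match the value series")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if m < 2 ** levels:
        raise ValueError(
            f"series of length {m} is too short for a {levels}-level decomposition "
            f"(needs >= {2 ** levels})"
        )

    def wrap(tag: str, axis: np.ndarray, data: np.ndarray):
        if matrix_input:
            return TransformedMatrix(tag, axis, data, sample_ids)
        return TransformedSeries(tag, axis, data[0],
                                 sample_ids[0] if sample_ids else None)

    approximations: dict[int, object] = {}
    details: dict[int, object] = {}
    pad_lengths: list[int] = []
    cur, wsum, wcount = vals, axis_nm.copy(), np.ones(m, dtype=int)
    for j in range(1, levels + 1):
        cur, det, wsum, wcount, padded = _haar_step(cur, wsum, wcount)
        pad_lengths.append(padded)
        coef_axis = wsum / wcount
        approximations[j] = wrap(f"L{j}", coef_axis, cur)
        details[j] = wrap(f"H{j}", coef_axis, det)
    return WaveletDecomposition(approximations, details, tuple(pad_lengths))


def apply_transform(tag: str, wavelengths_nm: np.ndarray, reflectance: np.ndarray,
                    clip_floor: float = CLIP_FLOOR_DEFAULT,
                    sample_ids: list[str] | None = None) -> TransformedMatrix:
    """Build the representation ``tag`` for a whole reflectance matrix.

    ``reflectance`` has samples on rows; the returned matrix carries the
    representation's own wavelength axis (shortened for derivatives, dyadic
    support midpoints for wavelet series).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    R = np.asarray(reflectance, dtype=float)
    if R.ndim != 2 or R.shape[1] != wl.size:
        raise ValueError("reflectance must be (n_samples, n_bands) matching the grid")

    if tag in DWT_TAGS:
        level = int(tag[1])
        dec = haar_dwt(R, wl, levels=3, sample_ids=sample_ids)
        series = dec.approximations[level] if tag[0] == "L" else dec.details[level]
        return series

    if tag in ("R", "dR"):
        base, base_tag = R, "R"
    elif tag in ("invR", "d_invR"):
        base = 1.0 / _clipped(R, clip_floor, "invR")
        base_tag = "invR"
    elif tag in ("logR", "d_logR"):
        base = np.log10(_clipped(R, clip_floor, "logR"))
        base_tag = "logR"
    else:
        raise ValueError(f"unknown transform tag {tag!r}")

    if tag in ("dR", "d_invR", "d_logR"):
        if wl.size < 3:
            raise ValueError("first derivative needs a grid of length >= 3")
        axis, values = _central_diff(wl, base)
        return TransformedMatrix(_DERIV_TAG[base_tag], axis, values, sample_ids)
    return TransformedMatrix(base_tag, wl, base, sample_ids)
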