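"""Core containers for the SPAD-from-reflectance pipeline.

The central object is :class:`SpectraSet`: a stack of leaf reflectance
spectra on one shared, uniformly spaced wavelength grid, order-aligned with
per-sample SPAD readings (a dimensionless relative-chlorophyll index from a
transmittance leaf meter). Transformed representations (derivatives, log,
wavelet approximation/detail series) live in :class:`TransformedSeries` /
:class:`TransformedMatrix`, which carry a nominal wavelength axis so that
"sensitive band (nm)" reporting stays well defined at every wavelet scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

DIRECTIONS = ("east", "south", "west", "north")

#: The twelve representations the pipeline compares: raw reflectance R, its
#: inverse and base-10 log, their first derivatives, and the three-level Haar
#: approximation (L) and detail (H) series.
TRANSFORM_TAGS = (
    "R", "invR", "logR", "dR", "d_invR", "d_logR",
    "L1", "L2", "L3", "H1", "H2", "H3",
)

_GRID_RTOL = 1e-9


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def check_uniform_grid(wavelengths_nm: np.ndarray, name: str = "wavelength grid") -> float:
    """Validate a strictly increasing, uniformly spaced axis; return the step."""
    if wavelengths_nm.size < 2:
        raise ValueError(f"{name} needs at least 2 points")
    d = np.diff(wavelengths_nm)
    if np.any(d <= 0):
        bad = np.nonzero(d <= 0)[0]
        raise ValueError(f"{name} not strictly increasing at rows {bad.tolist()}")
    step = float(d[0])
    off = np.nonzero(np.abs(d - step) > _GRID_RTOL * max(abs(step), 1.0))[0]
    if off.size:
        raise ValueError(f"{name} not uniformly spaced at rows {(off + 1).tolist()}")
    return step


@dataclass(frozen=True)
class Spectrum:
    """A single sample's reflectance on a wavelength grid, plus metadata."""

    sample_id: str
    direction: str
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths_nm, "wavelengths_nm", 1)
        r = _as_float_array(self.reflectance, "reflectance", 1)
        if wl.size != r.size:
            raise ValueError("wavelengths_nm and reflectance lengths differ")
        check_uniform_grid(wl)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", r)


@dataclass
class SpectraSet:
    """Aligned collection of spectra with SPAD labels.

    Parameters
    ----------
    wavelengths_nm
        Shared grid, strictly increasing, uniform spacing.
    reflectance
        Array of shape ``(n_samples, n_bands)``, values in ``[0, 1]``.
    spad
        One SPAD value per spectrum, order-aligned, or ``None`` if unlabeled.
    truth
        Optional record of generating parameters (planted sensitive band
        centers, SPAD-to-depth coefficients, latent SPAD) for recovery tests.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str]
    directions: list[str]
    spad: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.wavelengths_nm = _as_float_array(self.wavelengths_nm, "wavelengths_nm", 1)
        self.reflectance = _as_float_array(self.reflectance, "reflectance", 2)
        check_uniform_grid(self.wavelengths_nm)
        n, m = self.reflectance.shape
        if m != self.wavelengths_nm.size:
            raise ValueError(
                f"reflectance has {m} bands but the grid has {self.wavelengths_nm.size}"
            )
        if self.reflectance.size:
            if np.min(self.reflectance) < -1e-9 or np.max(self.reflectance) > 1 + 1e-9:
                raise ValueError("reflectance values outside [0, 1]")
            self.reflectance = np.clip(self.reflectance, 0.0, 1.0)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.directions = [str(d) for d in self.directions]
        if len(self.sample_ids) != n or len(self.directions) != n:
            raise ValueError("sample_ids/directions length does not match sample count")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        if self.spad is not None:
            self.spad = _as_float_array(self.spad, "spad", 1)
            if self.spad.size != n:
                raise ValueError("one SPAD value per spectrum is required")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def spectra(self) -> Iterator[Spectrum]:
        for i in range(self.n_samples):
            yield self.spectrum(i)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            sample_id=self.sample_ids[i],
            direction=self.directions[i],
            wavelengths_nm=self.wavelengths_nm,
            reflectance=self.reflectance[i],
        )

    def window(self, lo_nm: float, hi_nm: float) -> "SpectraSet":
        """Restrict to the analysis wavelength window ``[lo_nm, hi_nm]``."""
        keep = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if keep.sum() < 2:
            raise ValueError(f"window [{lo_nm}, {hi_nm}] nm retains <2 bands")
        return SpectraSet(
            wavelengths_nm=self.wavelengths_nm[keep],
            reflectance=self.reflectance[:, keep],
            sample_ids=list(self.sample_ids),
            directions=list(self.directions),
            spad=None if self.spad is None else self.spad.copy(),
            truth=self.truth,
        )

    def with_reflectance(self, reflectance: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            wavelengths_nm=self.wavelengths_nm.copy(),
            reflectance=reflectance,
            sample_ids=list(self.sample_ids),
            directions=list(self.directions),
            spad=None if self.spad is None else self.spad.copy(),
            truth=self.truth,
        )


def _check_axis(axis_nm, values, tag):
    axis = _as_float_array(axis_nm, "axis_nm", 1)
    vals = np.asarray(values, dtype=float)
    if vals.shape[-1] != axis.size:
        raise ValueError(f"{tag}: axis length {axis.size} != value length {vals.shape[-1]}")
    if np.any(np.diff(axis) <= 0):
        raise ValueError(f"{tag}: axis_nm must be strictly increasing")
    return axis, vals


@dataclass
class TransformedSeries:
    """One sample's transformed value series with a nominal wavelength axis."""

    transform_tag: str
    axis_nm: np.ndarray
    values: np.ndarray
    sample_id: str | None = None

    def __post_init__(self):
        self.axis_nm, self.values = _check_axis(self.axis_nm, self.values, self.transform_tag)
        if self.values.ndim != 1:
            raise ValueError("TransformedSeries values must be 1-dimensional")


@dataclass
class TransformedMatrix:
    """A whole dataset's transformed values, samples on rows."""

    transform_tag: str
    axis_nm: np.ndarray
    values: np.ndarray  # (n_samples, n_points)
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.axis_nm, self.values = _check_axis(self.axis_nm, self.values, self.transform_tag)
        if self.values.ndim != 2:
            raise ValueError("TransformedMatrix values must be 2-dimensional")

    def series(self, i: int) -> TransformedSeries:
        sid = None if self.sample_ids is None else self.sample_ids[i]
        return TransformedSeries(self.transform_tag, self.axis_nm, self.values[i], sid)


@dataclass
class WaveletDecomposition:
    """Three-level Haar decomposition: L1-L3 approximations, H1-H3 details.

    ``pad_lengths[j-1]`` counts boundary values appended before level ``j``;
    ``pad_length`` is their total. Each coefficient's ``axis_nm`` entry is the
    mean wavelength of the original samples in its support (pads excluded).
    """

    approximations: Mapping[int, TransformedMatrix | TransformedSeries]
    details: Mapping[int, TransformedMatrix | TransformedSeries]
    pad_lengths: tuple[int, ...]

    def __post_init__(self):
        levels = sorted(self.approximations)
        if levels != sorted(self.details):
            raise ValueError("approximation and detail levels differ")
        if levels and levels != list(range(1, len(levels) + 1)):
            raise ValueError(f"levels must be 1..{len(levels)}, got {levels}")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.approximations))

    @property
    def pad_length(self) -> int:
        return int(sum(self.pad_lengths))


@dataclass
class CorrelationProfile:
    """Per-band Pearson correlation of a representation against SPAD."""

    transform_tag: str
    axis_nm: np.ndarray
    r: np.ndarray
    n: int
    zero_variance: np.ndarray | None = None  # bands flagged r=0 for lack of variance

    def __post_init__(self):
        self.axis_nm, self.r = _check_axis(self.axis_nm, self.r, self.transform_tag)
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations outside [-1, 1]")
        self.r = np.clip(self.r, -1.0, 1.0)
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.r.size, dtype=bool)
        else:
            self.zero_variance = np.asarray(self.zero_variance, dtype=bool)

    @property
    def r2(self) -> np.ndarray:
        return self.r ** 2


@dataclass
class SensitiveBands:
    """Wavelengths selected as regression inputs, strongest first."""

    transform_tag: str
    bands_nm: np.ndarray
    scores: np.ndarray  # |r| at each band, non-increasing in selection order
    min_separation_nm: float
    exhausted: bool = False  # fewer bands found than requested

    def __post_init__(self):
        self.bands_nm = _as_float_array(self.bands_nm, "bands_nm", 1)
        self.scores = _as_float_array(self.scores, "scores", 1)
        if self.bands_nm.size != self.scores.size:
            raise ValueError("bands_nm and scores lengths differ")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing in selection order")
        b = np.sort(self.bands_nm)
        if b.size > 1 and np.min(np.diff(b)) < self.min_separation_nm - 1e-9:
            raise ValueError("selected bands violate the minimum separation")


@dataclass
class SplitSpec:
    """Random modeling/validation split; ``assignment`` holds group labels."""

    n_train: int
    n_valid: int
    seed: int = 20250605
    assignment: np.ndarray | None = None  # per-sample "train"/"valid"

    def __post_init__(self):
        if self.n_train < 3:
            raise ValueError("n_train must be at least 3")
        if self.n_valid < 1:
            raise ValueError("a non-empty validation group is required")
        if self.assignment is not None:
            self.assignment = np.asarray(self.assignment, dtype=object)
            labels = set(self.assignment.tolist())
            if not labels <= {"train", "valid"}:
                raise ValueError(f"unknown assignment labels: {labels - {'train', 'valid'}}")

    @property
    def train_mask(self) -> np.ndarray:
        if self.assignment is None:
            raise ValueError("split has not been assigned yet")
        return np.asarray([a == "train" for a in self.assignment], dtype=bool)


@dataclass
class FittedModel:
    """An affine SPAD predictor on selected band values.

    ``intercept``/``coefficients`` act on (optionally z-standardized)
    predictors and produce the (optionally z-standardized) response; the
    standardization constants are stored so prediction is always in SPAD
    units. ``raw_affine()`` folds them into original-unit coefficients.
    """

    transform_tag: str
    bands_nm: np.ndarray
    intercept: float
    coefficients: np.ndarray
    method: str  # "two_band_ols" | "pls"
    standardized: bool
    n_components: int | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0

    def __post_init__(self):
        self.bands_nm = _as_float_array(self.bands_nm, "bands_nm", 1)
        self.coefficients = _as_float_array(self.coefficients, "coefficients", 1)
        if self.coefficients.size != self.bands_nm.size:
            raise ValueError("one coefficient per band is required")
        k = self.bands_nm.size
        self.x_mean = np.zeros(k) if self.x_mean is None else np.asarray(self.x_mean, float)
        self.x_scale = np.ones(k) if self.x_scale is None else np.asarray(self.x_scale, float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.bands_nm.size:
            raise ValueError(f"predictor table must have {self.bands_nm.size} columns")
        z = (X - self.x_mean) / self.x_scale
        return self.y_mean + self.y_scale * (self.intercept + z @ self.coefficients)

    def raw_affine(self) -> tuple[float, np.ndarray]:
        """Intercept and coefficients acting directly on original-unit values."""
        coef = self.y_scale * self.coefficients / self.x_scale
        icpt = self.y_mean + self.y_scale * self.intercept - float(self.x_mean @ coef)
        return icpt, coef

    def equation(self) -> str:
        """Human-readable model string, e.g. ``y = 0.057 - 0.851*x_516 + 0.073*x_724``."""
        parts = [f"y = {self.intercept:.3f}"]
        for b, c in zip(self.bands_nm, self.coefficients):
            sign = "-" if c < 0 else "+"
            parts.append(f"{sign} {abs(c):.3f}*x_{b:g}")
        return " ".join(parts)

    def to_dict(self) -> dict:
        raw_icpt, raw_coef = self.raw_affine()
        return {
            "transform_tag": self.transform_tag,
            "bands_nm": self.bands_nm.tolist(),
            "method": self.method,
            "n_components": self.n_components,
            "standardized": bool(self.standardized),
            "intercept": float(self.intercept),
            "coefficients": self.coefficients.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": float(self.y_mean),
            "y_scale": float(self.y_scale),
            "raw_intercept": float(raw_icpt),
            "raw_coefficients": raw_coef.tolist(),
            "equation": self.equation(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedModel":
        return cls(
            transform_tag=d["transform_tag"],
            bands_nm=np.asarray(d["bands_nm"], float),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], float),
            method=d["method"],
            standardized=bool(d["standardized"]),
            n_components=d.get("n_components"),
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=np.asarray(d["x_scale"], float),
            y_mean=float(d["y_mean"]),
            y_scale=float(d["y_scale"]),
        )


@dataclass(frozen=True)
class EvaluationResult:
    """Coefficient of determination and RMSE on both splits, SPAD units."""

    r2_train: float
    rmse_train: float
    r2_valid: float
    rmse_valid: float
    n_train: int
    n_valid: int

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train, "rmse_train": self.rmse_train,
            "r2_valid": self.r2_valid, "rmse_valid": self.rmse_valid,
            "n_train": self.n_train, "n_valid": self.n_valid,
        }
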