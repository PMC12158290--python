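"""Synthetic pear-leaf reflectance spectra with SPAD-linked absorption.

The field campaign this pipeline targets is not publicly deposited, so every
downstream stage is exercised on generated data that reproduces the study's
statistical structure: 87 leaves sampled in four canopy directions
(22 east / 22 south / 22 west / 21 north); SPAD readings distributed
~N(45.8, 3.64^2) truncated to [32.6, 67.1] with a +/-1 SPAD meter error;
chlorophyll-dependent absorption wells in the blue (~450 nm) and red
(~670 nm); a logistic red-edge rise near 715 nm; a smooth low-order noise
continuum; and high-frequency "dust" noise that is independent per band —
the lever that makes wavelet detail (H) series unstable while approximation
(L) series stay usable.

The construction is additive::

    R(lam) = continuum(lam) - sum_b s_b * SPAD * G(lam; c_b, w_b)
             + smooth_noise(lam) + dust_noise(lam),   clipped to [0, 1]

with ``G`` a unit-height Gaussian and ``continuum`` a logistic step from the
visible level up to the NIR plateau across the red edge. Well depth is
linear in the latent SPAD, so band reflectance is strictly monotone in SPAD
when noise is off — the identifiability the recovery tests rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import chebyshev
from scipy.special import expit

from .datatypes import DIRECTIONS, SpectraSet

__all__ = ["SyntheticConfig", "generate_dataset", "DEFAULT_FEATURE_BANDS"]

#: (center nm, Gaussian sigma nm, well depth per SPAD unit, reflectance units)
DEFAULT_FEATURE_BANDS: tuple[tuple[float, float, float], ...] = (
    (450.0, 40.0, 0.0030),
    (670.0, 30.0, 0.0030),
)

_SMOOTH_NOISE_DEGREE = 4  # random Chebyshev polynomial order for the smooth component


def _default_direction_counts() -> dict[str, int]:
    return {"east": 22, "south": 22, "west": 22, "north": 21}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reproduce the study conditions."""

    n_samples: int = 87
    direction_counts: Mapping[str, int] = field(default_factory=_default_direction_counts)
    spad_mean: float = 45.8
    spad_sd: float = 3.64
    spad_min: float = 32.6
    spad_max: float = 67.1
    feature_bands: Sequence[tuple[float, float, float]] = DEFAULT_FEATURE_BANDS
    red_edge_center_nm: float = 715.0
    red_edge_width_nm: float = 15.0
    baseline_level: float = 0.45   # NIR plateau reflectance
    visible_level: float = 0.30    # visible continuum; wells bottom near 0.10 at SPAD max
    smooth_noise_sd: float = 0.004
    dust_noise_sd: float = 0.002
    spad_meter_error_sd: float = 1.0
    wl_start_nm: float = 350.0
    wl_stop_nm: float = 2500.0
    wl_step_nm: float = 1.0
    seed: int = 0

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_stop_nm - self.wl_start_nm) / self.wl_step_nm)) + 1
        return self.wl_start_nm + self.wl_step_nm * np.arange(n)

    def validate(self) -> None:
        counts = dict(self.direction_counts)
        if set(counts) != set(DIRECTIONS):
            raise ValueError(f"direction_counts must cover exactly {DIRECTIONS}")
        if any(c < 0 for c in counts.values()):
            raise ValueError("direction counts must be non-negative")
        if sum(counts.values()) != self.n_samples:
            raise ValueError(
                f"direction_counts sum to {sum(counts.values())}, expected n_samples={self.n_samples}"
            )
        if not (self.spad_min < self.spad_mean < self.spad_max):
            raise ValueError("require spad_min < spad_mean < spad_max")
        for name in ("spad_sd", "smooth_noise_sd", "dust_noise_sd", "spad_meter_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        wl = self.wavelengths()
        if wl.size < 8:
            raise ValueError(
                "wavelength grid shorter than 8 bands cannot support a "
                "three-level dyadic decomposition"
            )
        for center, width, _sens in self.feature_bands:
            if not (wl[0] <= center <= wl[-1]):
                raise ValueError(f"feature band center {center} nm lies outside the grid")
            if width <= 0:
                raise ValueError("feature band widths must be positive")
        if self.red_edge_width_nm <= 0 or self.wl_step_nm <= 0:
            raise ValueError("red_edge_width_nm and wl_step_nm must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["direction_counts"] = dict(self.direction_counts)
        d["feature_bands"] = [list(b) for b in self.feature_bands]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "feature_bands" in d:
            d["feature_bands"] = tuple(tuple(float(v) for v in b) for b in d["feature_bands"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from a JSON or YAML document mirroring the fields."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    out = np.empty(n)
    have = 0
    while have < n:  # rejection sampling; acceptance ~1 for the default bounds
        draw = rng.normal(mean, sd, size=2 * (n - have) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - have)
        out[have:have + take] = keep[:take]
        have += take
    return out


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Generate a :class:`SpectraSet` of synthetic leaf spectra.

    All randomness flows through one ``numpy`` generator seeded by
    ``config.seed``, so identical configs give bit-identical datasets. The
    recorded SPAD is the latent (spectrum-generating) SPAD plus meter error,
    clipped to ``[spad_min, spad_max]``; the latent values and the planted
    band/depth parameters are stored in ``SpectraSet.truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths()
    n = config.n_samples

    spad_true = _truncated_normal(
        rng, config.spad_mean, config.spad_sd, config.spad_min, config.spad_max, n
    )
    meter = rng.normal(0.0, config.spad_meter_error_sd, n) if config.spad_meter_error_sd > 0 else 0.0
    spad = np.clip(spad_true + meter, config.spad_min, config.spad_max)

    continuum = config.visible_level + (config.baseline_level - config.visible_level) * expit(
        (wl - config.red_edge_center_nm) / config.red_edge_width_nm
    )
    wells = np.zeros((n, wl.size))
    for center, width, sens in config.feature_bands:
        profile = np.exp(-0.5 * ((wl - center) / width) ** 2)
        wells += sens * spad_true[:, None] * profile[None, :]

    reflectance = continuum[None, :] - wells

    if config.smooth_noise_sd > 0:
        u = -1.0 + 2.0 * (wl - wl[0]) / (wl[-1] - wl[0])
        basis = chebyshev.chebvander(u, _SMOOTH_NOISE_DEGREE)  # (m, deg+1)
        coefs = rng.normal(0.0, config.smooth_noise_sd / np.sqrt(basis.shape[1]),
                           size=(n, basis.shape[1]))
        reflectance = reflectance + coefs @ basis.T
    if config.dust_noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, config.dust_noise_sd, size=(n, wl.size))

    reflectance = np.clip(reflectance, 0.0, 1.0)

    directions: list[str] = []
    for d in DIRECTIONS:
        directions.extend([d] * int(dict(config.direction_counts)[d]))
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    truth = {
        "band_centers_nm": [b[0] for b in config.feature_bands],
        "band_widths_nm": [b[1] for b in config.feature_bands],
        "depth_per_spad": [b[2] for b in config.feature_bands],
        "red_edge_center_nm": config.red_edge_center_nm,
        "spad_true": spad_true,
        "config": config.to_dict(),
    }
    return SpectraSet(
        wavelengths_nm=wl,
        reflectance=reflectance,
        sample_ids=sample_ids,
        directions=directions,
        spad=spad,
        truth=truth,
    )
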