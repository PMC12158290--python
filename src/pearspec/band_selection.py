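"""Correlation-based screening of wavelengths against SPAD.

Every band of a transformed representation is Pearson-correlated with the
SPAD readings; the regression then uses the few "sensitive bands" where
|r| peaks. Selection is greedy: repeatedly take the strongest remaining
band that keeps a minimum wavelength separation from those already chosen
(the separation guards against picking two near-duplicate neighbours from
the same absorption feature). Ties break toward the shorter wavelength.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .datatypes import CorrelationProfile, SensitiveBands, TransformedMatrix, TransformedSeries

__all__ = ["correlate", "select_bands"]

log = logging.getLogger(__name__)


def _as_matrix(series) -> TransformedMatrix:
    if isinstance(series, TransformedMatrix):
        return series
    if isinstance(series, Sequence) and series and isinstance(series[0], TransformedSeries):
        first = series[0]
        for s in series[1:]:
            if s.transform_tag != first.transform_tag or not np.array_equal(s.axis_nm, first.axis_nm):
                raise ValueError("all series must share one transform tag and axis")
        return TransformedMatrix(
            first.transform_tag, first.axis_nm,
            np.vstack([s.values for s in series]),
            [s.sample_id for s in series],
        )
    raise TypeError("expected a TransformedMatrix or a sequence of TransformedSeries")


def correlate(series, spad: np.ndarray) -> CorrelationProfile:
    """Pearson r of each band's transformed value against SPAD.

    Bands whose values do not vary across samples get ``r = 0`` and are
    flagged in ``zero_variance`` (and logged) rather than propagating NaNs.
    """
    matrix = _as_matrix(series)
    y = np.asarray(spad, dtype=float)
    X = matrix.values
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError(
            f"sample count mismatch: {X.shape[0]} spectra vs {y.size} SPAD values"
        )
    n = y.size
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc ** 2, axis=0))
    sy = np.sqrt(np.sum(yc ** 2))
    # relative test: a literally constant column still carries rounding noise
    zero_var = sx <= 1e-12 * np.sqrt(n) * np.maximum(np.abs(X).max(axis=0), 1e-30)
    if sy <= 1e-12 * np.sqrt(n) * max(np.abs(y).max(), 1e-30):
        log.warning("%s: SPAD has zero variance; all correlations set to 0", matrix.transform_tag)
        r = np.zeros(X.shape[1])
        zero_var = np.ones(X.shape[1], dtype=bool)
    else:
        r = np.zeros(X.shape[1])
        ok = ~zero_var
        r[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
        if zero_var.any():
            log.info(
                "%s: %d zero-variance band(s) flagged with r=0",
                matrix.transform_tag, int(zero_var.sum()),
            )
    r = np.clip(r, -1.0, 1.0)
    return CorrelationProfile(matrix.transform_tag, matrix.axis_nm, r, n, zero_var)


def select_bands(profile: CorrelationProfile, k: int = 2,
                 min_separation_nm: float = 50.0) -> SensitiveBands:
    """Greedy max-|r| band selection under a minimum-separation constraint.

    Equivalent to the lexicographic optimum over separation-feasible band
    subsets: the first pick is the global argmax of |r| (shorter wavelength
    on ties), each later pick the argmax among bands far enough from all
    earlier picks. If fewer than ``k`` bands are feasible the result is
    flagged ``exhausted`` instead of failing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    score = np.abs(profile.r)
    if not np.any(score > 0):
        raise ValueError(f"{profile.transform_tag}: correlation profile is degenerate (all r = 0)")
    # stable order: descending |r|, ascending wavelength on ties
    order = np.lexsort((profile.axis_nm, -score))
    chosen_idx: list[int] = []
    for idx in order:
        if len(chosen_idx) == k:
            break
        wl = profile.axis_nm[idx]
        if all(abs(wl - profile.axis_nm[j]) >= min_separation_nm for j in chosen_idx):
            chosen_idx.append(int(idx))
    exhausted = len(chosen_idx) < k
    if exhausted:
        log.warning(
            "%s: only %d of %d requested bands satisfy separation >= %g nm",
            profile.transform_tag, len(chosen_idx), k, min_separation_nm,
        )
    return SensitiveBands(
        transform_tag=profile.transform_tag,
        bands_nm=profile.axis_nm[chosen_idx],
        scores=score[chosen_idx],
        min_separation_nm=min_separation_nm,
        exhausted=exhausted,
    )
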