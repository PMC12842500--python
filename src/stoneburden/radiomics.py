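"""Texture and first-order features of stone VOIs, on the original grid and
on 3D wavelet sub-bands.

The feature families follow the community-standard (IBSI-style) definitions:

* first order — Energy ``sum x^2``, Total Energy (voxel volume times
  Energy), Minimum / Mean / Maximum.
* GLDM (gray-level dependence matrix) — for each voxel, its *dependence* is
  1 + the number of in-VOI Chebyshev-1 neighbors whose discretized level
  differs by at most ``alpha``; ``P(i, j)`` counts voxels of level *i* and
  dependence *j*.  Dependence Variance and Small Dependence Emphasis are
  moments of the normalized matrix.
* NGTDM (neighborhood gray-tone difference matrix) — per level *i*, the sum
  ``s_i`` of absolute differences between each voxel's level and the mean
  level of its valid neighbors; Complexity combines ``s_i`` across level
  pairs.

Gray levels come from fixed-bin-width, minimum-shifted discretization
(default 25 HU), which makes every texture feature invariant to a constant
HU offset.  The wavelet transform is a single-level undecimated separable
Haar bank (orthonormal taps from PyWavelets), yielding eight same-shape
sub-bands labelled by the per-axis filter letters in (x, y, z) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import pywt

DEFAULT_BIN_WIDTH = 25.0
DEFAULT_ALPHA = 0.0

SUBBAND_NAMES = ["".join(b) for b in product("LH", repeat=3)]  # LLL ... HHH

_NEIGHBOR_OFFSETS = [off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]


# ---------------------------------------------------------------------------
# discretization

@dataclass
class DiscretizedVOI:
    """Integer gray levels over a VOI's bounding box, with an in-VOI mask."""

    levels: np.ndarray   # int grid; meaningful only where mask is True
    mask: np.ndarray     # bool grid, same shape
    bin_width: float

    @property
    def n_levels(self) -> int:
        return int(self.levels[self.mask].max())

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def discretize(values: np.ndarray, mask: np.ndarray | None = None,
               bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedVOI:
    """Fixed-bin-width, minimum-shifted gray-level discretization.

    ``level = floor((x - min) / bin_width) + 1`` over in-mask voxels, so the
    lowest occupied level is always 1.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask and value grids must share a shape")
    if not mask.any():
        raise ValueError("cannot discretize an empty VOI")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    mn = values[mask].min()
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[mask] = np.floor((values[mask] - mn) / bin_width).astype(np.int64) + 1
    return DiscretizedVOI(levels=levels, mask=mask, bin_width=float(bin_width))


# ---------------------------------------------------------------------------
# wavelet sub-bands

def _filter_axis(arr: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Undecimated correlation with periodic boundary:
    ``y[i] = sum_k taps[k] * x[(i + k) mod n]`` along `axis`."""
    out = np.zeros_like(arr, dtype=float)
    for k, t in enumerate(taps):
        out += t * np.roll(arr, -k, axis=axis)
    return out


def _filter_axis_adjoint(arr: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(arr, dtype=float)
    for k, t in enumerate(taps):
        out += t * np.roll(arr, k, axis=axis)
    return out


def wavelet_subbands(patch: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Single-level stationary (undecimated) separable 3D transform.

    Returns the eight same-shape sub-bands keyed 'LLL' ... 'HHH'; the letter
    at position *p* names the filter applied along axis *p* (x, y, z).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 3:
        raise ValueError("patch must be 3D")
    if min(patch.shape) < 2:
        raise ValueError(f"each axis needs at least 2 voxels, got shape {patch.shape}")
    w = pywt.Wavelet(wavelet)
    taps = {"L": np.asarray(w.dec_lo, dtype=float),
            "H": np.asarray(w.dec_hi, dtype=float)}
    out = {}
    for name in SUBBAND_NAMES:
        band = patch
        for axis, letter in enumerate(name):
            band = _filter_axis(band, taps[letter], axis)
        out[name] = band
    return out


def wavelet_reconstruct(subbands: dict[str, np.ndarray],
                        wavelet: str = "haar") -> np.ndarray:
    """Invert :func:`wavelet_subbands` (tight-frame adjoint, /2 per axis)."""
    w = pywt.Wavelet(wavelet)
    taps = {"L": np.asarray(w.dec_lo, dtype=float),
            "H": np.asarray(w.dec_hi, dtype=float)}
    acc = None
    for name, band in subbands.items():
        rec = np.asarray(band, dtype=float)
        for axis, letter in enumerate(name):
            rec = _filter_axis_adjoint(rec, taps[letter], axis)
        acc = rec if acc is None else acc + rec
    return acc / 2 ** len(next(iter(subbands)))


# ---------------------------------------------------------------------------
# texture matrices

def _neighbor_stacks(disc: DiscretizedVOI):
    """Yield, for every Chebyshev-1 offset, the neighbor level grid and a
    validity grid (in-box and in-VOI), aligned with the central voxel."""
    lv = disc.levels
    mask = disc.mask
    for off in _NEIGHBOR_OFFSETS:
        shifted_lv = lv
        shifted_ok = mask
        for axis, d in enumerate(off):
            if d == 0:
                continue
            shifted_lv = np.roll(shifted_lv, -d, axis=axis)
            shifted_ok = np.roll(shifted_ok, -d, axis=axis)
            # voxels whose neighbor fell off the box edge are invalid
            edge = [slice(None)] * 3
            edge[axis] = slice(-d, None) if d > 0 else slice(None, -d)
            shifted_ok = shifted_ok.copy()
            shifted_ok[tuple(edge)] = False
        yield shifted_lv, shifted_ok


def gldm_matrix(disc: DiscretizedVOI, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Gray-level dependence matrix ``P[i-1, j-1]``, levels i in 1..n_levels,
    dependence j in 1..27.  Mass equals the VOI voxel count."""
    dep = np.ones(disc.levels.shape, dtype=np.int64)  # the voxel itself
    for nb_lv, nb_ok in _neighbor_stacks(disc):
        dep += (nb_ok & (np.abs(nb_lv - disc.levels) <= alpha)) & disc.mask
    levels = disc.levels[disc.mask]
    deps = dep[disc.mask]
    P = np.zeros((disc.n_levels, 27), dtype=np.int64)
    np.add.at(P, (levels - 1, deps - 1), 1)
    return P


def gldm_features(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        raise ValueError("empty dependence matrix")
    p = P / total
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    pj = p.sum(axis=0)
    mu_j = float((pj * j).sum())
    return {
        "Dependence Variance": float((pj * (j - mu_j) ** 2).sum()),
        "Small Dependence Emphasis": float((pj / j ** 2).sum()),
    }


@dataclass
class NGTDMatrix:
    n: np.ndarray   # voxel count per level (levels 1..n_levels)
    p: np.ndarray   # probabilities (sum to 1 over occupied levels)
    s: np.ndarray   # per-level sum of |level - neighbor mean|
    n_valid: int    # voxels with at least one valid neighbor


def ngtdm_matrix(disc: DiscretizedVOI) -> NGTDMatrix:
    """Neighborhood gray-tone difference matrix.

    Neighbor means use only in-VOI neighbors; voxels with no valid neighbor
    are excluded from the counts.
    """
    nb_sum = np.zeros(disc.levels.shape, dtype=float)
    nb_cnt = np.zeros(disc.levels.shape, dtype=np.int64)
    for nb_lv, nb_ok in _neighbor_stacks(disc):
        nb_sum += np.where(nb_ok, nb_lv, 0)
        nb_cnt += nb_ok
    valid = disc.mask & (nb_cnt > 0)
    n_levels = disc.n_levels
    n = np.zeros(n_levels, dtype=np.int64)
    s = np.zeros(n_levels, dtype=float)
    lv = disc.levels[valid]
    diff = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n, lv - 1, 1)
    np.add.at(s, lv - 1, diff)
    n_valid = int(valid.sum())
    p = n / n_valid if n_valid else n.astype(float)
    return NGTDMatrix(n=n, p=p, s=s, n_valid=n_valid)


def ngtdm_features(m: NGTDMatrix) -> dict[str, float]:
    """Complexity: ``(1/N_v) sum_{i,j occupied} |i-j| (p_i s_i + p_j s_j)/(p_i + p_j)``.

    A VOI whose voxels have no valid neighbors (e.g. a single voxel) has
    Complexity 0 by convention.
    """
    if m.n_valid == 0:
        return {"Complexity": 0.0}
    occ = np.flatnonzero(m.p > 0)
    i = occ[:, None]
    j = occ[None, :]
    pi, pj = m.p[i], m.p[j]
    si, sj = m.s[i], m.s[j]
    lev = occ + 1
    complexity = (np.abs(lev[:, None] - lev[None, :])
                  * (pi * si + pj * sj) / (pi + pj)).sum() / m.n_valid
    return {"Complexity": float(complexity)}


# ---------------------------------------------------------------------------
# first order and feature assembly

def first_order_features(values: np.ndarray, spacing) -> dict[str, float]:
    """Energy, Total Energy (mm^3-weighted), Minimum, Mean, Maximum."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot compute first-order features of an empty VOI")
    sx, sy, sz = (float(s) for s in spacing)
    energy = float((values ** 2).sum())
    return {
        "Energy": energy,
        "Total Energy": sx * sy * sz * energy,
        "Minimum": float(values.min()),
        "Mean": float(values.mean()),
        "Maximum": float(values.max()),
    }


def extract_features(image, voxels: np.ndarray, *,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     alpha: float = DEFAULT_ALPHA,
                     wavelet_on: bool = True,
                     wavelet: str = "haar") -> dict[str, float]:
    """Full named feature vector for one stone VOI.

    Filtering (the wavelet bank) runs on the VOI's bounding box expanded by
    a one-voxel context margin (clipped to the grid) so single-slice stones
    still have a non-degenerate patch; features are then computed over the
    VOI voxels only.  Names follow ``<filter>-<family>-<feature>``, e.g.
    ``wavelet-HHH-GLDM-Dependence Variance``.
    """
    voxels = np.asarray(voxels, dtype=np.intp).reshape(-1, 3)
    if voxels.shape[0] == 0:
        raise ValueError("cannot extract features from an empty VOI")
    lo = np.maximum(voxels.min(axis=0) - 1, 0)
    hi = np.minimum(voxels.max(axis=0) + 2, image.shape)
    patch = image.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    mask = np.zeros(patch.shape, dtype=bool)
    mask[tuple((voxels - lo).T)] = True

    grids = {"original": patch}
    if wavelet_on:
        for band, g in wavelet_subbands(patch, wavelet).items():
            grids[f"wavelet-{band}"] = g

    out: dict[str, float] = {}
    for filt, grid in grids.items():
        vals = grid[mask]
        for feat, v in first_order_features(vals, image.spacing).items():
            out[f"{filt}-first order-{feat}"] = v
        disc = discretize(grid, mask, bin_width)
        for feat, v in gldm_features(gldm_matrix(disc, alpha)).items():
            out[f"{filt}-GLDM-{feat}"] = v
        for feat, v in ngtdm_features(ngtdm_matrix(disc)).items():
            out[f"{filt}-NGTDM-{feat}"] = v
    return out


def feature_table(image, components: list[np.ndarray], **kwargs) -> pd.DataFrame:
    """Feature vectors for a list of VOI components, one row each."""
    rows = [extract_features(image, comp, **kwargs) for comp in components]
    return pd.DataFrame(rows)


def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score: mean 0, sample SD 1; constant columns become 0."""
    if len(table) < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    out = table.copy().astype(float)
    sd = out.std(ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant feature columns mapped to zero: "
                      f"{list(out.columns[constant])}", stacklevel=2)
    out = out - out.mean()
    out.loc[:, ~constant.values] = out.loc[:, ~constant.values] / sd[~constant]
    out.loc[:, constant.values] = 0.0
    return out
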