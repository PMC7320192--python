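"""Quantitative map evaluation: FSC, resolution at a threshold, real-space
cross-correlation, and the shared Gaussian low-pass filter.

The Fourier shell correlation between maps :math:`a` and :math:`b` is

.. math::

    \\mathrm{FSC}(s) = \\frac{\\mathrm{Re}\\sum_{|k| \\approx s}
        F_a(k)\\,\\overline{F_b(k)}}
        {\\sqrt{\\sum |F_a|^2 \\sum |F_b|^2}}

over spherical shells one Fourier voxel wide (shell index = round(|k|)).
The frequency at which the curve first falls through 0.5 is reported as the
resolution.  The real-space cross-correlation coefficient (CCC) is the
Pearson correlation over all voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fourier import cfftn, icfftn, radius_grid
from .io_maps import DensityMap, FSCTable


@dataclass
class FSCCurve:
    """Per-shell correlation between two maps on a common grid."""

    shell_freq: np.ndarray      # 1/Å, one per shell (DC .. Nyquist)
    fsc: np.ndarray             # correlation per shell; NaN where undefined
    voxel_size: float
    box: int

    def to_table(self) -> FSCTable:
        valid = np.isfinite(self.fsc)
        return FSCTable(self.shell_freq[valid], np.clip(self.fsc[valid], -1, 1))


@dataclass
class Resolution:
    """Resolution estimate from an FSC curve.

    ``at_nyquist`` flags curves that never fall below the threshold (the
    value is then clamped to 2·voxel_size); ``no_signal`` flags curves that
    start below the threshold.
    """

    angstrom: float
    threshold: float
    at_nyquist: bool = False
    no_signal: bool = False


def _check_same_grid(a: DensityMap, b: DensityMap) -> None:
    if a.values.shape != b.values.shape:
        raise ValueError(f"grid mismatch: {a.values.shape} vs {b.values.shape}")
    if not np.isclose(a.voxel_size, b.voxel_size):
        raise ValueError(f"voxel size mismatch: {a.voxel_size} vs {b.voxel_size}")


def shell_indices(shape: tuple[int, ...]) -> np.ndarray:
    """Integer shell index per Fourier voxel: round(|k|) in voxel units."""
    return np.rint(radius_grid(shape)).astype(np.int64)


def fsc(a: DensityMap, b: DensityMap) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid.

    Shells with no voxels (none on cubic grids up to Nyquist) or with zero
    power in either map yield NaN.
    """
    _check_same_grid(a, b)
    n = a.box
    fa = cfftn(a.values)
    fb = cfftn(b.values)
    shells = shell_indices(fa.shape).ravel()
    n_shells = n // 2 + 1
    sel = shells < n_shells

    cross = np.bincount(shells[sel], weights=(fa * np.conj(fb)).real.ravel()[sel],
                        minlength=n_shells)
    pa = np.bincount(shells[sel], weights=(np.abs(fa) ** 2).ravel()[sel],
                     minlength=n_shells)
    pb = np.bincount(shells[sel], weights=(np.abs(fb) ** 2).ravel()[sel],
                     minlength=n_shells)
    counts = np.bincount(shells[sel], minlength=n_shells)

    with np.errstate(invalid="ignore", divide="ignore"):
        curve = cross / np.sqrt(pa * pb)
    curve[(counts == 0) | (pa == 0) | (pb == 0)] = np.nan

    freq = np.arange(n_shells) / (n * a.voxel_size)
    return FSCCurve(freq, curve, a.voxel_size, n)


def resolution_at(curve: FSCCurve, threshold: float = 0.5) -> Resolution:
    """Resolution (Å) where the FSC curve first falls through ``threshold``.

    The crossing frequency is linearly interpolated between the bracketing
    shells.  Curves that never drop below the threshold are clamped to the
    Nyquist resolution ``2·voxel_size`` and flagged.
    """
    valid = np.isfinite(curve.fsc)
    f = curve.shell_freq[valid]
    c = curve.fsc[valid]
    if f.size == 0:
        raise ValueError("empty FSC curve")
    nyquist = 2.0 * curve.voxel_size
    if c[0] < threshold:
        return Resolution(1.0 / f[1] if f.size > 1 and f[1] > 0 else np.inf,
                          threshold, no_signal=True)
    below = np.nonzero(c < threshold)[0]
    if below.size == 0:
        return Resolution(nyquist, threshold, at_nyquist=True)
    j = below[0]
    i = j - 1
    # linear interpolation of the crossing between shells i and j
    t = (c[i] - threshold) / (c[i] - c[j])
    freq_cross = f[i] + t * (f[j] - f[i])
    return Resolution(float(1.0 / freq_cross), threshold)


def ccc(a: DensityMap, b: DensityMap) -> float:
    """Real-space cross-correlation coefficient (Pearson, all voxels)."""
    _check_same_grid(a, b)
    x = a.values.ravel().astype(float)
    y = b.values.ravel().astype(float)
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("CCC undefined for a zero-variance map")
    return float(np.dot(x, y) / (nx * ny))


def gaussian_transfer(shape: tuple[int, ...], voxel_size: float,
                      resolution: float) -> np.ndarray:
    """Radial Gaussian transfer function with value 0.5 at 1/resolution.

    G(k) = exp(−ln2 · (|k|·resolution)²), |k| in 1/Å on the centered grid.
    """
    n = shape[0]
    k = radius_grid(shape) / (n * voxel_size)
    return np.exp(-np.log(2.0) * (k * resolution) ** 2)


def lowpass(density_map: DensityMap, resolution: float) -> DensityMap:
    """Gaussian low-pass with half-max transfer at ``1/resolution``.

    The DC term is untouched; the output is real.
    """
    if resolution < 2.0 * density_map.voxel_size:
        raise ValueError(
            f"resolution {resolution} Å is below Nyquist "
            f"({2 * density_map.voxel_size} Å)"
        )
    transfer = gaussian_transfer(density_map.shape, density_map.voxel_size,
                                 resolution)
    filtered = icfftn(cfftn(density_map.values) * transfer).real
    return DensityMap(filtered, density_map.voxel_size,
                      label=f"{density_map.label} lowpass {resolution:g}A")


def half_map_fsc(odd: DensityMap, even: DensityMap) -> FSCCurve:
    """Convenience wrapper: FSC between two half-data reconstructions."""
    return fsc(odd, even)


def z_elongation_ratio(density_map: DensityMap, filter_res: float = 8.0,
                       level: float = 0.5) -> float:
    """Support-extent ratio z/x at ``level``·max after an 8 Å display filter.

    Quantifies the missing-wedge elongation artifact: >1 means the particle
    is stretched along the beam (z).  The map is low-pass filtered first
    (as maps are conventionally displayed) so the half-max support is not
    dominated by single sharp voxels.
    """
    filtered = lowpass(density_map, max(filter_res, 2 * density_map.voxel_size))
    support = filtered.values > level * filtered.values.max()
    z_hit = np.nonzero(support.any(axis=(0, 1)))[0]
    x_hit = np.nonzero(support.any(axis=(1, 2)))[0]
    z_extent = (z_hit.max() - z_hit.min() + 1) if z_hit.size else 1
    x_extent = (x_hit.max() - x_hit.min() + 1) if x_hit.size else 1
    return float(z_extent) / float(x_extent)
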