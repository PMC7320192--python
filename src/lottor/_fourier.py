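"""Centered FFT helpers shared by the simulation, restoration and metrics code.

Every Fourier-domain array in this package uses the *centered* layout: DC
sits at index ``n // 2`` on each axis, matching the real-space box center
convention of :mod:`lottor.io_maps`.
"""

from __future__ import annotations

import numpy as np


def cfftn(values: np.ndarray) -> np.ndarray:
    """Centered n-dimensional FFT (DC at index n//2)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(values)))


def icfftn(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfftn`; returns a complex array."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spectrum)))


def centered_coords(n: int) -> np.ndarray:
    """Integer frequency (or voxel-offset) coordinates, DC at index n//2."""
    return np.arange(n) - n // 2


def radius_grid(shape: tuple[int, ...]) -> np.ndarray:
    """|k| in voxel units on the centered grid."""
    axes = np.meshgrid(*(centered_coords(n) for n in shape), indexing="ij")
    return np.sqrt(sum(a.astype(float) ** 2 for a in axes))
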