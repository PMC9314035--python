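"""Centered unitary FFT helpers.

All k-space in this package is DC-centered (DC at index ``N // 2`` per
axis) and the transform is orthonormal (``norm="ortho"``), so Parseval's
identity holds exactly and the adjoint of the forward FFT is its inverse.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from numpy.typing import NDArray


def cfftn(x: NDArray, axes: tuple[int, ...] = (-3, -2, -1)) -> NDArray:
    """Centered orthonormal n-dimensional FFT over ``axes``."""
    return np.fft.fftshift(
        sfft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def cifftn(k: NDArray, axes: tuple[int, ...] = (-3, -2, -1)) -> NDArray:
    """Inverse of :func:`cfftn`."""
    return np.fft.fftshift(
        sfft.ifftn(np.fft.ifftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def dc_index(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Index of the DC component under the centered convention."""
    return tuple(n // 2 for n in shape)
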