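"""Centered unitary FFT helpers.

One convention, used everywhere: DC sits at index ``N // 2`` and transforms
are unitary (``norm="ortho"``), so data-consistency and regularization terms
are balanced and regularization weights transfer across grid sizes.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as spfft


def fftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered unitary FFT along ``axes`` (default: all)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    elif np.isscalar(axes):
        axes = (axes,)
    return spfft.fftshift(
        spfft.fftn(spfft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered unitary inverse FFT along ``axes`` (default: all)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    elif np.isscalar(axes):
        axes = (axes,)
    return spfft.fftshift(
        spfft.ifftn(spfft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D FFT over the last two axes."""
    return fftc(x, axes=(-2, -1))


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D inverse FFT over the last two axes."""
    return ifftc(x, axes=(-2, -1))
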