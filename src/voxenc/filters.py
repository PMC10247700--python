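"""Batched FFT convolution with a fixed filter bank.

All Gabor stages in the package (fixed extractor banks, the synthetic
cortex's ground-truth energy stage, the frozen oriented-energy prefilter)
convolve a stack of images with the same modest set of kernels; doing this
per image with ``fftconvolve`` is wasteful.  The bank precomputes padded
kernel spectra once and convolves whole image batches in a single
vectorized FFT pass, matching ``scipy.signal.fftconvolve(..., mode="same")``
up to floating-point round-off.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft


class FilterBank:
    """Precomputed-spectrum linear convolution with complex kernels."""

    def __init__(self, kernels: list[np.ndarray], resolution: int):
        self.resolution = resolution
        self.kernels = [np.asarray(k) for k in kernels]
        kh = max(k.shape[0] for k in self.kernels)
        kw = max(k.shape[1] for k in self.kernels)
        self._shape = (sp_fft.next_fast_len(resolution + kh - 1),
                       sp_fft.next_fast_len(resolution + kw - 1))
        self._offsets = []
        spectra = []
        for k in self.kernels:
            spectra.append(sp_fft.fft2(k, self._shape))
            # fftconvolve 'same' crops the full result starting here
            self._offsets.append(((k.shape[0] - 1) // 2, (k.shape[1] - 1) // 2))
        self._spectra = np.stack(spectra)  # (C, FH, FW)

    @property
    def n_channels(self) -> int:
        return len(self.kernels)

    def convolve(self, images: np.ndarray) -> np.ndarray:
        """(N, R, R) real images -> (N, C, R, R) complex responses."""
        if images.ndim != 3 or images.shape[-1] != self.resolution:
            raise ValueError(f"expected (N, {self.resolution}, "
                             f"{self.resolution}) images, got {images.shape}")
        f_img = sp_fft.fft2(images, self._shape)          # (N, FH, FW)
        prod = f_img[:, None] * self._spectra[None]       # (N, C, FH, FW)
        full = sp_fft.ifft2(prod)
        r = self.resolution
        out = np.empty((images.shape[0], self.n_channels, r, r),
                       dtype=complex)
        for ci, (oy, ox) in enumerate(self._offsets):
            out[:, ci] = full[:, ci, oy:oy + r, ox:ox + r]
        return out

    def energy(self, images: np.ndarray) -> np.ndarray:
        """Quadrature amplitude |response| per kernel, (N, C, R, R)."""
        return np.abs(self.convolve(images))
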