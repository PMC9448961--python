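"""Maximal-overlap discrete wavelet transform (MODWT) with exact inverse.

The MODWT is the undecimated, shift-invariant variant of the orthonormal
DWT: at every level the signal is circularly filtered with upsampled,
1/sqrt(2)-rescaled scaling/wavelet filters, so each of the J detail bands
and the final approximation band has the full signal length.  With the
circular boundary the analysis/synthesis pair is exact for any signal
length, and the transform conserves energy:
``||x||^2 = sum_j ||D_j||^2 + ||A_J||^2``.

The default configuration — Symlet-4 at level J = 6 — decomposes a window
into seven bands (D1..D6 plus A6); a 250-sample window therefore carries
7 x 250 = 1,750 coefficients, which is the regression target dimension in
coefficient-mode training.

Filters come from PyWavelets; the pyramid itself is implemented here with
FFT circular convolution because PyWavelets' undecimated transform (SWT)
requires the signal length to be a power-of-two multiple, which bedside
windows are not.  All operations accept batched input (leading axes are
broadcast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .exceptions import FormatError, ParameterError

DEFAULT_WAVELET = "sym4"
DEFAULT_LEVEL = 6


def _upsampled_filter_fft(coeffs: np.ndarray, spacing: int, n: int) -> np.ndarray:
    """FFT of the filter with taps placed ``spacing`` samples apart (mod n)."""
    f = np.zeros(n)
    idx = (np.arange(len(coeffs)) * spacing) % n
    np.add.at(f, idx, coeffs)
    return np.fft.fft(f)


def _filter_ffts(wavelet: str, level: int, n: int):
    wav = pywt.Wavelet(wavelet)
    g = np.asarray(wav.dec_lo) / np.sqrt(2.0)  # MODWT scaling filter
    h = np.asarray(wav.dec_hi) / np.sqrt(2.0)  # MODWT wavelet filter
    gf, hf = [], []
    for j in range(1, level + 1):
        spacing = 2 ** (j - 1)
        gf.append(_upsampled_filter_fft(g, spacing, n))
        hf.append(_upsampled_filter_fft(h, spacing, n))
    return gf, hf


@dataclass
class CoeffVector:
    """MODWT coefficients of one or more windows.

    ``bands`` has shape (..., level + 1, window_samples): detail bands
    D1..DJ in order, then the approximation AJ.  ``flatten`` lays a window
    out as one vector of length (level + 1) * window_samples.
    """

    bands: np.ndarray
    wavelet: str = DEFAULT_WAVELET
    level: int = DEFAULT_LEVEL

    @property
    def n_bands(self) -> int:
        return self.bands.shape[-2]

    @property
    def window_samples(self) -> int:
        return self.bands.shape[-1]

    def flatten(self) -> np.ndarray:
        return self.bands.reshape(*self.bands.shape[:-2], -1)

    @classmethod
    def from_flat(cls, flat: np.ndarray, window_samples: int,
                  wavelet: str = DEFAULT_WAVELET,
                  level: int = DEFAULT_LEVEL) -> "CoeffVector":
        n_bands = level + 1
        if flat.shape[-1] != n_bands * window_samples:
            raise FormatError(
                f"flat length {flat.shape[-1]} != {n_bands} x {window_samples}"
            )
        return cls(
            bands=flat.reshape(*flat.shape[:-1], n_bands, window_samples),
            wavelet=wavelet, level=level,
        )


def modwt_decompose(x: np.ndarray, level: int = DEFAULT_LEVEL,
                    wavelet: str = DEFAULT_WAVELET) -> CoeffVector:
    """Decompose (batched) windows into level+1 MODWT bands.

    Parameters
    ----------
    x : array, shape (..., n)
        Signal window(s); the transform runs along the last axis with a
        circular boundary.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2 ** level:
        raise ParameterError(
            f"window of {n} samples is too short for level {level}; "
            f"use level <= {int(np.log2(n))}"
        )
    gf, hf = _filter_ffts(wavelet, level, n)
    v_hat = np.fft.fft(x, axis=-1)
    bands = []
    for j in range(level):
        bands.append(np.fft.ifft(v_hat * hf[j], axis=-1).real)
        v_hat = v_hat * gf[j]
    bands.append(np.fft.ifft(v_hat, axis=-1).real)
    return CoeffVector(
        bands=np.stack(bands, axis=-2), wavelet=wavelet, level=level
    )


def modwt_reconstruct(c: CoeffVector) -> np.ndarray:
    """Invert :func:`modwt_decompose` exactly (to round-off)."""
    bands = np.asarray(c.bands, dtype=float)
    if bands.shape[-2] != c.level + 1:
        raise FormatError(
            f"expected {c.level + 1} bands for level {c.level}, "
            f"got {bands.shape[-2]}"
        )
    n = bands.shape[-1]
    gf, hf = _filter_ffts(c.wavelet, c.level, n)
    v_hat = np.fft.fft(bands[..., -1, :], axis=-1)
    for j in range(c.level - 1, -1, -1):
        w_hat = np.fft.fft(bands[..., j, :], axis=-1)
        # Synthesis is circular correlation: conjugate filter spectra.
        v_hat = v_hat * np.conj(gf[j]) + w_hat * np.conj(hf[j])
    return np.fft.ifft(v_hat, axis=-1).real
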