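"""1-D wavelet scattering transform features.

The scattering transform cascades complex Gabor (Gaussian-envelope)
wavelet filterbanks with modulus nonlinearities and a final Gaussian
low-pass, producing features that are stable to small time shifts and
deformations while retaining multiscale amplitude structure — the
properties that make them effective inputs for waveform regression.

Layout.  A cascade with ``n_filterbanks`` banks produces scattering orders
1..n_filterbanks; order d coefficients live in channel d-1 of the output
tensor, with the order-0 (plain low-pass) path prepended to channel 0.
Each path contributes ``n`` time frames (the low-pass output subsampled at
a quarter of the invariance scale); channels are zero-padded along the
path axis to the maximum path count ``m`` so the tensor per window and
signal is (m x n) x n_filterbanks.  Path counts depend only on the window
length and the configuration, never on signal content.

The cascade follows the standard frequency-decreasing rule (a path only
continues into wavelets of lower centre frequency), and all filtering is
circular via the FFT, so features are deterministic and positively
homogeneous: scaling the input by a > 0 scales every coefficient by a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, ParameterError
from .simulate import FS

_F_MAX_CYCLES = 0.35  # highest wavelet centre frequency (cycles/sample)


@dataclass(frozen=True)
class ScatteringConfig:
    """Configuration of the scattering cascade.

    ``invariance_scale_s`` is the standard deviation of the final Gaussian
    averaging window; ``None`` defaults to half the analysed window.
    ``quality_factors`` gives wavelets-per-octave for each filterbank; the
    usual (8, 1) is extended with 1s to ``n_filterbanks``.
    """

    n_filterbanks: int = 4
    invariance_scale_s: float | None = None
    quality_factors: tuple[float, ...] = (8.0, 1.0)
    wavelet_family: str = "gabor"

    def validate(self, window_s: float) -> None:
        if self.n_filterbanks < 1:
            raise ParameterError("n_filterbanks must be >= 1")
        if self.wavelet_family != "gabor":
            raise ParameterError(
                f"unsupported wavelet family: {self.wavelet_family!r}"
            )
        if self.invariance_scale_s is not None and \
                self.invariance_scale_s > window_s + 1e-12:
            raise ParameterError(
                f"invariance scale {self.invariance_scale_s} s exceeds the "
                f"{window_s} s window"
            )

    def resolved_qs(self) -> tuple[float, ...]:
        qs = tuple(self.quality_factors)
        if len(qs) < self.n_filterbanks:
            qs = qs + (1.0,) * (self.n_filterbanks - len(qs))
        return qs[: self.n_filterbanks]


@dataclass
class FeatureTensor:
    """Scattering coefficients for a set of windows.

    ``values`` has shape (n_windows, n_signals, m * n, n_channels) where m
    is the (padded) path count per channel and n the number of time frames.
    ``flatten``/``unflatten`` are exact inverses given the stored layout.
    """

    values: np.ndarray
    m: int
    n: int
    signal_names: tuple[str, ...]
    subject_ids: np.ndarray
    config: ScatteringConfig
    paths_per_channel: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_signals(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[3]


def flatten_features(t: FeatureTensor) -> np.ndarray:
    """One feature vector per window (row-major over signal, path-time, channel)."""
    return t.values.reshape(t.n_windows, -1)


def unflatten_features(flat: np.ndarray, like: FeatureTensor) -> FeatureTensor:
    """Inverse of :func:`flatten_features` given a layout template."""
    values = np.asarray(flat).reshape(
        -1, like.n_signals, like.m * like.n, like.n_channels
    )
    return FeatureTensor(
        values=values, m=like.m, n=like.n, signal_names=like.signal_names,
        subject_ids=like.subject_ids, config=like.config,
        paths_per_channel=like.paths_per_channel,
    )


class ScatteringTransform:
    """Precomputed scattering operator for windows of a fixed length."""

    def __init__(self, window_samples: int, config: ScatteringConfig,
                 window_s: float | None = None, fs: float = FS):
        if window_samples < 8:
            raise ParameterError("window too short for scattering")
        if window_s is None:
            window_s = window_samples / fs
        config.validate(window_s)
        self.config = config
        self.n = window_samples  # signal length (frames computed below)
        inv_s = config.invariance_scale_s
        if inv_s is None:
            inv_s = window_s / 2.0
        self.sigma_t = max(inv_s * fs, 1.0)  # samples
        self.stride = max(1, int(self.sigma_t // 4))
        self.n_frames = int(np.ceil(window_samples / self.stride))

        freqs = np.fft.fftfreq(window_samples)  # cycles/sample
        # Gaussian low-pass with time-domain std sigma_t (unit DC gain).
        self.phi_hat = np.exp(-2.0 * np.pi ** 2 * self.sigma_t ** 2 * freqs ** 2)

        f_min = 1.0 / (2.0 * self.sigma_t)
        self.banks = []  # per order: (centre_freqs, psi_hats [n_k, N])
        for q in config.resolved_qs():
            centres, psis = [], []
            f = _F_MAX_CYCLES
            ratio = 2.0 ** (1.0 / q)
            sigma_rel = 1.0 - 2.0 ** (-1.0 / q)
            while f > f_min:
                sigma_f = max(f * sigma_rel, 1.0 / window_samples)
                psi = np.exp(-((freqs - f) ** 2) / (2.0 * sigma_f ** 2))
                psi[freqs <= 0] = 0.0  # analytic wavelet
                centres.append(f)
                psis.append(psi)
                f /= ratio
            if not centres:
                raise ParameterError(
                    "invariance scale leaves no wavelet above the low-pass band"
                )
            self.banks.append((np.asarray(centres), np.asarray(psis)))

        # Enumerate path counts once; they depend only on the layout.
        self.paths_per_channel = self._count_paths()
        self.m = max(self.paths_per_channel)

    def _count_paths(self) -> tuple[int, ...]:
        counts = [0] * len(self.banks)

        def walk(order, parent_f):
            if order >= len(self.banks):
                return
            centres, _ = self.banks[order]
            for f in centres:
                if f >= parent_f:
                    continue
                counts[order] += 1
                walk(order + 1, f)

        walk(0, np.inf)
        counts[0] += 1  # order-0 low-pass path lives in channel 0
        return tuple(counts)

    def _lowpass(self, xhat: np.ndarray) -> np.ndarray:
        s = np.fft.ifft(xhat * self.phi_hat, axis=-1).real
        return s[..., :: self.stride]

    def transform_array(self, x: np.ndarray) -> np.ndarray:
        """Scatter (..., window_samples) signals.

        Returns an array of shape (..., m * n_frames, n_filterbanks).
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n:
            raise InputError(
                f"expected windows of {self.n} samples, got {x.shape[-1]}"
            )
        lead = x.shape[:-1]
        out = np.zeros(lead + (len(self.banks), self.m, self.n_frames))
        cursor = [0] * len(self.banks)

        def emit(order, frames):
            out[..., order, cursor[order], :] = frames
            cursor[order] += 1

        def walk(xhat, order, parent_f):
            if order >= len(self.banks):
                return
            centres, psis = self.banks[order]
            for f, psi in zip(centres, psis):
                if f >= parent_f:
                    continue
                u = np.abs(np.fft.ifft(xhat * psi, axis=-1))
                uhat = np.fft.fft(u, axis=-1)
                emit(order, np.maximum(self._lowpass(uhat), 0.0))
                walk(uhat, order + 1, f)

        xhat0 = np.fft.fft(x, axis=-1)
        emit(0, self._lowpass(xhat0))  # order-0 path (may be signed)
        walk(xhat0, 0, np.inf)
        # (..., ch, m, frames) -> (..., m * frames, ch)
        axes = tuple(range(len(lead)))
        return out.transpose(axes + (len(lead) + 1, len(lead) + 2, len(lead))
                             ).reshape(lead + (self.m * self.n_frames,
                                               len(self.banks)))


def scattering_features(windows, config: ScatteringConfig | None = None
                        ) -> FeatureTensor:
    """Compute scattering features for every window of a WindowSet."""
    config = config or ScatteringConfig()
    op = ScatteringTransform(windows.window_samples, config,
                             window_s=windows.window_s)
    values = op.transform_array(windows.input_windows)
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite scattering coefficients")
    return FeatureTensor(
        values=values, m=op.m, n=op.n_frames,
        signal_names=tuple(windows.input_signals),
        subject_ids=windows.subject_ids, config=config,
        paths_per_channel=op.paths_per_channel,
    )
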