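"""Band decomposition of a voltage trace into phase and amplitude envelopes.

A raw trace V is resolved into a low-frequency component V_low and a
high-frequency component V_high; the Hilbert transform then yields the
low-frequency phase phi_low, the low-frequency amplitude envelope A_low and
the high-frequency amplitude envelope A_high. These five series are the
inputs to all coupling models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sg
from scipy.fft import next_fast_len

from . import filters
from .filters import FilterSpec, apply_filter, design_bandpass

__all__ = ["BandDecomposition", "analytic_phase_amplitude", "decompose"]


@dataclass
class BandDecomposition:
    """A voltage trace resolved into band components and envelopes.

    All arrays have the same length as the input signal. ``phi_low`` lies in
    (-pi, pi]; the envelopes are non-negative.
    """

    v_low: np.ndarray
    v_high: np.ndarray
    phi_low: np.ndarray
    a_low: np.ndarray
    a_high: np.ndarray
    fs: float
    low_band: tuple[float, float] = filters.LOW_BAND
    high_band: tuple[float, float] = filters.HIGH_BAND
    #: Optional binary condition indicator aligned with the samples.
    condition: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.v_low)

    def trimmed(self, edge_s: float = 1.0) -> "BandDecomposition":
        """Return a copy with ``edge_s`` seconds removed from each end.

        Filtering and the Hilbert transform are unreliable near the record
        edges; model fitting discards one second per side by default.
        """
        k = int(round(edge_s * self.fs))
        if k == 0:
            return self
        if 2 * k >= len(self):
            raise ValueError("trim longer than the record")
        sl = slice(k, len(self) - k)
        return BandDecomposition(
            self.v_low[sl], self.v_high[sl], self.phi_low[sl],
            self.a_low[sl], self.a_high[sl], self.fs,
            self.low_band, self.high_band,
            None if self.condition is None else self.condition[sl],
        )

    def to_frame(self):
        """Columnar view (t, v_low, v_high, phi_low, a_low, a_high)."""
        import pandas as pd

        t = np.arange(len(self)) / self.fs
        return pd.DataFrame({
            "t": t, "v_low": self.v_low, "v_high": self.v_high,
            "phi_low": self.phi_low, "a_low": self.a_low, "a_high": self.a_high,
        })


def analytic_phase_amplitude(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude of a real signal.

    The analytic signal is computed with the Hilbert transform (FFT padded to
    a fast length); the amplitude is its modulus and the phase its argument
    in (-pi, pi].

    Returns
    -------
    (phase, amplitude)
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = _sg.hilbert(x, next_fast_len(n))[:n]
    return np.angle(a), np.abs(a)


def decompose(
    samples: np.ndarray,
    fs: float,
    low_band: tuple[float, float] = filters.LOW_BAND,
    high_band: tuple[float, float] = filters.HIGH_BAND,
    low_order: int = filters.LOW_ORDER,
    high_order: int = filters.HIGH_ORDER,
) -> BandDecomposition:
    """Filter a voltage trace into two bands and extract phases/envelopes.

    Parameters
    ----------
    samples : array_like
        The voltage trace (one sample per entry).
    fs : float
        Sampling rate in Hz. Must exceed twice the upper edge of the high
        band.
    low_band, high_band : tuple of float
        Passband edges in Hz for the slow and fast components.
    low_order, high_order : int
        FIR filter orders (taps - 1).
    """
    samples = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("signal contains non-finite samples")
    filters.check_band_overlap(low_band, high_band)

    h_low = design_bandpass(
        FilterSpec(tuple(low_band), low_order, filters.LOW_TRANSITION), fs)
    h_high = design_bandpass(
        FilterSpec(tuple(high_band), high_order, filters.HIGH_TRANSITION), fs)

    v_low = apply_filter(samples, h_low)
    v_high = apply_filter(samples, h_high)
    phi_low, a_low = analytic_phase_amplitude(v_low)
    _, a_high = analytic_phase_amplitude(v_high)
    return BandDecomposition(
        v_low, v_high, phi_low, a_low, a_high, fs,
        tuple(low_band), tuple(high_band),
    )
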