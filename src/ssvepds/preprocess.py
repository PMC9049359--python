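"""Zero-phase FIR band-pass filtering of raw EEG.

The pipeline isolates the narrow band around the 60 Hz stimulation frequency
(default pass band 55-65 Hz) with a linear-phase FIR filter applied forward
and backward ("zero-phase"), so that the phase relation between the SSVEP
and the sinusoidal reference is preserved for the CCA stage.  The filter
order trades off stop-band attenuation against the shortest window that can
be filtered, so it is itself a meta-parameter searched on training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .containers import Recording

__all__ = [
    "BandpassSpec",
    "design_bandpass",
    "apply_zero_phase",
    "search_filter_order",
]

DEFAULT_ORDER = 66
DEFAULT_BAND = (55.0, 65.0)


@dataclass(frozen=True)
class BandpassSpec:
    """FIR band-pass specification: even ``order``, pass ``band`` in Hz."""

    order: int = DEFAULT_ORDER
    band: tuple[float, float] = DEFAULT_BAND
    f_sample: float = 2048.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.f_sample / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if self.order < 2 or self.order % 2 != 0:
            raise ValueError("filter order must be an even integer >= 2")


def design_bandpass(spec: BandpassSpec) -> np.ndarray:
    """Design the linear-phase (type-I) band-pass FIR.

    Windowed-sinc design with a Hamming window; returns ``order + 1``
    symmetric coefficients.
    """
    return signal.firwin(
        spec.order + 1,
        list(spec.band),
        pass_zero=False,
        window="hamming",
        fs=spec.f_sample,
    )


def _filter_array(coeffs: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis.

    The signal is reflection-padded by one filter length at both ends, then
    convolved with the forward-backward kernel ``conv(b, reversed(b))`` —
    exactly equivalent to filtering twice (once reversed), which squares the
    magnitude response and cancels the phase.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    n = data.shape[-1]
    pad = len(coeffs)
    if n <= pad:
        raise ValueError(
            f"window too short: {n} samples cannot be filtered with a "
            f"{len(coeffs)}-tap filter (need more than {pad} samples)"
        )
    # conv(b, reversed(b)) is symmetric, so convolution == correlation here;
    # ndimage's 'mirror' boundary is exactly the reflection padding (the
    # kernel half-width is order < order+1, so deeper extension is never read)
    kernel = np.convolve(coeffs, coeffs[::-1])
    return ndimage.convolve1d(data, kernel, axis=-1, mode="mirror")


class GrowingWindowFilter:
    """Incremental zero-phase filtering of a growing window.

    Filtered values farther than the kernel half-width from the window end
    cannot change when the window grows, so they are cached; each growth
    step refilters only the tail.  The result is bit-identical to
    re-filtering the full window with :func:`apply_zero_phase` (same
    reflection padding, same forward-backward kernel).
    """

    def __init__(self, coeffs: np.ndarray, n_channels: int, capacity: int):
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.pad = len(self.coeffs)
        self.half = self.pad - 1  # dependence range of the combined kernel
        self.kernel = np.convolve(self.coeffs, self.coeffs[::-1])
        self._filt = np.empty((n_channels, capacity))
        self._stable = 0

    def reset(self) -> None:
        self._stable = 0

    def window(self, data: np.ndarray, w: int) -> np.ndarray:
        """Zero-phase filtered view of ``data[:, :w]`` (w non-decreasing)."""
        if w <= self.pad:
            raise ValueError("window too short for the filter length")
        if w > self._filt.shape[1]:
            extra = np.empty((self._filt.shape[0], w - self._filt.shape[1]))
            self._filt = np.concatenate([self._filt, extra], axis=1)
        start = min(self._stable, w)
        if start < w:
            pad, m = self.pad, self.half
            padded = np.pad(data[:, :w], ((0, 0), (pad, pad)), mode="reflect")
            seg = ndimage.convolve1d(
                padded[:, start + pad - m : w + pad + m],
                self.kernel, axis=-1, mode="constant",
            )
            self._filt[:, start:w] = seg[:, m : m + (w - start)]
            self._stable = max(0, w - m)
        return self._filt[:, :w]


def apply_zero_phase(coeffs: np.ndarray, recording):
    """Zero-phase filter a :class:`Recording` (or plain array) per channel."""
    if isinstance(recording, Recording):
        return Recording(
            _filter_array(coeffs, recording.data), recording.fs, recording.ch_names
        )
    return _filter_array(coeffs, np.asarray(recording, dtype=float))


def search_filter_order(training, orders, eval_window: float = 1.0,
                        f_stim: float = 60.0, band=DEFAULT_BAND):
    """Grid-search the FIR order maximizing ITR on the training data.

    For each candidate order the full offline pipeline is run: band-pass
    filtering, CCA filter-bank training, LDA, leave-one-trial-out accuracy at
    ``eval_window`` seconds, and the ITR at that window.  Ties are broken
    toward the lowest order, which permits the shortest classifiable windows.

    Returns ``(best_order, table)`` where ``table`` has one row per order.
    """
    from .metrics import itr, loo_accuracy  # deferred: metrics imports this module

    orders = list(orders)
    if not orders:
        raise ValueError("empty filter-order grid")
    window_len = int(round(eval_window * training.fs))
    if window_len > training.n_samples:
        raise ValueError("evaluation window exceeds trial length")
    C = len(training.classes)
    rows = []
    for order in orders:
        if order + 1 >= window_len:
            raise ValueError(
                f"order {order} leaves no room in a {window_len}-sample window"
            )
        g = loo_accuracy(
            training, window_len, f_stim=f_stim, filter_order=order, band=band
        )
        rows.append({"order": order, "accuracy": g,
                     "itr": itr(g, C, eval_window) if g > 0 else 0.0})
    table = pd.DataFrame(rows)
    best_i = table.sort_values(["itr", "order"], ascending=[False, True]).index[0]
    return int(table.loc[best_i, "order"]), table
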