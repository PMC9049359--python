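"""Evaluation machinery: ITR, narrow-band SNR, cross-validation, grid searches.

The information transfer rate (ITR, bits/min) of a C-class selection made in
T seconds with accuracy G is

    ITR = (60 / T) * (log2 C + G log2 G + (1 - G) log2((1 - G) / (C - 1)))

SSVEP response strength is quantified as the power at the stimulation
frequency divided by the mean power in the 58.75-61.25 Hz band excluding
the stimulation bin (periodogram at 0.25 Hz resolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .containers import Recording, TrialSet
from .preprocess import DEFAULT_BAND, DEFAULT_ORDER, BandpassSpec, apply_zero_phase, design_bandpass
from .cca import iter_window_stats
from .lda import GaussianLDA

__all__ = [
    "itr",
    "snr_60hz",
    "SNREstimate",
    "loo_accuracy",
    "optimal_fixed_window",
    "grid_search_NP",
    "pearson",
    "cohort_summary",
    "band_periodogram_powers",
]


def itr(G: float, C: int, T: float) -> float:
    """Information transfer rate in bits/min.

    ``G`` is the classification accuracy, ``C`` the number of classes and
    ``T`` the selection time in seconds.  At G=1 the entropy terms vanish by
    continuity.  The formula has its minimum (exactly 0) at chance accuracy
    G = 1/C and rises on both sides; a below-chance G is reported faithfully
    but flagged with a warning, since the formula then credits information
    to systematically wrong answers.
    """
    if C < 2:
        raise ValueError("C must be >= 2")
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0 < G <= 1:
        raise ValueError("G must lie in (0, 1]")
    if G < 1.0 / C:
        warnings.warn(
            "accuracy below chance: the ITR formula overstates throughput",
            RuntimeWarning, stacklevel=2,
        )
    bits = np.log2(C)
    if G > 0:
        bits += G * np.log2(G)
    if G < 1:
        bits += (1 - G) * np.log2((1 - G) / (C - 1))
    return 60.0 / T * float(bits)


def band_periodogram_powers(
    data: np.ndarray,
    fs: float,
    f_stim: float,
    band: tuple[float, float] = (58.75, 61.25),
) -> tuple[float, float]:
    """Channel-averaged periodogram power at ``f_stim`` and around it.

    The periodogram (boxcar taper) is zero-padded to the next 4-second
    multiple so bins fall on a 0.25 Hz grid that contains the band edges and
    the stimulation frequency exactly.  Returns ``(power at the f_stim bin,
    mean power over the in-band bins excluding that bin)``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[1]
    block = int(round(4 * fs))
    nfft = max(int(np.ceil(n / block)) * block, block)
    freqs, pxx = sp_signal.periodogram(
        data, fs=fs, window="boxcar", nfft=nfft, detrend="constant", axis=1
    )
    mean_pxx = pxx.mean(axis=0)
    sig_bin = int(np.argmin(np.abs(freqs - f_stim)))
    in_band = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    in_band[sig_bin] = False
    if in_band.sum() < 2:
        raise ValueError("noise band contains fewer than 2 bins")
    return float(mean_pxx[sig_bin]), float(mean_pxx[in_band].mean())


@dataclass(frozen=True)
class SNREstimate:
    signal_power: float
    noise_power: float
    snr: float
    resolution: float  # Hz per bin


def snr_60hz(recording, f_stim: float = 60.0,
             band: tuple[float, float] = (58.75, 61.25)) -> SNREstimate:
    """Narrow-band SNR of the SSVEP response.

    Power at the stimulation-frequency bin over the mean power of the
    0.25 Hz bins in ``band`` excluding that bin, averaged over channels.
    Recordings shorter than 4 s are zero-padded (degraded effective
    resolution, warned).
    """
    if isinstance(recording, Recording):
        data, fs = recording.data, recording.fs
    else:
        raise TypeError("snr_60hz expects a Recording")
    if f_stim >= fs / 2 or band[1] >= fs / 2:
        raise ValueError("band outside the Nyquist range")
    if data.shape[1] < 4 * fs:
        warnings.warn(
            "recording shorter than 4 s: 0.25 Hz bins obtained by zero-padding",
            RuntimeWarning,
            stacklevel=2,
        )
    sig, noise = band_periodogram_powers(data, fs, f_stim, band)
    snr = sig / noise if noise > 0 else np.inf
    return SNREstimate(sig, noise, float(snr), 0.25)


def _filtered(training: TrialSet, filter_order: int, filt_band) -> np.ndarray:
    spec = BandpassSpec(order=filter_order, band=tuple(filt_band),
                        f_sample=training.fs)
    return apply_zero_phase(design_bandpass(spec), training.data)


def _loo_for_stats(stats, labels: np.ndarray, leak_held_out: bool = False) -> float:
    """Leave-one-trial-out accuracy from precomputed window statistics."""
    classes = np.unique(labels)
    n = stats.n_trials
    class_idx = {int(c): np.flatnonzero(labels == c) for c in classes}
    # full-data banks and baseline features (first canonical pair per class)
    banks = {}
    for c in classes:
        A, B, _ = stats.solve_class(class_idx[int(c)])
        banks[int(c)] = (A[:, 0], B[:, 0])
    F = np.column_stack([stats.features(*banks[int(c)]) for c in classes])
    col_of = {int(c): j for j, c in enumerate(classes)}
    correct = 0
    for j in range(n):
        c_j = int(labels[j])
        keep = np.ones(n, dtype=bool)
        keep[j] = False
        Fj = F.copy()
        if not leak_held_out:
            idx = class_idx[c_j]
            down = idx[idx != j]
            if len(down) < 2:
                raise ValueError("every class needs at least 3 trials for LOO")
            A, B, _ = stats.solve_class(down)
            Fj[:, col_of[c_j]] = stats.features(A[:, 0], B[:, 0])
        model = GaussianLDA().fit(Fj[keep], labels[keep])
        if int(model.predict(Fj[j])) == c_j:
            correct += 1
    return correct / n


def loo_accuracy(training: TrialSet, window_len: int, f_stim: float = 60.0,
                 filter_order: int = DEFAULT_ORDER, band=DEFAULT_BAND,
                 leak_held_out: bool = False) -> float:
    """Leave-one-trial-out classification accuracy at one window length.

    For each held-out trial, the filter bank of its class and all LDA
    training features are recomputed without it, so the held-out trial
    contributes to neither the spatial filters nor the classifier.
    ``leak_held_out=True`` deliberately skips the filter-bank exclusion — a
    negative control for leakage detection, never for reporting.
    """
    classes, counts = np.unique(training.labels, return_counts=True)
    if np.any(counts < 3):
        raise ValueError("need at least 3 trials per class for LOO")
    if window_len > training.n_samples:
        raise ValueError("window_len exceeds trial length")
    data = _filtered(training, filter_order, band)
    stats = next(iter_window_stats(data, f_stim, training.fs, [window_len]))
    return _loo_for_stats(stats, training.labels, leak_held_out)


def optimal_fixed_window(training: TrialSet, window_grid_s, f_stim: float = 60.0,
                         filter_order: int = DEFAULT_ORDER, band=DEFAULT_BAND,
                         filtered_data: np.ndarray | None = None):
    """Fixed window length maximizing ITR of the LOO accuracy.

    ``window_grid_s`` is a grid of candidate windows in seconds.  Returns
    ``(T_star_seconds, table)`` with per-window accuracy and ITR; ties are
    broken toward the shortest window.  ``filtered_data`` may carry the
    already band-pass-filtered trials (to avoid re-filtering when the same
    session is used elsewhere); it must match ``training.data`` in shape.
    """
    grid = sorted(float(t) for t in window_grid_s)
    if not grid:
        raise ValueError("empty window grid")
    lengths = [int(round(t * training.fs)) for t in grid]
    if lengths[-1] > training.n_samples:
        raise ValueError("window grid exceeds trial length")
    C = len(training.classes)
    if filtered_data is None:
        data = _filtered(training, filter_order, band)
    else:
        if filtered_data.shape != training.data.shape:
            raise ValueError("filtered_data shape mismatch")
        data = filtered_data
    rows = []
    for t_s, stats in zip(
        grid, iter_window_stats(data, f_stim, training.fs, lengths)
    ):
        g = _loo_for_stats(stats, training.labels)
        rate = itr(g, C, t_s) if g > 0 else -np.inf
        rows.append({"window_s": t_s, "accuracy": g, "itr": rate})
    table = pd.DataFrame(rows)
    best = table.sort_values(["itr", "window_s"], ascending=[False, True]).index[0]
    return float(table.loc[best, "window_s"]), table


def grid_search_NP(training: TrialSet, N_grid, P_grid, stop_config=None,
                   n_folds: int = 5, f_stim: float = 60.0,
                   filter_order: int = DEFAULT_ORDER, band=DEFAULT_BAND):
    """Cross-validated grid search over the stopping parameters (N, P).

    Folds split whole stimulation sequences (class-balanced).  For each
    fold, per-length models are trained on the remaining sequences, the test
    trials are played back chunk-by-chunk, and the per-window (label,
    posterior) traces are recorded once; every (N, P) pair then replays its
    counter automaton over those traces.  ITR uses the pooled accuracy and
    mean stopping time.  Ties prefer larger N, then larger P (the more
    conservative stopper).

    Returns ``(N_star, P_star, surface)`` with one surface row per pair.
    """
    from .dynstop import StopConfig, DynamicStoppingClassifier, _automaton

    N_grid = sorted(set(int(n) for n in N_grid))
    P_grid = sorted(set(float(p) for p in P_grid))
    if not N_grid or not P_grid:
        raise ValueError("empty (N, P) grid")
    if stop_config is None:
        base = StopConfig(
            f_sample=training.fs,
            max_window=min(int(round(4 * training.fs)), training.n_samples),
        )
    else:
        base = stop_config
    if base.max_window > training.n_samples:
        raise ValueError("max_window exceeds trial length")
    if training.sequence is not None:
        groups = training.sequence
    else:
        groups = np.arange(training.n_trials)
    uniq = np.unique(groups)
    n_folds = min(n_folds, len(uniq))
    folds = [uniq[i::n_folds] for i in range(n_folds)]
    C = len(training.classes)
    traces, truth = [], []
    for heldout in folds:
        test_mask = np.isin(groups, heldout)
        clf = DynamicStoppingClassifier(
            N=base.N, P=base.P, chunk_samples=base.chunk_samples,
            f_stim=f_stim, f_sample=training.fs, filter_order=filter_order,
            band=tuple(band), max_window=base.max_window,
        )
        clf.fit(training.data[~test_mask], training.labels[~test_mask])
        for i in np.flatnonzero(test_mask):
            traces.append(clf.trace(training.data[i]))
            truth.append(training.labels[i])
    surface = []
    for N in N_grid:
        for P in P_grid:
            stops, labels = [], []
            for (wins, labs, posts) in traces:
                k, lab, forced = _automaton(labs, posts, N, P)
                stops.append(wins[k])
                labels.append(lab)
            acc = float(np.mean(np.asarray(labels) == np.asarray(truth)))
            mean_t = float(np.mean(stops)) / training.fs
            rate = itr(acc, C, mean_t) if acc > 0 else -np.inf
            surface.append({"N": N, "P": P, "accuracy": acc,
                            "mean_time_s": mean_t, "itr": rate})
    surface = pd.DataFrame(surface)
    best = surface.sort_values(
        ["itr", "N", "P"], ascending=[False, False, False]
    ).index[0]
    return int(surface.loc[best, "N"]), float(surface.loc[best, "P"]), surface


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation (ddof=1) of each numeric column."""
    if len(results) < 2:
        raise ValueError("need at least 2 subjects")
    num = results.select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "std": num.std(ddof=1)}).T
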