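"""Online classification on growing windows with dynamic stopping.

The stream arrives in amplifier chunks (131 samples at 2048 Hz by default).
After every chunk the growing window is band-pass filtered, reduced to CCA
features and classified; the decision becomes final once N consecutive
evaluations return the same label, each with a posterior of at least P.
Because classification accuracy degrades when a short window is compared
against statistics learned on full-length trials, a separate filter bank and
LDA are trained for every reachable window length, with the training trials
trimmed to that length (the model cache).

A trial that exhausts its maximum window (default: the 4 s training length)
without meeting the criterion emits a *forced* decision carrying the last
label, so the interface always answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import Recording, TrialSet
from .preprocess import (
    BandpassSpec,
    DEFAULT_BAND,
    DEFAULT_ORDER,
    GrowingWindowFilter,
    apply_zero_phase,
    design_bandpass,
)
from .cca import CCAFilterBank, iter_window_stats
from .lda import GaussianLDA
from . import metrics as _metrics

__all__ = [
    "StopConfig",
    "Decision",
    "InsufficientDataError",
    "DynamicStoppingClassifier",
    "build_model_cache",
    "evaluate_window",
    "run_trial",
    "run_session",
]


class InsufficientDataError(RuntimeError):
    """The stream ended before the first classifiable window was reached."""


@dataclass(frozen=True)
class StopConfig:
    """Dynamic-stopping parameters.

    ``N``: required consecutive agreeing classifications; ``P``: posterior
    threshold each of them must reach; ``chunk_samples``: amplifier delivery
    quantum; ``max_window``: timeout in samples (default 4 s worth);
    ``min_window``: first classifiable window (default: set by the engine
    from the filter length).
    """

    N: int = 2
    P: float = 0.95
    chunk_samples: int = 131
    f_sample: float = 2048.0
    max_window: int | None = None
    min_window: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0, 1]")
        if self.chunk_samples < 1:
            raise ValueError("chunk_samples must be >= 1")
        if self.max_window is None:
            object.__setattr__(self, "max_window", int(round(4 * self.f_sample)))
        if self.min_window is not None and self.min_window > self.max_window:
            raise ValueError("min_window must not exceed max_window")


@dataclass
class Decision:
    """Outcome of one dynamically stopped trial."""

    label: int
    stop_window: int  # samples consumed when the decision was made
    stop_time: float  # seconds, = stop_window / f_sample
    trace: list[tuple[int, int, float]] = field(default_factory=list)
    forced: bool = False


def _automaton(labels, posts, N: int, P: float,
               hold_on_low_posterior: bool = False) -> tuple[int, int, bool]:
    """Scan a (label, posterior) trace; return (stop index, label, forced).

    The agreement counter increments when the label repeats with posterior
    >= P, restarts at 1 when a *new* label reaches P, and resets to 0 on a
    sub-threshold evaluation (unless the hold variant is enabled and the
    label at least repeated).  The decision is final when the counter
    reaches N; an exhausted trace forces the last label.
    """
    counter = 0
    prev = None
    for k, (lab, post) in enumerate(zip(labels, posts)):
        if post >= P:
            counter = counter + 1 if lab == prev else 1
        elif not (hold_on_low_posterior and lab == prev):
            counter = 0
        prev = lab
        if counter >= N:
            return k, lab, False
    return len(labels) - 1, prev, True


class DynamicStoppingClassifier(BaseEstimator):
    """Dynamic-stopping SSVEP classifier with a per-window-length model cache.

    ``fit`` trains, for every window length reachable by whole chunks up to
    ``max_window``, a class-specific CCA filter bank and an LDA on the
    training trials trimmed to that length.  ``predict_stream`` consumes a
    chunk iterator and returns a :class:`Decision`; ``score_session``
    evaluates a whole playback session.

    Parameters mirror :class:`StopConfig` plus the pipeline settings
    (stimulation frequency, FIR order and band, feature mode, LDA priors).
    """

    def __init__(self, N: int = 2, P: float = 0.95, chunk_samples: int = 131,
                 f_stim: float = 60.0, f_sample: float = 2048.0,
                 filter_order: int = DEFAULT_ORDER, band: tuple = DEFAULT_BAND,
                 max_window: int | None = None, min_window: int | None = None,
                 feature_mode: str = "first", priors=None,
                 include_forced: bool = True,
                 hold_on_low_posterior: bool = False):
        self.N = N
        self.P = P
        self.chunk_samples = chunk_samples
        self.f_stim = f_stim
        self.f_sample = f_sample
        self.filter_order = filter_order
        self.band = band
        self.max_window = max_window
        self.min_window = min_window
        self.feature_mode = feature_mode
        self.priors = priors
        self.include_forced = include_forced
        self.hold_on_low_posterior = hold_on_low_posterior

    # -- training -----------------------------------------------------------

    def _stop_config(self) -> StopConfig:
        return StopConfig(
            N=self.N, P=self.P, chunk_samples=self.chunk_samples,
            f_sample=self.f_sample, max_window=self.max_window,
            min_window=self.min_window,
        )

    def fit(self, X, y, filtered_data: np.ndarray | None = None):
        """Build the model cache from training trials ``X`` (n x L x T).

        ``filtered_data`` optionally carries the already zero-phase-filtered
        trials (same shape as ``X``) to avoid filtering the session twice.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be 3-D: trials x channels x samples")
        cfg = self._stop_config()
        if X.shape[2] < cfg.max_window:
            raise ValueError(
                f"training trials ({X.shape[2]} samples) are shorter than "
                f"max_window ({cfg.max_window})"
            )
        spec = BandpassSpec(order=self.filter_order, band=tuple(self.band),
                            f_sample=self.f_sample)
        self.coeffs_ = design_bandpass(spec)
        floor = cfg.min_window
        if floor is None:
            floor = max(cfg.chunk_samples, len(self.coeffs_) + 1)
        k_min = int(np.ceil(floor / cfg.chunk_samples))
        k_max = cfg.max_window // cfg.chunk_samples
        if k_min > k_max:
            raise ValueError("no classifiable window length below max_window")
        self.lengths_ = [k * cfg.chunk_samples for k in range(k_min, k_max + 1)]
        self.classes_ = np.unique(y)
        self.n_channels_ = X.shape[1]
        if filtered_data is not None:
            if filtered_data.shape != X.shape:
                raise ValueError("filtered_data shape mismatch")
            filtered = filtered_data
        else:
            filtered = apply_zero_phase(self.coeffs_, X)
        n_comp = 1 if self.feature_mode == "first" else 2
        self.models_ = {}
        class_idx = {int(c): np.flatnonzero(y == c) for c in self.classes_}
        for stats in iter_window_stats(filtered, self.f_stim, self.f_sample,
                                       self.lengths_):
            bank = CCAFilterBank(f_stim=self.f_stim, f_sample=self.f_sample,
                                 feature_mode=self.feature_mode)
            bank.classes_ = self.classes_
            bank.n_channels_ = self.n_channels_
            bank.window_len_ = stats.window_len
            bank.A_, bank.B_, bank.correlations_ = {}, {}, {}
            cols = []
            for c in self.classes_:
                A, B, r = stats.solve_class(class_idx[int(c)])
                bank.A_[int(c)] = A
                bank.B_[int(c)] = B
                bank.correlations_[int(c)] = r
                for k in range(n_comp):
                    if k < A.shape[1]:
                        cols.append(stats.features(A[:, k], B[:, k]))
                    else:
                        cols.append(np.zeros(stats.n_trials))
            F = np.column_stack(cols)
            model = GaussianLDA(priors=self.priors).fit(F, y)
            self.models_[stats.window_len] = (bank, model)
        return self

    # -- evaluation ---------------------------------------------------------

    def evaluate_window(self, window: np.ndarray) -> tuple[int, float]:
        """Filter, featurize and classify one window of a cached length."""
        window = np.asarray(window, dtype=float)
        if window.ndim != 2:
            raise ValueError("window must be 2-D (channels x samples)")
        w = window.shape[1]
        if w not in self.models_:
            raise KeyError(
                f"window length {w} is not a cached model length "
                f"(multiples of {self.chunk_samples} in "
                f"[{self.lengths_[0]}, {self.lengths_[-1]}])"
            )
        return self._classify_filtered(apply_zero_phase(self.coeffs_, window))

    def _classify_filtered(self, fw: np.ndarray) -> tuple[int, float]:
        bank, model = self.models_[fw.shape[1]]
        post = model.predict_proba(bank.transform(fw[None]))[0]
        best = int(np.argmax(post))
        return int(model.classes_[best]), float(post[best])

    def trace(self, trial: np.ndarray):
        """(windows, labels, posteriors) over *all* cached lengths (no stop)."""
        trial = np.asarray(trial, dtype=float)
        gwf = GrowingWindowFilter(self.coeffs_, trial.shape[0], self.lengths_[-1])
        wins, labels, posts = [], [], []
        for w in self.lengths_:
            if w > trial.shape[1]:
                break
            lab, post = self._classify_filtered(gwf.window(trial, w))
            wins.append(w)
            labels.append(lab)
            posts.append(post)
        return np.array(wins), np.array(labels), np.array(posts)

    def predict_stream(self, stream) -> Decision:
        """Consume chunks until the stopping criterion fires (or times out)."""
        cfg = self._stop_config()
        buffer = None
        gwf = None
        total = 0
        counter = 0
        prev = None
        last = None
        trace: list[tuple[int, int, float]] = []
        next_i = 0  # index into self.lengths_
        for chunk in stream:
            chunk = np.asarray(chunk, dtype=float)
            if buffer is None:
                buffer = chunk
                gwf = GrowingWindowFilter(
                    self.coeffs_, buffer.shape[0], self.lengths_[-1]
                )
            else:
                buffer = np.concatenate([buffer, chunk], axis=1)
            total = buffer.shape[1]
            while next_i < len(self.lengths_) and self.lengths_[next_i] <= total:
                w = self.lengths_[next_i]
                next_i += 1
                lab, post = self._classify_filtered(gwf.window(buffer, w))
                trace.append((w, lab, post))
                if post >= cfg.P:
                    counter = counter + 1 if lab == prev else 1
                elif not (self.hold_on_low_posterior and lab == prev):
                    counter = 0
                prev = lab
                last = (w, lab, post)
                if counter >= cfg.N:
                    return Decision(lab, w, w / self.f_sample, trace, False)
            if next_i >= len(self.lengths_):
                break  # max_window reached without satisfying the criterion
        if last is None:
            raise InsufficientDataError(
                f"stream ended after {total} samples, before the first "
                f"classifiable window ({self.lengths_[0] if self.lengths_ else '?'})"
            )
        w, lab, post = last
        return Decision(lab, w, w / self.f_sample, trace, True)

    def predict_fixed(self, X, window_len: int) -> np.ndarray:
        """Classify trials truncated to one fixed cached window length."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return np.array(
            [self.evaluate_window(x[:, :window_len])[0] for x in X]
        )

    def score_session(self, X, y, count_gap: bool = False,
                      gap_s: float = 0.5):
        """Play back labelled trials and summarize the session.

        Returns ``(decisions, summary)``; the summary holds accuracy, mean
        stopping time, the resulting ITR (selection time optionally
        including the inter-trial gaze-shift gap), the forced-timeout
        fraction, and a per-target breakdown.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or len(y) != X.shape[0]:
            raise ValueError("need trials x channels x samples plus one label each")
        from .synth import chunk_stream  # local import: synth imports metrics

        decisions = [
            self.predict_stream(
                chunk_stream(Recording(x, self.f_sample), self.chunk_samples)
            )
            for x in X
        ]
        labels = np.array([d.label for d in decisions])
        times = np.array([d.stop_time for d in decisions])
        forced = np.array([d.forced for d in decisions])
        use = np.ones(len(y), dtype=bool) if self.include_forced else ~forced
        acc = float(np.mean(labels[use] == y[use])) if use.any() else np.nan
        mean_t = float(times.mean())
        T_sel = mean_t + (gap_s if count_gap else 0.0)
        C = len(self.classes_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rate = _metrics.itr(acc, C, T_sel) if acc > 0 else -np.inf
        per_target = pd.DataFrame(
            [
                {
                    "target": int(c),
                    "accuracy": float(np.mean(labels[y == c] == c)),
                    "mean_time_s": float(times[y == c].mean()),
                    "n": int(np.sum(y == c)),
                }
                for c in np.unique(y)
            ]
        )
        summary = {
            "accuracy": acc,
            "mean_time_s": mean_t,
            "itr": float(rate),
            "forced_fraction": float(forced.mean()),
            "per_target": per_target,
            "n_trials": int(len(y)),
        }
        return decisions, summary


# -- functional wrappers ----------------------------------------------------


def build_model_cache(training: TrialSet, stop_config: StopConfig | None = None,
                      f_stim: float = 60.0, filter_order: int = DEFAULT_ORDER,
                      band=DEFAULT_BAND, **kwargs) -> DynamicStoppingClassifier:
    """Train per-window-length models (the cache) from a training session."""
    cfg = stop_config or StopConfig(f_sample=training.fs)
    clf = DynamicStoppingClassifier(
        N=cfg.N, P=cfg.P, chunk_samples=cfg.chunk_samples, f_stim=f_stim,
        f_sample=training.fs, filter_order=filter_order, band=tuple(band),
        max_window=cfg.max_window, min_window=cfg.min_window, **kwargs,
    )
    return clf.fit(training.data, training.labels)


def evaluate_window(window, cache: DynamicStoppingClassifier) -> tuple[int, float]:
    """Label and winning posterior for one window of a cached length."""
    if isinstance(window, Recording):
        window = window.data
    return cache.evaluate_window(window)


def run_trial(stream, cache: DynamicStoppingClassifier,
              stop_config: StopConfig | None = None) -> Decision:
    """Run the dynamic-stopping automaton over one chunked stream."""
    if stop_config is not None:
        cache = _with_config(cache, stop_config)
    return cache.predict_stream(stream)


def run_session(trials: TrialSet, cache: DynamicStoppingClassifier,
                stop_config: StopConfig | None = None, **kwargs):
    """Play back a labelled session; returns (decisions, summary)."""
    if stop_config is not None:
        cache = _with_config(cache, stop_config)
    return cache.score_session(trials.data, trials.labels, **kwargs)


def _with_config(cache: DynamicStoppingClassifier,
                 cfg: StopConfig) -> DynamicStoppingClassifier:
    """A view of the cache running under different stopping parameters."""
    if cfg.max_window > max(cache.lengths_):
        raise ValueError("stop_config.max_window exceeds the cached lengths")
    import copy

    clone = copy.copy(cache)
    clone.N, clone.P = cfg.N, cfg.P
    clone.chunk_samples = cfg.chunk_samples
    clone.max_window, clone.min_window = cfg.max_window, cfg.min_window
    clone.lengths_ = [w for w in cache.lengths_ if w <= cfg.max_window]
    return clone
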