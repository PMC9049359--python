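"""Canonical-correlation spatial filtering against a sinusoidal reference.

For each target class, the trials of that class are trimmed to a common
window length, concatenated along time, and canonically correlated with a
two-row sinusoidal reference (sine and cosine at the stimulation frequency):

    r = max_{A,B} corr(A X, B Y),     Y = [sin(2 pi f t); cos(2 pi f t)]

The resulting per-class spatial filters ``A_c`` and reference filters
``B_c`` are then *fixed*; applying all C of them to a new window and
collecting the first canonical correlation of each yields the C-dimensional
feature vector handed to the LDA classifier.

Two numerically equivalent solvers are provided: :func:`solve_cca` works on
raw signals via QR/SVD, and a private scatter-matrix path lets the
dynamic-stopping model cache and leave-one-trial-out loops retrain banks at
many window lengths from per-trial second moments without revisiting the
raw samples.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import Recording, TrialSet

__all__ = [
    "make_reference",
    "solve_cca",
    "CCAFilterBank",
    "train_filter_bank",
    "extract_features",
]


#: Projection variance below this fraction of the window's total power
#: (times the filter's squared norm) is considered numerically nulled.
DEGENERATE_REL_VAR = 1e-18


def make_reference(f_stim: float, f_sample: float, n_samples: int) -> np.ndarray:
    """Sinusoidal reference: row 0 is sin, row 1 is cos, at ``f_stim`` Hz.

    Time starts at t=0 and advances in steps of ``1/f_sample``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not f_stim < f_sample / 2:
        raise ValueError("f_stim must be below the Nyquist frequency")
    t = np.arange(n_samples) / f_sample
    w = 2 * np.pi * f_stim * t
    return np.vstack([np.sin(w), np.cos(w)])


def _whiten(C: np.ndarray) -> tuple[np.ndarray, int]:
    """Symmetric whitening transform of a PSD scatter matrix (rank-aware)."""
    vals, vecs = np.linalg.eigh(C)
    tol = max(C.shape[0], 1) * np.finfo(float).eps * max(vals[-1], 0.0)
    keep = vals > tol
    rank = int(keep.sum())
    if rank == 0:
        return np.zeros((C.shape[0], 0)), 0
    return vecs[:, keep] / np.sqrt(vals[keep]), rank


def _cca_from_scatter(
    Cxx: np.ndarray,
    Cxy: np.ndarray,
    Cyy: np.ndarray,
    n_total: int,
    max_components: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CCA weights and correlations from centered scatter matrices."""
    Wx, rank_x = _whiten(Cxx)
    Wy, rank_y = _whiten(Cyy)
    k = min(rank_x, rank_y, max_components)
    if k == 0:
        L, M = Cxx.shape[0], Cyy.shape[0]
        return np.zeros((L, 0)), np.zeros((M, 0)), np.zeros(0)
    U, s, Vt = np.linalg.svd(Wx.T @ Cxy @ Wy)
    scale = np.sqrt(max(n_total - 1, 1))  # unit-variance projections
    A = Wx @ U[:, :k] * scale
    B = Wy @ Vt.T[:, :k] * scale
    return A, B, np.clip(s[:k], 0.0, 1.0)


def solve_cca(
    X: np.ndarray, Y: np.ndarray, max_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve ``r = max corr(AX, BY)`` by orthogonalization and SVD.

    ``X`` is channels x samples, ``Y`` reference-rows x samples; both are
    centered internally.  Returns ``(A, B, r)`` with canonical correlations
    sorted in descending order, correlations clipped to [0, 1], and weights
    scaled so the canonical projections have unit variance.  Rank-deficient
    inputs reduce the number of components with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with the same number of samples")
    T = X.shape[1]
    if T <= X.shape[0] + Y.shape[0]:
        raise ValueError(
            f"too few samples ({T}) for CCA with {X.shape[0]}+{Y.shape[0]} variables"
        )
    Xc = (X - X.mean(axis=1, keepdims=True)).T
    Yc = (Y - Y.mean(axis=1, keepdims=True)).T

    def orth(M):
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int((s > tol).sum())
        return U[:, :rank], s[:rank], Vt[:rank], rank

    Qx, sx, Vxt, rank_x = orth(Xc)
    Qy, sy, Vyt, rank_y = orth(Yc)
    if rank_x < X.shape[0] or rank_y < Y.shape[0]:
        warnings.warn(
            "rank-deficient input: returning fewer canonical components",
            RuntimeWarning,
            stacklevel=2,
        )
    k = min(rank_x, rank_y, max_components)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    scale = np.sqrt(T - 1)
    A = (Vxt.T / sx) @ U[:, :k] * scale
    B = (Vyt.T / sy) @ Vt.T[:, :k] * scale
    return A, B, np.clip(s[:k], 0.0, 1.0)


class WindowStats:
    """Per-trial second moments of trials against the reference at one length.

    Everything the training side needs — class-level CCA banks (trials
    concatenated with a per-trial restarted reference) and per-trial
    canonical-correlation features under fixed filters — is a function of
    these moments, which makes retraining at many window lengths and
    leave-one-trial-out downdates cheap.
    """

    def __init__(self, Sxx, Sxy, sx, window_len, f_stim, f_sample):
        self.Sxx = Sxx  # (n, L, L)
        self.Sxy = Sxy  # (n, L, 2)
        self.sx = sx  # (n, L)
        self.window_len = int(window_len)
        self.f_stim = f_stim
        self.f_sample = f_sample
        Y = make_reference(f_stim, f_sample, self.window_len)
        self.Syy = Y @ Y.T
        self.sy = Y.sum(axis=1)
        w = self.window_len
        self.Cyy = self.Syy - np.outer(self.sy, self.sy) / w
        # centered per-trial moments (per-window mean removal)
        self.Cxx = self.Sxx - self.sx[:, :, None] * self.sx[:, None, :] / w
        self.Cxy = self.Sxy - self.sx[:, :, None] * self.sy[None, None, :] / w

    @property
    def n_trials(self) -> int:
        return self.Sxx.shape[0]

    @classmethod
    def from_trials(cls, data: np.ndarray, f_stim: float, f_sample: float,
                    window_len: int) -> "WindowStats":
        X = np.asarray(data, dtype=float)[:, :, :window_len]
        Y = make_reference(f_stim, f_sample, window_len)
        Sxx = np.einsum("nlt,nmt->nlm", X, X, optimize=True)
        Sxy = np.einsum("nlt,kt->nlk", X, Y, optimize=True)
        return cls(Sxx, Sxy, X.sum(axis=2), window_len, f_stim, f_sample)

    def solve_class(self, idx, max_components: int = 2):
        """Train one class filter pair from the trials in ``idx``.

        Equivalent to concatenating the trimmed trials along time against a
        reference that restarts at t=0 for every trial, and solving the CCA
        on the concatenation.
        """
        idx = np.asarray(idx)
        n_c = len(idx)
        w = self.window_len
        T_c = n_c * w
        sx_c = self.sx[idx].sum(axis=0)
        Cxx = self.Sxx[idx].sum(axis=0) - np.outer(sx_c, sx_c) / T_c
        Cxy = self.Sxy[idx].sum(axis=0) - np.outer(sx_c, self.sy) / w
        Cyy = n_c * self.Cyy
        return _cca_from_scatter(Cxx, Cxy, Cyy, T_c, max_components)

    def features(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """|corr| of each trial's window with the reference under (a, b).

        A projection whose variance is negligible relative to the window's
        total power (the filter direction nulls the signal, leaving only
        roundoff) is treated as degenerate and yields feature 0 — roundoff
        residue would otherwise correlate spuriously with the reference.
        """
        cov = (self.Cxy @ b) @ a
        var_x = np.clip((self.Cxx @ a) @ a, 0.0, None)
        var_y = float(b @ self.Cyy @ b)
        total = np.trace(self.Cxx, axis1=1, axis2=2)
        good = var_x > DEGENERATE_REL_VAR * (a @ a) * total
        out = np.zeros(self.n_trials)
        denom = np.sqrt(var_x[good] * var_y)
        out[good] = np.abs(cov[good]) / denom
        return np.clip(out, 0.0, 1.0)


def iter_window_stats(data: np.ndarray, f_stim: float, f_sample: float, lengths):
    """Yield :class:`WindowStats` at each requested length (ascending).

    Accumulates per-trial moments incrementally over the new segment of each
    window, so sweeping many lengths costs one pass over the samples.
    """
    data = np.asarray(data, dtype=float)
    lengths = sorted(int(w) for w in lengths)
    n, L, T = data.shape
    if lengths and lengths[-1] > T:
        raise ValueError("requested window length exceeds trial length")
    Y_full = make_reference(f_stim, f_sample, lengths[-1]) if lengths else None
    Sxx = np.zeros((n, L, L))
    Sxy = np.zeros((n, L, 2))
    sx = np.zeros((n, L))
    prev = 0
    for w in lengths:
        if w > prev:
            seg = data[:, :, prev:w]
            Sxx += np.einsum("nlt,nmt->nlm", seg, seg, optimize=True)
            Sxy += np.einsum("nlt,kt->nlk", seg, Y_full[:, prev:w], optimize=True)
            sx += seg.sum(axis=2)
            prev = w
        yield WindowStats(Sxx.copy(), Sxy.copy(), sx.copy(), w, f_stim, f_sample)


class CCAFilterBank(TransformerMixin, BaseEstimator):
    """Class-specific CCA spatial filter bank trained at one window length.

    Parameters
    ----------
    f_stim : stimulation frequency of the sinusoidal reference, Hz.
    f_sample : sampling rate, Hz.
    feature_mode : ``"first"`` emits the first canonical correlation per
        class (d = C features); ``"both"`` emits both canonical pairs
        (d = 2C, zero-padded where a class bank is rank-deficient).

    After ``fit``, ``A_[c]`` (channels x K) and ``B_[c]`` (2 x K columns as
    rows x K) hold the spatial and reference filters of each class, and
    ``correlations_[c]`` the training canonical correlations (descending).
    """

    def __init__(self, f_stim: float = 60.0, f_sample: float = 2048.0,
                 feature_mode: str = "first"):
        self.f_stim = f_stim
        self.f_sample = f_sample
        self.feature_mode = feature_mode

    def _check_mode(self) -> None:
        if self.feature_mode not in ("first", "both"):
            raise ValueError("feature_mode must be 'first' or 'both'")

    def fit(self, X, y):
        """Train per-class filters from trials ``X`` (n x channels x window)."""
        self._check_mode()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be 3-D: trials x channels x samples")
        if len(y) != X.shape[0]:
            raise ValueError("label count does not match trial count")
        classes, counts = np.unique(y, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 trials")
        w = X.shape[2]
        if w <= X.shape[1] + 2:
            raise ValueError("window too short for CCA on this channel count")
        stats = WindowStats.from_trials(X, self.f_stim, self.f_sample, w)
        self.classes_ = classes
        self.n_channels_ = X.shape[1]
        self.window_len_ = w
        self.A_, self.B_, self.correlations_ = {}, {}, {}
        for c in classes:
            A, B, r = stats.solve_class(np.flatnonzero(y == c))
            self.A_[int(c)] = A
            self.B_[int(c)] = B
            self.correlations_[int(c)] = r
        return self

    def _features_one(self, Xc: np.ndarray, Yc: np.ndarray, c: int,
                      n_comp: int, total_power: float) -> np.ndarray:
        A, B = self.A_[c], self.B_[c]
        out = np.zeros(n_comp)
        for k in range(min(n_comp, A.shape[1])):
            a = A[:, k]
            px = a @ Xc
            py = B[:, k] @ Yc
            var_x = px @ px
            # same degeneracy rule as the scatter path: a nulled projection
            # leaves only roundoff, which must not correlate spuriously
            if var_x > DEGENERATE_REL_VAR * (a @ a) * total_power:
                out[k] = min(abs(px @ py) / np.sqrt(var_x * (py @ py)), 1.0)
        return out

    def transform(self, X) -> np.ndarray:
        """Feature vectors for windows ``X`` (n x channels x window).

        Filters are applied *fixed* (no re-solving on test data); each
        window and the regenerated reference are mean-centered, projected,
        and correlated; absolute values are returned.  Degenerate windows
        (zero variance) produce zero features with a warning.
        """
        self._check_mode()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.n_channels_:
            raise ValueError("X must be trials x channels x samples")
        if X.shape[2] != self.window_len_:
            raise ValueError(
                f"window length {X.shape[2]} does not match the bank's trained "
                f"length {self.window_len_}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in input window")
        Y = make_reference(self.f_stim, self.f_sample, self.window_len_)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        Xc = X - X.mean(axis=2, keepdims=True)
        n_comp = 1 if self.feature_mode == "first" else 2
        F = np.zeros((X.shape[0], len(self.classes_) * n_comp))
        for i in range(X.shape[0]):
            total = float(np.sum(Xc[i] ** 2))
            feats = [
                self._features_one(Xc[i], Yc, int(c), n_comp, total)
                for c in self.classes_
            ]
            F[i] = np.concatenate(feats)
        if np.any(F.sum(axis=1) == 0):
            warnings.warn(
                "degenerate (zero-variance) window produced all-zero features",
                RuntimeWarning,
                stacklevel=2,
            )
        return F


def train_filter_bank(trials: TrialSet, window_len: int, f_stim: float = 60.0,
                      feature_mode: str = "first") -> CCAFilterBank:
    """Trim each trial to ``window_len`` samples and train the filter bank."""
    if window_len > trials.n_samples:
        raise ValueError("window_len exceeds trial length")
    bank = CCAFilterBank(f_stim=f_stim, f_sample=trials.fs, feature_mode=feature_mode)
    return bank.fit(trials.data[:, :, :window_len], trials.labels)


def extract_features(X, bank: CCAFilterBank) -> np.ndarray:
    """Feature vector(s) for a window (Recording, 2-D array, or stack)."""
    if isinstance(X, Recording):
        return bank.transform(X.data[None])[0]
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return bank.transform(X[None])[0]
    return bank.transform(X)
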