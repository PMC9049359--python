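"""Gaussian linear discriminant classification with posterior probabilities.

Class-conditional densities are multivariate Gaussians sharing one pooled
covariance; the classifier returns ``argmax_c P(c|f)`` with the posterior
obtained from Bayes' rule.  The shared normalization constant cancels in the
posterior, and all densities are evaluated in log-space with a log-sum-exp
normalization for numerical stability.  The pooled covariance is the
unbiased within-class estimate (scatter divided by n - C) and is shrunk
toward its diagonal only if ill-conditioned.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["GaussianLDA", "train_lda", "posterior", "classify"]

_SHRINKAGE_GRID = (0.0, 1e-4, 1e-2, 1e-1)
_COND_LIMIT = 1e8


class GaussianLDA(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis with explicit Gaussian posteriors.

    Parameters
    ----------
    priors : class prior probabilities; ``None`` means uniform (the
        stimulation protocol visits every target equally often).

    Fitted attributes: ``classes_``, ``means_`` (C x d class centroids),
    ``covariance_`` (pooled d x d), ``priors_``, ``shrinkage_`` (the
    diagonal-shrinkage weight actually applied).
    """

    def __init__(self, priors=None):
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in features")
        if len(y) != X.shape[0]:
            raise ValueError("label count does not match sample count")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 samples")
        n, d = X.shape
        if n < d + 1:
            raise ValueError("need at least d + 1 samples in total")
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        scatter = np.zeros((d, d))
        for c, mu in zip(classes, means):
            R = X[y == c] - mu
            scatter += R.T @ R
        cov = scatter / (n - len(classes))
        if np.any(np.diag(cov) <= 0):
            warnings.warn(
                "zero-variance feature dimension; covariance regularized",
                RuntimeWarning,
                stacklevel=2,
            )
        cov, gamma = _regularize(cov)
        if self.priors is None:
            priors = np.full(len(classes), 1.0 / len(classes))
        else:
            priors = np.asarray(self.priors, dtype=float)
            if len(priors) != len(classes) or np.any(priors < 0):
                raise ValueError("priors must be non-negative, one per class")
            priors = priors / priors.sum()
        self.classes_ = classes
        self.means_ = means
        self.covariance_ = cov
        self.priors_ = priors
        self.shrinkage_ = gamma
        self._chol = np.linalg.cholesky(cov)
        return self

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None]
        if X.shape[1] != self.means_.shape[1]:
            raise ValueError("feature dimension does not match the model")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in features")
        # log P(f|c) + log p(c) up to the shared Gaussian constant
        diff = X[:, None, :] - self.means_[None, :, :]  # (n, C, d)
        sol = np.linalg.solve(
            self._chol, diff.transpose(1, 2, 0)
        )  # (C, d, n) whitened
        maha = np.einsum("cdn,cdn->cn", sol, sol).T  # (n, C)
        log_joint = -0.5 * maha + np.log(self.priors_)[None, :]
        log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
        return log_post[0] if single else log_post

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities P(c|f); rows sum to 1."""
        return np.exp(self._log_posterior(X))

    def predict(self, X) -> np.ndarray:
        """Most probable class; exact ties go to the lowest class index."""
        lp = self._log_posterior(X)
        if lp.ndim == 1:
            return self.classes_[int(np.argmax(lp))]
        return self.classes_[np.argmax(lp, axis=1)]


def _regularize(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest diagonal shrinkage from the fixed grid taming the condition."""
    diag = np.diag(np.diag(cov))
    if np.all(np.diag(cov) <= 0):
        # fully degenerate: fall back to identity scaling
        return np.eye(cov.shape[0]) * max(np.trace(cov) / cov.shape[0], 1e-12), 1.0
    floor = np.eye(cov.shape[0]) * max(np.diag(cov).max(), 1e-300) * 1e-12
    for gamma in _SHRINKAGE_GRID:
        cand = (1 - gamma) * cov + gamma * diag + floor
        if np.linalg.cond(cand) < _COND_LIMIT:
            return cand, gamma
    gamma = _SHRINKAGE_GRID[-1]
    cand = (1 - gamma) * cov + gamma * diag
    cand += np.eye(cov.shape[0]) * np.diag(cand).max() * 1e-6
    return cand, gamma


def train_lda(features, labels, priors=None) -> GaussianLDA:
    """Fit the Gaussian LDA on feature vectors (samples x d)."""
    return GaussianLDA(priors=priors).fit(np.asarray(features), labels)


def posterior(model: GaussianLDA, f) -> np.ndarray:
    """Posterior probability vector over classes for one feature vector."""
    return model.predict_proba(np.asarray(f, dtype=float))


def classify(model: GaussianLDA, f):
    """Class label with the maximum posterior (ties: lowest class index)."""
    return model.predict(np.asarray(f, dtype=float))
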