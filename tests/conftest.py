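"""Shared fixtures: small, fast synthetic configurations.

Unit tests run at a reduced scale (8 channels, 3 classes, 512 Hz, 1 s
trials, 64-sample chunks) so the whole suite stays quick; the full study
conditions (32 channels, 5 classes, 2048 Hz, 131-sample chunks) are
exercised by the acceptance tests.
"""

import pytest
from hypothesis import settings, HealthCheck

import ssvepds as s

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 512.0
CHUNK = 64
ORDER = 30


def small_config(snr: float, seed: int, **kw) -> s.SynthConfig:
    return s.SynthConfig(
        n_channels=8, n_classes=3, f_sample=FS, snr=snr, seed=seed, **kw
    )


def small_session(snr: float, seed: int, n_sequences: int = 6,
                  duration: float = 1.0, min_separation: float = 0.5,
                  **kw) -> s.TrialSet:
    cfg = small_config(snr, seed, **kw)
    topo = s.make_topographies(cfg.n_channels, cfg.n_classes,
                               min_separation, seed=seed)
    return s.simulate_session(n_sequences, duration, cfg, topo)


def small_classifier(**kw) -> s.DynamicStoppingClassifier:
    params = dict(
        N=2, P=0.95, chunk_samples=CHUNK, f_stim=60.0, f_sample=FS,
        filter_order=ORDER, max_window=int(FS),
    )
    params.update(kw)
    return s.DynamicStoppingClassifier(**params)


@pytest.fixture(scope="session")
def clean_session() -> s.TrialSet:
    """High-SNR session: easily separable at short windows."""
    return small_session(snr=30.0, seed=101)


@pytest.fixture(scope="session")
def noisy_session() -> s.TrialSet:
    """Mid-SNR session: imperfect accuracy, useful for leakage checks."""
    return small_session(snr=1.8, seed=202)


@pytest.fixture(scope="session")
def chance_session() -> s.TrialSet:
    """No SSVEP component at all: classification must sit at chance."""
    return small_session(snr=0.0, seed=303)


@pytest.fixture(scope="session")
def noiseless_session() -> s.TrialSet:
    """Pure rank-1 sinusoids, no noise, no jitter, orthogonal topographies.

    The exactly separable limit: each class's rank-1 CCA filter nulls the
    other classes' patterns, so features are 1 for the true class and 0
    elsewhere.  (With correlated topographies and zero noise every class
    filter recovers a perfect 60 Hz sinusoid, so separation needs noise.)
    """
    return small_session(
        snr=8.0, seed=404, min_separation=1.0,
        noise_scale=0.0, phase_jitter=0.0, amp_jitter=0.0,
    )


@pytest.fixture(scope="session")
def fitted_clean(clean_session):
    clf = small_classifier()
    return clf.fit(clean_session.data, clean_session.labels)
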