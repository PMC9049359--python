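"""Synthetic spatially-coded SSVEP EEG generator.

The spatially-coded paradigm drives all targets with a single flicker
frequency; what distinguishes the classes is the scalp *topography* of the
steady-state response, which depends on where the flicker falls in the
visual field.  The generator therefore emulates:

* an L-channel recording (default 32 channels at 2048 Hz),
* a narrow-band sinusoidal SSVEP component at the stimulation frequency
  (default 60 Hz) projected through a class-specific unit-norm topography,
  with per-trial phase and amplitude jitter,
* spatially mixed 1/f^alpha Gaussian background noise,
* the amplifier's chunked delivery of the online stream (131-sample chunks).

The ``snr`` parameter is calibrated against :func:`ssvepds.metrics.snr_60hz`
(power at the stimulation frequency over the mean power in the surrounding
58.75-61.25 Hz band excluding the stimulation bin), so that the measured
narrow-band SNR of generated trials matches the configured value in
expectation.  Because the stimulation bin itself contains noise, that
estimator has a floor of ~1; configured values at or below 1 produce no
discernible tone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator

import numpy as np

from .containers import Recording, TrialSet
from .metrics import band_periodogram_powers

__all__ = [
    "SynthConfig",
    "make_topographies",
    "simulate_trial",
    "simulate_session",
    "chunk_stream",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic SSVEP recording setup."""

    n_channels: int = 32
    n_classes: int = 5
    f_stim: float = 60.0
    f_sample: float = 2048.0
    snr: float = 4.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    phase_jitter: float = 0.3
    amp_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not self.f_stim < self.f_sample / 2:
            raise ValueError("stimulation frequency must be below Nyquist")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_topographies(
    L: int, C: int, min_separation: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Draw ``C`` unit-norm scalp patterns in ``L`` channels.

    Patterns are built from a seeded random orthonormal frame: each class
    pattern mixes its own orthogonal direction with one shared direction so
    that every pair has absolute correlation exactly ``1 - min_separation``
    (0 for ``min_separation=1``, i.e. mutually orthogonal patterns).

    Returns an ``L x C`` matrix, one unit-norm column per class.
    """
    if C < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= min_separation <= 1.0:
        raise ValueError("min_separation must lie in [0, 1]")
    if L < C:
        raise ValueError(
            f"cannot place {C} patterns with pairwise correlation "
            f"<= {1 - min_separation:.3g} in only {L} channels"
        )
    rho = 1.0 - min_separation
    need_shared = rho > 0
    n_dirs = C + 1 if need_shared else C
    if need_shared and L < n_dirs:
        raise ValueError(
            f"correlated patterns (separation {min_separation}) need at least "
            f"{n_dirs} channels for {C} classes"
        )
    rng = np.random.default_rng(seed)
    gauss = rng.standard_normal((L, n_dirs))
    q, r = np.linalg.qr(gauss)
    q *= np.sign(np.diag(r))  # fix the sign convention -> deterministic
    if not need_shared:
        return q[:, :C]
    shared = q[:, C]
    beta = np.sqrt(rho)
    topo = np.sqrt(1.0 - rho) * q[:, :C] + beta * shared[:, None]
    return topo


def _pink_noise(
    rng: np.random.Generator, L: int, n: int, alpha: float, fs: float
) -> np.ndarray:
    """Spatially independent 1/f^alpha Gaussian noise, unit variance per row."""
    n_bins = n // 2 + 1
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # clamp below 1 Hz so the spectrum does not diverge at DC
    shaped = np.maximum(f, 1.0) ** (-alpha / 2.0)
    shaped[0] = 0.0
    spec = (
        rng.standard_normal((L, n_bins)) + 1j * rng.standard_normal((L, n_bins))
    ) * shaped
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _mixing_matrix(config: SynthConfig) -> np.ndarray:
    """Session-fixed orthogonal spatial mixing of the noise sources."""
    rng = np.random.default_rng([config.seed, 1])
    q, r = np.linalg.qr(rng.standard_normal((config.n_channels, config.n_channels)))
    return q * np.sign(np.diag(r))


_CAL_CACHE: dict[tuple, tuple[float, float]] = {}


def _calibration(config: SynthConfig, n: int) -> tuple[float, float]:
    """(noise band power, unit-tone bin power) under the snr_60hz estimator.

    Both are channel-averaged periodogram quantities at the estimator's
    0.25 Hz bin alignment; the noise term is a small seeded Monte-Carlo
    average (deterministic for a fixed config).
    """
    key = (
        config.n_channels,
        config.f_stim,
        config.f_sample,
        config.noise_exponent,
        config.noise_scale,
        config.seed,
        n,
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    t = np.arange(n) / config.f_sample
    tone = np.sin(2 * np.pi * config.f_stim * t)[None, :]
    sig_bin, _ = band_periodogram_powers(tone, config.f_sample, config.f_stim)
    if config.noise_scale == 0:
        result = (0.0, float(sig_bin))
    else:
        rng = np.random.default_rng([config.seed, 2])
        mix = _mixing_matrix(config)
        band = []
        for _ in range(4):
            noise = config.noise_scale * (
                mix @ _pink_noise(rng, config.n_channels, n, config.noise_exponent,
                                  config.f_sample)
            )
            _, noise_band = band_periodogram_powers(noise, config.f_sample, config.f_stim)
            band.append(noise_band)
        result = (float(np.mean(band)), float(sig_bin))
    _CAL_CACHE[key] = result
    return result


def _tone_gain(config: SynthConfig, n: int) -> float:
    """Tone amplitude realizing the configured narrow-band SNR."""
    p_noise, p_tone = _calibration(config, n)
    if config.noise_scale == 0:
        return 1.0  # noiseless: unit amplitude, SNR is infinite anyway
    excess = max(config.snr - 1.0, 0.0)  # estimator noise floor is ~1
    if excess == 0 or p_tone == 0:
        return 0.0
    mean_sq_amp = np.exp(config.amp_jitter**2)  # E[a^2] of the lognormal jitter
    return float(
        np.sqrt(excess * config.n_channels * p_noise / (p_tone * mean_sq_amp))
    )


def simulate_trial(
    class_label: int,
    duration: float,
    config: SynthConfig,
    topographies: np.ndarray,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Simulate one trial of gazing at target ``class_label`` (1-based).

    The SSVEP component is ``a * sin(2*pi*f_stim*t + phi)`` projected through
    the class topography, with per-trial lognormal amplitude jitter ``a``
    (mean 1) and Gaussian phase jitter ``phi``; background is spatially mixed
    1/f^alpha noise.
    """
    C = config.n_classes
    if not 1 <= class_label <= C:
        raise ValueError(f"class_label must be in 1..{C}")
    if duration < 1.0 / config.f_stim:
        raise ValueError("duration shorter than one stimulation cycle")
    topographies = np.asarray(topographies, dtype=float)
    if topographies.shape != (config.n_channels, C):
        raise ValueError("topographies shape must be (n_channels, n_classes)")
    if rng is None:
        rng = config.rng()
    n = int(round(duration * config.f_sample))
    t = np.arange(n) / config.f_sample
    phi = config.phase_jitter * rng.standard_normal()
    amp = np.exp(config.amp_jitter * rng.standard_normal() - config.amp_jitter**2 / 2)
    gain = _tone_gain(config, n)
    tone = gain * amp * np.sin(2 * np.pi * config.f_stim * t + phi)
    data = topographies[:, class_label - 1][:, None] * tone[None, :]
    if config.noise_scale > 0:
        noise = _pink_noise(rng, config.n_channels, n, config.noise_exponent,
                            config.f_sample)
        data = data + config.noise_scale * (_mixing_matrix(config) @ noise)
    return Recording(data, config.f_sample)


def simulate_session(
    n_sequences: int,
    trial_duration: float,
    config: SynthConfig,
    topographies: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TrialSet:
    """Simulate a session of ``n_sequences`` sequences.

    Each sequence visits every target exactly once in randomized order, as in
    the cued training protocol, so the resulting ``C * n_sequences`` trials
    are perfectly class-balanced.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if topographies is None:
        topographies = make_topographies(
            config.n_channels, config.n_classes, seed=config.seed
        )
    if rng is None:
        rng = config.rng()
    C = config.n_classes
    n_samples = int(round(trial_duration * config.f_sample))
    data = np.empty((C * n_sequences, config.n_channels, n_samples))
    labels, seq_ids = [], []
    i = 0
    for s in range(n_sequences):
        order = rng.permutation(C) + 1
        for label in order:
            rec = simulate_trial(int(label), trial_duration, config, topographies, rng)
            data[i] = rec.data
            labels.append(int(label))
            seq_ids.append(s)
            i += 1
    return TrialSet(
        data,
        np.array(labels),
        config.f_sample,
        sequence=np.array(seq_ids),
        meta={"config": config.to_dict()},
    )


def chunk_stream(recording: Recording, chunk_samples: int = 131) -> Iterator[np.ndarray]:
    """Replay a recording as the amplifier would deliver it.

    Yields consecutive non-overlapping ``channels x chunk_samples`` blocks; a
    trailing partial chunk is withheld, matching amplifier behaviour (data
    arrive only in whole chunks).
    """
    if chunk_samples < 1:
        raise ValueError("chunk_samples must be >= 1")
    n_full = recording.n_samples // chunk_samples
    for k in range(n_full):
        yield recording.data[:, k * chunk_samples : (k + 1) * chunk_samples]
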