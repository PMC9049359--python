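"""File formats: native columnar sessions, EDF/BDF ingest, model containers.

The native interchange format is a plain columnar numeric file (one column
per channel, one row per sample) with a JSON sidecar carrying the sampling
rate, trial labels and boundaries, and the generating configuration.  It is
lossless at the stated precision, which EDF's 16-bit quantization is not;
EDF/BDF (the amplifier's native exports) are supported at the boundary,
read-only, through :mod:`mne`.

Trained models (the per-window-length cache of CCA filter banks and LDAs)
serialize to a single versioned JSON container.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import Recording, TrialSet
from .cca import CCAFilterBank
from .lda import GaussianLDA
from .dynstop import DynamicStoppingClassifier

__all__ = [
    "write_session",
    "read_session",
    "read_recording",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_session(trials: TrialSet, path) -> Path:
    """Write a session as ``<path>.csv`` plus a ``<path>.json`` sidecar."""
    path = Path(path).with_suffix(".csv")
    flat = trials.data.transpose(0, 2, 1).reshape(-1, trials.n_channels)
    header = ",".join(f"ch{i+1}" for i in range(trials.n_channels))
    np.savetxt(path, flat, fmt="%.10e", delimiter=",", header=header, comments="")
    boundaries = [
        [i * trials.n_samples, (i + 1) * trials.n_samples]
        for i in range(trials.n_trials)
    ]
    sidecar = {
        "fs": trials.fs,
        "n_channels": trials.n_channels,
        "n_samples_total": int(trials.n_trials * trials.n_samples),
        "labels": trials.labels.tolist(),
        "trial_boundaries": boundaries,
        "sequence": None if trials.sequence is None else trials.sequence.tolist(),
        "meta": trials.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path) -> TrialSet:
    """Read a native session written by :func:`write_session`."""
    path = Path(path).with_suffix(".csv")
    sidecar = json.loads(_sidecar_path(path).read_text())
    flat = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if flat.shape != (sidecar["n_samples_total"], sidecar["n_channels"]):
        raise ValueError(
            f"{path}: data shape {flat.shape} does not match sidecar "
            f"({sidecar['n_samples_total']} x {sidecar['n_channels']}); "
            "truncated or corrupt file"
        )
    trials = [flat[a:b].T for a, b in sidecar["trial_boundaries"]]
    seq = sidecar.get("sequence")
    return TrialSet(
        np.stack(trials),
        np.asarray(sidecar["labels"]),
        sidecar["fs"],
        sequence=None if seq is None else np.asarray(seq),
        meta=sidecar.get("meta", {}),
    )


def read_recording(path, fs: float | None = None) -> Recording:
    """Read a continuous multichannel recording.

    ``.edf``/``.bdf`` files are parsed with :mod:`mne`; native columnar
    files need their JSON sidecar (or an explicit ``fs``).  A sampling rate
    that contradicts a required ``fs`` is a hard error, never silently
    resampled.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_edf if suffix == ".edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        rec = Recording(raw.get_data(), float(raw.info["sfreq"]),
                        list(raw.ch_names))
    else:
        file_fs = fs
        sidecar_file = _sidecar_path(path)
        expected = None
        if sidecar_file.exists():
            sidecar = json.loads(sidecar_file.read_text())
            file_fs = sidecar["fs"]
            expected = (sidecar.get("n_samples_total"), sidecar.get("n_channels"))
        if file_fs is None:
            raise ValueError(f"{path}: no JSON sidecar and no fs given")
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if expected is not None and expected[0] is not None:
            if data.shape != tuple(expected):
                raise ValueError(f"{path}: truncated or corrupt file")
        rec = Recording(data.T, file_fs)
    if fs is not None and abs(rec.fs - fs) > 1e-9:
        raise ValueError(
            f"{path}: file sampling rate {rec.fs} Hz contradicts the "
            f"configured {fs} Hz"
        )
    return rec


def _lda_to_dict(model: GaussianLDA) -> dict:
    return {
        "classes": model.classes_.tolist(),
        "means": model.means_.tolist(),
        "covariance": model.covariance_.tolist(),
        "priors": model.priors_.tolist(),
        "shrinkage": model.shrinkage_,
    }


def _lda_from_dict(d: dict) -> GaussianLDA:
    model = GaussianLDA()
    model.classes_ = np.asarray(d["classes"])
    model.means_ = np.asarray(d["means"])
    model.covariance_ = np.asarray(d["covariance"])
    model.priors_ = np.asarray(d["priors"])
    model.shrinkage_ = d["shrinkage"]
    model._chol = np.linalg.cholesky(model.covariance_)
    return model


def save_model(clf: DynamicStoppingClassifier, path) -> Path:
    """Serialize a fitted dynamic-stopping model cache to JSON."""
    path = Path(path)
    entries = {}
    for w, (bank, model) in clf.models_.items():
        entries[str(w)] = {
            "A": {str(c): a.tolist() for c, a in bank.A_.items()},
            "B": {str(c): b.tolist() for c, b in bank.B_.items()},
            "correlations": {str(c): r.tolist() for c, r in bank.correlations_.items()},
            "lda": _lda_to_dict(model),
        }
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": clf.get_params(),
        "classes": clf.classes_.tolist(),
        "n_channels": clf.n_channels_,
        "lengths": clf.lengths_,
        "filter_coeffs": clf.coeffs_.tolist(),
        "models": entries,
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> DynamicStoppingClassifier:
    """Load a model container written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model container version in {path}")
    params = payload["params"]
    params["band"] = tuple(params["band"])
    clf = DynamicStoppingClassifier(**params)
    clf.classes_ = np.asarray(payload["classes"])
    clf.n_channels_ = payload["n_channels"]
    clf.lengths_ = list(payload["lengths"])
    clf.coeffs_ = np.asarray(payload["filter_coeffs"])
    clf.models_ = {}
    for w_str, entry in payload["models"].items():
        bank = CCAFilterBank(f_stim=clf.f_stim, f_sample=clf.f_sample,
                             feature_mode=clf.feature_mode)
        bank.classes_ = clf.classes_
        bank.n_channels_ = clf.n_channels_
        bank.window_len_ = int(w_str)
        bank.A_ = {int(c): np.asarray(a) for c, a in entry["A"].items()}
        bank.B_ = {int(c): np.asarray(b) for c, b in entry["B"].items()}
        bank.correlations_ = {
            int(c): np.asarray(r) for c, r in entry["correlations"].items()
        }
        clf.models_[int(w_str)] = (bank, _lda_from_dict(entry["lda"]))
    return clf
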