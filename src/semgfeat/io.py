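"""Readers and writers for MAT-style recording containers and feature tables.

The on-disk recording dialect follows the convention of public sEMG
benchmark releases: a MAT file with an ``emg`` signal matrix and
per-sample ``stimulus``/``repetition`` label vectors, where relabeled
variants (``restimulus``/``rerepetition``, aligned to the actual
movement rather than the on-screen cue) are preferred when present.
Sampling rate is not stored uniformly in such files, so the reader
accepts it as an argument and only falls back to a ``sampling_rate``
field when the file carries one (files written by this package do).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import loadmat, savemat

from .core import EMGRecording
from .engine import FeatureMatrix

__all__ = [
    "RecordingFileDialect",
    "read_recording",
    "write_recording",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class RecordingFileDialect:
    """Field-name resolution rules for a recording container."""

    signal_field: str = "emg"
    stimulus_fields: tuple[str, ...] = ("restimulus", "stimulus")
    repetition_fields: tuple[str, ...] = ("rerepetition", "repetition")

    @classmethod
    def raw_labels(cls) -> "RecordingFileDialect":
        """Prefer the original (cue-aligned) labels over relabeled ones."""
        return cls(
            stimulus_fields=("stimulus", "restimulus"),
            repetition_fields=("repetition", "rerepetition"),
        )


def _pick_field(mat: dict, candidates: tuple[str, ...], path) -> np.ndarray:
    for name in candidates:
        if name in mat:
            return np.asarray(mat[name]).squeeze()
    available = sorted(k for k in mat if not k.startswith("__"))
    raise ValueError(
        f"{path}: none of the fields {candidates} present; available: {available}"
    )


def read_recording(
    path,
    dialect: RecordingFileDialect = RecordingFileDialect(),
    sampling_rate: float | None = None,
) -> EMGRecording:
    """Load an :class:`EMGRecording` from a MAT container.

    ``sampling_rate`` overrides any rate stored in the file; one of the
    two must be available.
    """
    path = Path(path)
    try:
        mat = loadmat(path)
    except NotImplementedError:
        import h5py  # HDF5-based MAT (v7.3)

        with h5py.File(path, "r") as f:
            mat = {k: np.asarray(f[k]).T for k in f.keys()}
    if RecordingFileDialect().signal_field not in mat and dialect.signal_field not in mat:
        available = sorted(k for k in mat if not k.startswith("__"))
        raise ValueError(
            f"{path}: signal field {dialect.signal_field!r} missing; "
            f"available fields: {available}"
        )
    signal = np.atleast_2d(np.asarray(mat[dialect.signal_field], dtype=np.float64))
    stimulus = _pick_field(mat, dialect.stimulus_fields, path)
    repetition = _pick_field(mat, dialect.repetition_fields, path)
    for name, vec in (("stimulus", stimulus), ("repetition", repetition)):
        if vec.size != signal.shape[0]:
            raise ValueError(
                f"{path}: {name} length {vec.size} != signal rows {signal.shape[0]}"
            )
    if sampling_rate is None:
        if "sampling_rate" in mat:
            sampling_rate = float(np.asarray(mat["sampling_rate"]).squeeze())
        else:
            raise ValueError(
                f"{path}: file stores no sampling_rate; pass sampling_rate="
            )
    return EMGRecording(
        signal=signal,
        stimulus=stimulus.astype(np.int64),
        repetition=repetition.astype(np.int64),
        sampling_rate=sampling_rate,
    )


def write_recording(rec: EMGRecording, path) -> None:
    """Write a recording as a version-5 MAT container (lossless)."""
    savemat(
        Path(path),
        {
            "emg": rec.signal,
            "stimulus": rec.stimulus[:, None],
            "repetition": rec.repetition[:, None],
            "sampling_rate": np.array([[rec.sampling_rate]]),
        },
    )


def _csv_header(fm: FeatureMatrix) -> list[str]:
    per_channel, n_channels = fm.column_layout
    cols = [
        f"{fm.feature_name}_ch{c:02d}_v{v:02d}"
        for c in range(n_channels)
        for v in range(per_channel)
    ]
    return cols + ["stim", "rep"]


def write_features(fm: FeatureMatrix, path, format: str = "mat") -> None:
    """Write a feature matrix with its aligned label vectors.

    ``mat`` and ``npz`` are lossless binary formats storing arrays
    ``feat``/``featStim``/``featRep``; ``csv`` is a single-header text
    table whose columns are the channel-major feature values followed by
    ``stim`` and ``rep``.
    """
    path = Path(path)
    if format == "mat":
        savemat(
            path,
            {
                "feat": fm.feat.reshape(fm.feat.shape[0], -1) if fm.feat.size else fm.feat,
                "featStim": fm.featStim[:, None],
                "featRep": fm.featRep[:, None],
                "feature_name": fm.feature_name,
                "column_layout": np.array([fm.column_layout]),
            },
        )
    elif format == "npz":
        np.savez(
            path,
            feat=fm.feat,
            featStim=fm.featStim,
            featRep=fm.featRep,
            feature_name=fm.feature_name,
            column_layout=np.array(fm.column_layout),
        )
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_csv_header(fm))
            for row, s, r in zip(fm.feat, fm.featStim, fm.featRep):
                writer.writerow([repr(float(v)) for v in row] + [int(s), int(r)])
    else:
        raise ValueError(f"unknown format {format!r}; use mat, npz or csv")


def read_features(path) -> FeatureMatrix:
    """Load a feature matrix written by :func:`write_features` (mat/npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path, allow_pickle=False)
        name = str(data["feature_name"])
        layout = tuple(int(v) for v in data["column_layout"])
        feat = data["feat"]
        stim = data["featStim"]
        rep = data["featRep"]
    else:
        mat = loadmat(path)
        name = str(np.asarray(mat["feature_name"]).squeeze())
        layout = tuple(int(v) for v in np.asarray(mat["column_layout"]).squeeze())
        feat = np.atleast_2d(mat["feat"])
        stim = np.asarray(mat["featStim"]).squeeze()
        rep = np.asarray(mat["featRep"]).squeeze()
    stim = np.atleast_1d(stim).astype(np.int64)
    rep = np.atleast_1d(rep).astype(np.int64)
    if feat.shape[0] != stim.size:  # 0-row matrices load as (1, 0) or (0, n)
        feat = feat.reshape(stim.size, -1)
    return FeatureMatrix(
        feat=np.asarray(feat, dtype=np.float64),
        featStim=stim,
        featRep=rep,
        feature_name=name,
        column_layout=(layout[0], layout[1]),
    )
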