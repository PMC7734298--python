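"""Cohort file handling, optional bandpass filtering, and run logs.

On-disk contract: a cohort is a manifest TSV with columns
``subject_id, class, path`` plus one delimited series file per subject
(T rows x R columns, header row of region labels, identical shape and
label order across subjects).  Paths in the manifest are resolved relative
to the manifest's directory.  ROI indices in all outputs are 1-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .classify import ClassTensor

__all__ = ["load_series", "load_cohort", "zscore_series", "bandpass", "write_run_log"]


def load_series(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read one subject's T x R ROI series table; returns (data, region labels)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"series file {path} contains non-finite values")
    return data, [str(c) for c in df.columns]


def zscore_series(X: np.ndarray) -> np.ndarray:
    """Standardize each ROI time series (column) to mean 0, sd 1.

    BOLD amplitudes are not comparable across subjects, and the classifier's
    Frobenius-norm reconstruction errors are scale-sensitive; constant
    columns are left centered.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def load_cohort(
    manifest_path: str | Path, *, zscore: bool = False
) -> list[ClassTensor]:
    """Load a manifest into one ClassTensor per class (first-appearance order).

    Sample order within each class follows manifest order.  Shape or
    region-label inconsistencies raise an error naming the offending subject.
    """
    manifest_path = Path(manifest_path)
    mf = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "class", "path"}
    if not required.issubset(mf.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if mf["subject_id"].duplicated().any():
        dupes = mf.loc[mf["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")

    base = manifest_path.parent
    ref_labels: list[str] | None = None
    ref_shape: tuple[int, int] | None = None
    by_class: dict[str, list[tuple[str, np.ndarray]]] = {}
    for row in mf.itertuples(index=False):
        data, labels = load_series(base / row.path)
        if ref_labels is None:
            ref_labels, ref_shape = labels, data.shape
        elif data.shape != ref_shape:
            raise ValueError(
                f"subject {row.subject_id!r}: series shape {data.shape} does not "
                f"match the cohort shape {ref_shape}"
            )
        elif labels != ref_labels:
            raise ValueError(
                f"subject {row.subject_id!r}: region labels differ from the cohort's"
            )
        if zscore:
            data = zscore_series(data)
        by_class.setdefault(row._1, []).append((row.subject_id, data))

    classes = []
    for label, members in by_class.items():
        ids = [sid for sid, _ in members]
        data = np.stack([d for _, d in members], axis=2)
        classes.append(ClassTensor(data, label, ids, ref_labels))
    return classes


def bandpass(
    series: np.ndarray,
    low_hz: float,
    high_hz: float,
    tr_seconds: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of each ROI column.

    Typical rs-fMRI use keeps the 0.01-0.08 Hz band.  ``low_hz = 0`` gives a
    pure low-pass.  Forward-backward filtering keeps phases intact so the
    classifier is insensitive to filter-induced time shifts.
    """
    X = np.asarray(series, dtype=float)
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    if not 0 <= low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz: need 0 <= low < high < "
            f"Nyquist ({nyq:.4g} Hz for TR={tr_seconds}s)"
        )
    if low_hz == 0:
        sos = _signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    else:
        sos = _signal.butter(
            order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
        )
    return _signal.sosfiltfilt(sos, X, axis=0)


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_log(
    out_path: str | Path,
    command: str,
    params: dict,
    input_files: list[str | Path] = (),
) -> Path:
    """Machine-readable run log: command, parameters, input hashes, package version.

    Deliberately contains no timestamps so reruns with the same seed and
    configuration are byte-identical.
    """
    from . import __version__

    log = {
        "command": command,
        "version": __version__,
        "params": {k: params[k] for k in sorted(params)},
        "inputs": {str(p): _file_sha256(Path(p)) for p in input_files},
    }
    out_path = Path(out_path)
    out_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
    return out_path
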