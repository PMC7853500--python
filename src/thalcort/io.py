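"""Evoked-response dataset container and its on-disk dialect.

A dataset holds per-subject, per-condition source-level waveforms on a shared
time grid (conditions ordered pre, early-post, late-post).  On disk it is a
JSON metadata sidecar (``<name>.json``, schema ``evoked.dataset.v1``) plus an
array payload (``<name>.npz``); a plain-CSV import path exists for
interoperability with other tools.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observation import CONDITION_LABELS

__all__ = ["EvokedDataset", "read_dataset", "write_dataset", "import_csv", "config_hash"]

_SCHEMA = "evoked.dataset.v1"


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class EvokedDataset:
    """Per-subject, per-condition waveforms with sampling metadata.

    ``waveforms`` is (n_subjects, n_conditions, n_time); all subjects share
    the sampling rate ``fs`` (Hz) and time origin ``t0`` (ms).
    """

    subject_ids: tuple
    waveforms: np.ndarray
    fs: float = 1000.0
    t0: float = 0.0
    condition_labels: tuple = CONDITION_LABELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        self.subject_ids = tuple(self.subject_ids)
        self.condition_labels = tuple(self.condition_labels)
        if self.waveforms.ndim != 3:
            raise ValueError("waveforms must be (n_subjects, n_conditions, n_time)")
        if len(self.subject_ids) != self.waveforms.shape[0]:
            raise ValueError("subject_ids length must match waveforms")
        if len(self.condition_labels) != self.waveforms.shape[1]:
            raise ValueError("condition_labels length must match waveforms")
        unknown = set(self.condition_labels) - set(CONDITION_LABELS)
        if unknown:
            raise ValueError(f"unknown condition labels {sorted(unknown)}")
        if not np.all(np.isfinite(self.waveforms)):
            raise ValueError("waveforms must be finite")

    @property
    def n_subjects(self) -> int:
        return self.waveforms.shape[0]

    @property
    def t_grid(self) -> np.ndarray:
        n_t = self.waveforms.shape[2]
        return self.t0 + np.arange(n_t) * 1000.0 / self.fs

    def subject(self, i: int) -> np.ndarray:
        return self.waveforms[i]


def write_dataset(ds: EvokedDataset, path) -> Path:
    """Write the JSON sidecar and npz payload; returns the JSON path."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    npz_path = path.with_suffix(".npz")
    meta = {
        "schema": _SCHEMA,
        "fs": ds.fs,
        "t0": ds.t0,
        "condition_labels": list(ds.condition_labels),
        "subjects": [
            {"id": sid, "fs": ds.fs, "t0": ds.t0,
             "condition_labels": list(ds.condition_labels)}
            for sid in ds.subject_ids
        ],
        "array_file": npz_path.name,
        "provenance": ds.provenance,
    }
    path.write_text(json.dumps(meta, indent=1))
    np.savez(npz_path, waveforms=ds.waveforms)
    return path


def _schema_error(pointer: str, message: str):
    raise ValueError(f"dataset schema violation at {pointer}: {message}")


def read_dataset(path) -> EvokedDataset:
    """Read and validate a dataset; exact inverse of :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = json.loads(path.read_text())
    if meta.get("schema") != _SCHEMA:
        _schema_error("/schema", f"expected {_SCHEMA!r}, got {meta.get('schema')!r}")
    for key in ("fs", "subjects", "array_file", "condition_labels"):
        if key not in meta:
            _schema_error(f"/{key}", "missing required field")
    subjects = meta["subjects"]
    for k, rec in enumerate(subjects[1:], start=1):
        if rec.get("fs") != subjects[0].get("fs") or rec.get("t0") != subjects[0].get("t0"):
            _schema_error(
                f"/subjects/{k}/fs",
                f"time grid of subject {rec.get('id')!r} differs from subject "
                f"{subjects[0].get('id')!r}; all subjects must share one grid",
            )
    arrays = np.load(path.parent / meta["array_file"])
    return EvokedDataset(
        subject_ids=[rec["id"] for rec in subjects],
        waveforms=arrays["waveforms"],
        fs=meta["fs"],
        t0=meta.get("t0", 0.0),
        condition_labels=tuple(meta["condition_labels"]),
        provenance=meta.get("provenance", {}),
    )


def import_csv(paths, fs: float, subject_ids=None, t0: float = 0.0,
               provenance: dict | None = None) -> EvokedDataset:
    """Build a dataset from per-subject CSV tables.

    Each CSV holds one column per condition (named as in
    ``CONDITION_LABELS``); an optional ``time`` column is ignored for the
    values but checked against ``fs``.  Sample count = duration x rate.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    waves = []
    for p in paths:
        df = pd.read_csv(p)
        if "time" in df.columns:
            t = df["time"].to_numpy(dtype=float)
            if len(t) > 1 and not np.allclose(np.diff(t), 1000.0 / fs):
                _schema_error(f"/{Path(p).name}/time", f"time step inconsistent with fs={fs}")
            df = df.drop(columns="time")
        missing = [c for c in CONDITION_LABELS if c not in df.columns]
        if missing:
            _schema_error(f"/{Path(p).name}", f"missing condition columns {missing}")
        waves.append(df[list(CONDITION_LABELS)].to_numpy(dtype=float).T)
    if subject_ids is None:
        subject_ids = [Path(p).stem for p in paths]
    return EvokedDataset(
        subject_ids=subject_ids, waveforms=np.stack(waves), fs=fs, t0=t0,
        provenance=provenance or {"import_source": [str(p) for p in paths]},
    )
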