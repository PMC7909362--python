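"""Reading and writing 12-lead ECG recordings and clinical covariate tables.

The canonical on-disk layout is a wide CSV (one column per lead, samples in
microvolts) with a JSON sidecar carrying the sampling rate, the recording
mode label and beat annotations.  A minimal plain-text "wfdb-like" dialect
(text header + whitespace-separated ASCII sample matrix) is also supported
so that converted study files can be ingested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical lead order of a standard 12-lead ECG.
LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The four recording modes of the study protocol: atrial-paced
#: ventricular-sensed (AAI) and atrial-paced ventricular-paced (DDD),
#: each on study day 1 and day 7.
MODE_LABELS = ("AAI-1", "DDD-1", "AAI-7", "DDD-7")

#: Beat classes; only ``normal`` beats enter the median beat.
BEAT_CLASSES = ("normal", "ectopic", "fusion", "artifact")


class EcgFormatError(ValueError):
    """Raised when an on-disk recording violates the 12-lead contract."""


class CovariateSchemaError(ValueError):
    """Raised when the covariate table is missing or violates its schema."""


@dataclass
class Ecg12Lead:
    """A raw 12-lead ECG recording.

    Parameters
    ----------
    samples
        Array of shape ``(12, n_samples)`` in microvolts, rows ordered as
        :data:`LEAD_NAMES`.
    fs
        Sampling rate in Hz.
    mode_label
        One of :data:`MODE_LABELS` (or ``""`` when unknown).
    beat_annotations
        List of ``(sample_index, beat_class)`` tuples, strictly increasing
        sample indices.  Empty when beats have not been labeled.
    """

    samples: np.ndarray
    fs: float
    mode_label: str = ""
    beat_annotations: list[tuple[int, str]] = field(default_factory=list)
    lead_names: tuple[str, ...] = LEAD_NAMES
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise EcgFormatError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[0] != 12:
            raise EcgFormatError(
                f"expected 12 leads, got array of shape {self.samples.shape}"
            )
        n = self.samples.shape[1]
        if n < 2 * self.fs:
            raise EcgFormatError(
                f"recording too short: {n} samples < 2 s at {self.fs} Hz"
            )
        if tuple(self.lead_names) != LEAD_NAMES:
            raise EcgFormatError(
                f"leads must be in canonical order {LEAD_NAMES}, got {self.lead_names}"
            )
        idx = [i for i, _ in self.beat_annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise EcgFormatError("beat annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= n):
            raise EcgFormatError("beat annotation index out of range")
        for _, cls in self.beat_annotations:
            if cls not in BEAT_CLASSES:
                raise EcgFormatError(f"unknown beat class {cls!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def lead(self, name: str) -> np.ndarray:
        return self.samples[LEAD_NAMES.index(name)]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_ecg(ecg: Ecg12Lead, path: str | Path) -> None:
    """Write a recording as wide CSV plus JSON sidecar (lossless)."""
    path = Path(path)
    df = pd.DataFrame(ecg.samples.T, columns=list(LEAD_NAMES))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": ecg.fs,
        "mode_label": ecg.mode_label,
        "patient_id": ecg.patient_id,
        "units": "uV",
        "beat_annotations": [[int(i), c] for i, c in ecg.beat_annotations],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_ecg(path: str | Path, dialect: str = "csv-wide") -> Ecg12Lead:
    """Read a recording from disk.

    Parameters
    ----------
    path
        CSV file (``csv-wide``) or text header file (``wfdb-like``).
    dialect
        ``"csv-wide"`` (canonical) or ``"wfdb-like"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ECG file not found: {path}")
    if dialect == "csv-wide":
        return _read_csv_wide(path)
    if dialect == "wfdb-like":
        return _read_wfdb_like(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_wide(path: Path) -> Ecg12Lead:
    df = pd.read_csv(path, float_precision="round_trip")
    found = list(df.columns)
    missing = [l for l in LEAD_NAMES if l not in found]
    if missing:
        raise EcgFormatError(
            f"{path}: expected 12 leads, missing {missing}; found {found}"
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise EcgFormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    samples = df[list(LEAD_NAMES)].to_numpy(dtype=float).T
    if meta.get("units", "uV") == "mV":
        samples = samples * 1000.0
    anns = [(int(i), str(c)) for i, c in meta.get("beat_annotations", [])]
    return Ecg12Lead(
        samples=samples,
        fs=float(meta["fs"]),
        mode_label=meta.get("mode_label", ""),
        beat_annotations=anns,
        patient_id=meta.get("patient_id", ""),
    )


def _read_wfdb_like(path: Path) -> Ecg12Lead:
    """Plain-text variant of a signal+header pair.

    Header (``.hea``-style text): first line ``<record> <n_sig> <fs>
    <n_samples>``; following lines one lead name each.  Samples live in
    ``<record>.asc`` as a whitespace-separated matrix (rows = samples,
    columns = leads) in microvolts.
    """
    header = path.read_text().splitlines()
    first = header[0].split()
    record, n_sig, fs = first[0], int(first[1]), float(first[2])
    names = [ln.split()[0] for ln in header[1 : 1 + n_sig]]
    sig_path = path.parent / f"{record}.asc"
    if not sig_path.exists():
        raise EcgFormatError(f"{path}: missing signal file {sig_path.name}")
    mat = np.loadtxt(sig_path)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[1] != n_sig or n_sig != 12:
        raise EcgFormatError(
            f"{path}: expected 12 leads, found {n_sig} ({names})"
        )
    order = [names.index(l) for l in LEAD_NAMES if l in names]
    missing = [l for l in LEAD_NAMES if l not in names]
    if missing:
        raise EcgFormatError(f"{path}: missing leads {missing}")
    return Ecg12Lead(samples=mat[:, order].T, fs=fs, mode_label="", patient_id=record)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

#: Columns required of a covariate table (one row per patient).
COVARIATE_COLUMNS = (
    "patient_id", "age", "female", "history_MI", "history_NSVT",
    "history_sustained_VT", "LVEF", "diabetes", "hypertension",
    "ACEi_ARB", "classIII_AA",
)

_BINARY_COLUMNS = (
    "female", "history_MI", "history_NSVT", "history_sustained_VT",
    "diabetes", "hypertension", "ACEi_ARB", "classIII_AA",
)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical covariate table.

    Sex is coded with female as the indicator (column ``female``); a
    ``sex`` column with values {female, male} is accepted and recoded.
    """
    df = pd.read_csv(path)
    if "sex" in df.columns and "female" not in df.columns:
        df["female"] = (df["sex"].astype(str).str.lower() == "female").astype(int)
        df = df.drop(columns=["sex"])
    return validate_covariates(df)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise CovariateSchemaError(f"covariate table missing columns: {missing}")
    df = df[list(COVARIATE_COLUMNS)].copy()
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise CovariateSchemaError(f"duplicated patient ids: {dups}")
    if df[list(COVARIATE_COLUMNS[1:])].isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise CovariateSchemaError(f"missing values in columns: {bad}")
    lvef = df["LVEF"].to_numpy(dtype=float)
    if np.any((lvef <= 0) | (lvef >= 100)):
        raise CovariateSchemaError("LVEF must lie strictly between 0 and 100%")
    for c in _BINARY_COLUMNS:
        vals = set(pd.unique(df[c].astype(int)))
        if not vals <= {0, 1}:
            raise CovariateSchemaError(f"column {c} must be 0/1, found {vals}")
        df[c] = df[c].astype(int)
    df["patient_id"] = df["patient_id"].astype(str)
    return df.set_index("patient_id", drop=False)


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
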