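"""Recording container, EDF read/write, feature tables and packaged fixtures.

EDF support is implemented here directly (plain EDF, 16-bit samples,
one-second data records) so that recordings can round-trip without any
third-party EDF dependency.  Subject/session/task metadata, which plain EDF
has no native fields for, is carried as ``key=value`` pairs in the
"local recording identification" header field.
"""

from __future__ import annotations

import io as _stdio
import struct
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Electrode labels of the 10-20-system montage used throughout the package.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
)

#: Default physical range (symmetric, µV) declared when writing EDF.
DEFAULT_PHYSICAL_RANGE_UV = 500.0

_EDF_DIGITAL_MAX = 32767


class EdfIOError(IOError):
    """Raised when an EDF file cannot be read or is malformed."""


@dataclass
class Recording:
    """A continuous multichannel EEG recording in µV.

    Attributes
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.
    fs:
        Sampling rate in Hz.
    channel_labels:
        One label per row of ``data``.
    subject_id, session_id, task_id:
        Cohort metadata; ``task_id`` is the attention-state label (1-4).
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    subject_id: str = "S00"
    session_id: int = 1
    task_id: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.task_id not in (1, 2, 3, 4):
            raise ValueError(f"task_id must be 1..4, got {self.task_id}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self, **changes) -> "Recording":
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)


def _pad_field(value, width: int) -> bytes:
    text = str(value)
    raw = text.encode("ascii", errors="replace")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def write_edf(recording: Recording, path) -> None:
    """Write a :class:`Recording` as a plain EDF file.

    Samples are quantized to 16 bits over a symmetric physical range that
    covers the data (at least ±`DEFAULT_PHYSICAL_RANGE_UV`).  The recording
    is stored in one-second data records; the final record is zero-padded
    and the true sample count is kept in the header so reads are exact.
    """
    fs = int(round(recording.fs))
    if abs(fs - recording.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_sig = recording.n_channels
    n_samples = recording.n_samples
    n_records = -(-n_samples // fs)  # ceil

    peak = float(np.max(np.abs(recording.data))) if n_samples else 0.0
    phys = max(DEFAULT_PHYSICAL_RANGE_UV, peak * 1.01)

    header = _stdio.BytesIO()
    header.write(_pad_field("0", 8))
    header.write(_pad_field(recording.subject_id, 80))
    rec_id = (
        f"task={recording.task_id} session={recording.session_id} "
        f"subject={recording.subject_id} nsamp={n_samples}"
    )
    header.write(_pad_field(rec_id, 80))
    header.write(_pad_field("01.01.00", 8))
    header.write(_pad_field("00.00.00", 8))
    header.write(_pad_field(256 * (1 + n_sig), 8))
    header.write(_pad_field("", 44))
    header.write(_pad_field(n_records, 8))
    header.write(_pad_field(1, 8))  # record duration, seconds
    header.write(_pad_field(n_sig, 4))

    for label in recording.channel_labels:
        header.write(_pad_field(label, 16))
    for _ in range(n_sig):
        header.write(_pad_field("AgAgCl electrode", 80))
    for _ in range(n_sig):
        header.write(_pad_field("uV", 8))
    for _ in range(n_sig):
        header.write(_pad_field(f"{-phys:.6g}", 8))
    for _ in range(n_sig):
        header.write(_pad_field(f"{phys:.6g}", 8))
    for _ in range(n_sig):
        header.write(_pad_field(-_EDF_DIGITAL_MAX, 8))
    for _ in range(n_sig):
        header.write(_pad_field(_EDF_DIGITAL_MAX, 8))
    for _ in range(n_sig):
        header.write(_pad_field("BP:0.5-30Hz", 80))
    for _ in range(n_sig):
        header.write(_pad_field(fs, 8))
    for _ in range(n_sig):
        header.write(_pad_field("", 32))

    padded = np.zeros((n_sig, n_records * fs), dtype=np.float64)
    padded[:, :n_samples] = recording.data
    digital = np.round(padded / phys * _EDF_DIGITAL_MAX)
    digital = np.clip(digital, -_EDF_DIGITAL_MAX, _EDF_DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())


def _parse_recording_id(text: str) -> dict:
    out = {}
    for token in text.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` (plain EDF, uV signals)."""
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:  # pragma: no cover - passthrough
        raise EdfIOError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise EdfIOError(f"malformed EDF file {path}: header truncated")

    def text(lo, hi):
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    subject_id = text(8, 88)
    meta = _parse_recording_id(text(88, 168))
    try:
        header_bytes = int(text(184, 192))
        n_records = int(text(236, 244))
        record_dur = float(text(244, 252))
        n_sig = int(text(252, 256))
    except ValueError as exc:
        raise EdfIOError(f"malformed EDF file {path}: bad header field") from exc
    if len(raw) < header_bytes or n_sig <= 0:
        raise EdfIOError(f"malformed EDF file {path}: inconsistent header")

    sig = raw[256:header_bytes]

    def sig_fields(offset, width, count=None):
        count = n_sig if count is None else count
        return [
            sig[offset + i * width : offset + (i + 1) * width]
            .decode("ascii", errors="replace")
            .strip()
            for i in range(count)
        ]

    # field order: label16 transducer80 dim8 pmin8 pmax8 dmin8 dmax8 prefilter80 nsamp8 reserved32
    labels = sig_fields(0, 16)
    off_pmin = n_sig * (16 + 80 + 8)
    off_pmax = off_pmin + n_sig * 8
    off_dmin = off_pmax + n_sig * 8
    off_dmax = off_dmin + n_sig * 8
    off_nsamp = off_dmax + n_sig * 8 + n_sig * 80
    try:
        pmin = [float(v) for v in sig_fields(off_pmin, 8)]
        pmax = [float(v) for v in sig_fields(off_pmax, 8)]
        dmin = [int(v) for v in sig_fields(off_dmin, 8)]
        dmax = [int(v) for v in sig_fields(off_dmax, 8)]
        spr = [int(v) for v in sig_fields(off_nsamp, 8)]
    except ValueError as exc:
        raise EdfIOError(f"malformed EDF file {path}: bad signal header") from exc

    if len(set(spr)) != 1:
        raise EdfIOError(f"unsupported EDF file {path}: mixed sampling rates")
    samples_per_record = spr[0]
    fs = samples_per_record / record_dur

    expected = header_bytes + n_records * n_sig * samples_per_record * 2
    if len(raw) < expected:
        raise EdfIOError(
            f"malformed EDF file {path}: expected {expected} bytes, got {len(raw)}"
        )

    body = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    body = body.reshape(n_records, n_sig, samples_per_record)
    digital = np.concatenate([body[r] for r in range(n_records)], axis=1).astype(
        np.float64
    )
    data = np.empty_like(digital)
    for i in range(n_sig):
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[i] = pmin[i] + (digital[i] - dmin[i]) * scale

    n_samples = int(meta.get("nsamp", data.shape[1]))
    data = data[:, :n_samples]
    return Recording(
        data=data,
        fs=fs,
        channel_labels=tuple(labels),
        subject_id=meta.get("subject", subject_id or "S00"),
        session_id=int(meta.get("session", 1)),
        task_id=int(meta.get("task", 1)),
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("label", "subject", "session")


def feature_column_names(
    channel_labels: Sequence[str] = DEFAULT_CHANNELS, n_features: int = 10
) -> list[str]:
    """Feature-major column names: F1 over all channels, then F2, ..."""
    return [
        f"F{k}_{ch}" for k in range(1, n_features + 1) for ch in channel_labels
    ]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV (lossless float round-trip)."""
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing metadata columns: {missing}")
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table at {path} missing column {col!r}")
    return table


# ---------------------------------------------------------------------------
# Packaged fixtures (printed tables)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedAccuracyTable:
    """Per-subject session-holdout accuracies before/after feature selection."""

    subjects: tuple[int, ...]
    accuracy_before: tuple[float, ...]
    accuracy_after: tuple[float, ...]

    def __post_init__(self):
        n = len(self.subjects)
        if len(self.accuracy_before) != n or len(self.accuracy_after) != n:
            raise ValueError("column length mismatch")
        for v in (*self.accuracy_before, *self.accuracy_after):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"accuracy {v} outside [0, 100]")

    @property
    def n(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class SfsStepTable:
    """Published sequential-forward-selection step log.

    ``candidate_order`` is the greedy visiting order; ``accuracies`` maps each
    evaluated subset (as a frozenset of group ids) to its validation accuracy
    in percent, so the table can serve as a deterministic subset evaluator.
    """

    candidate_order: tuple[str, ...]
    steps: tuple[tuple[str, tuple[str, ...], float, str], ...]
    accuracies: dict = field(default_factory=dict)

    def evaluator(self):
        """Return a subset -> accuracy%% lookup callable."""

        def evaluate(subset) -> float:
            key = frozenset(subset)
            if key not in self.accuracies:
                raise KeyError(f"subset {sorted(subset)} not in the step table")
            return self.accuracies[key]

        return evaluate


def _fixture_path(name: str):
    return resources.files("eegattn.fixtures").joinpath(name)


def load_table7_fixture() -> PairedAccuracyTable:
    """The 14 printed before/after per-subject accuracies."""
    df = pd.read_csv(_fixture_path("table7.csv"))
    return PairedAccuracyTable(
        subjects=tuple(int(s) for s in df["subject"]),
        accuracy_before=tuple(float(v) for v in df["accuracy_before"]),
        accuracy_after=tuple(float(v) for v in df["accuracy_after"]),
    )


def load_table6_fixture() -> SfsStepTable:
    """The printed SFS step log (candidate order, subset accuracies, flags)."""
    df = pd.read_csv(_fixture_path("table6.csv"))
    steps = []
    accuracies = {}
    for _, row in df.iterrows():
        subset = tuple(row["subset"].split(","))
        acc = float(row["accuracy_pct"])
        steps.append((row["newly_added"], subset, acc, row["retained"]))
        accuracies[frozenset(subset)] = acc
    return SfsStepTable(
        candidate_order=tuple(df["newly_added"]),
        steps=tuple(steps),
        accuracies=accuracies,
    )


def load_table5_fixture() -> dict:
    """Single-feature-group validation accuracies, as {group_id: accuracy%}."""
    df = pd.read_csv(_fixture_path("table5.csv"))
    return {row["group"]: float(row["accuracy_pct"]) for _, row in df.iterrows()}


def load_table4_fixture() -> pd.DataFrame:
    """Per-subject epoch counts for the four tasks (printed sample sizes)."""
    return pd.read_csv(_fixture_path("table4.csv"))
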