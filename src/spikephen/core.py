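"""Domain types, validation, ISI computation, and event/feature table I/O.

Event tables are UTF-8 delimited text (tab or comma, auto-detected from the
header line) with columns ``time_s``, ``amplitude``, ``spikelet_count``.
Per-cell metadata lives in a small YAML document with keys ``cell_id``,
``recording_duration_s``, ``group_label`` and ``genotype``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientDataError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Two event times closer than this are treated as duplicates (1 microsecond).
TIME_RESOLUTION_S = 1e-6

#: Recordings shorter than this are excluded from analysis.
MIN_RECORDING_DURATION_S = 75.0

#: Exact column order of the per-cell feature table.
FEATURE_TABLE_COLUMNS = [
    "cell_id",
    "group_label",
    "frequency_hz",
    "frequency_mode_hz",
    "cv",
    "cv2",
    "pause_percent",
    "rhythmicity_index",
    "cs_frequency_hz",
    "doublet_frequency_hz",
    "combined_cs_frequency_hz",
    "heterogeneous_cs",
]

EVENT_COLUMNS = ["time_s", "amplitude", "spikelet_count"]


@dataclass
class SpikeEventSeries:
    """An ordered per-cell spike-event record with metadata.

    Parameters
    ----------
    cell_id : str
        Unique identifier of the recorded cell.
    times_s : ndarray
        Strictly increasing event times in seconds, all within
        ``[0, recording_duration_s]``.
    amplitudes : ndarray
        Positive peak amplitudes (arbitrary units), one per event.
    spikelet_counts : ndarray
        Non-negative integer spikelet counts, one per event.
    recording_duration_s : float
        Total analyzed recording time in seconds (authoritative; taken
        from metadata, not inferred from the spike span).
    group_label : str
        Age/genotype group label, e.g. ``"control_P7-8"``.
    genotype : str
        Genotype string.
    """

    cell_id: str
    times_s: np.ndarray
    amplitudes: np.ndarray
    spikelet_counts: np.ndarray
    recording_duration_s: float
    group_label: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.spikelet_counts = np.asarray(self.spikelet_counts, dtype=int)
        self.validate()

    @property
    def n_events(self) -> int:
        return len(self.times_s)

    def validate(self) -> None:
        if not (self.recording_duration_s > 0):
            raise ValidationError(
                f"{self.cell_id}: recording_duration_s must be > 0, "
                f"got {self.recording_duration_s}"
            )
        n = len(self.times_s)
        if len(self.amplitudes) != n or len(self.spikelet_counts) != n:
            raise ValidationError(
                f"{self.cell_id}: times, amplitudes and spikelet counts must "
                "have equal length"
            )
        if n:
            diffs = np.diff(self.times_s)
            if np.any(diffs < TIME_RESOLUTION_S):
                bad = int(np.argmin(diffs))
                if diffs[bad] <= 0:
                    raise ValidationError(
                        f"{self.cell_id}: event times not strictly increasing "
                        f"at index {bad + 1}"
                    )
                raise ValidationError(
                    f"{self.cell_id}: duplicate event times (< 1 us apart) "
                    f"at index {bad + 1}"
                )
            if self.times_s[0] < 0 or self.times_s[-1] > self.recording_duration_s:
                raise ValidationError(
                    f"{self.cell_id}: event times must lie in "
                    f"[0, {self.recording_duration_s}]"
                )
            if np.any(self.amplitudes <= 0):
                raise ValidationError(f"{self.cell_id}: amplitudes must be > 0")
            if np.any(self.spikelet_counts < 0):
                raise ValidationError(
                    f"{self.cell_id}: spikelet counts must be >= 0"
                )


@dataclass
class ISISequence:
    """Successive interspike intervals of one train, in seconds."""

    isis_s: np.ndarray
    mean_isi_s: float
    n_spikes: int

    def __post_init__(self) -> None:
        self.isis_s = np.asarray(self.isis_s, dtype=float)


def compute_isis(times_s: Sequence[float]) -> ISISequence:
    """Successive differences of a strictly increasing spike-time sequence.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 times are given.
    ValidationError
        If the times are not strictly increasing.
    """
    times = np.asarray(times_s, dtype=float)
    if times.size < 2:
        raise InsufficientDataError(
            f"need >= 2 spike times to compute ISIs, got {times.size}"
        )
    isis = np.diff(times)
    if np.any(isis <= 0):
        raise ValidationError("spike times must be strictly increasing")
    return ISISequence(isis_s=isis, mean_isi_s=float(isis.mean()), n_spikes=times.size)


@dataclass
class DurationDecision:
    """Accept/reject outcome of the minimum-recording-length filter."""

    accepted: bool
    reason: str


def filter_by_duration(
    series: SpikeEventSeries, min_duration_s: float = MIN_RECORDING_DURATION_S
) -> DurationDecision:
    """Accept a cell iff its recording lasts at least ``min_duration_s``.

    The bound is inclusive: a recording of exactly ``min_duration_s``
    seconds is accepted.
    """
    dur = series.recording_duration_s
    if dur >= min_duration_s:
        decision = DurationDecision(
            True, f"{series.cell_id}: duration {dur:g} s >= {min_duration_s:g} s"
        )
    else:
        decision = DurationDecision(
            False, f"{series.cell_id}: duration {dur:g} s < {min_duration_s:g} s"
        )
    logger.debug("duration filter: %s", decision.reason)
    return decision


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _detect_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ParseError(f"cannot detect delimiter from header line: {header!r}")


def load_event_table(path: str | Path) -> pd.DataFrame:
    """Read an event table, validating header and per-row types."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        delim = _detect_delimiter(header)
        names = [c.strip() for c in header.split(delim)]
        if names != EVENT_COLUMNS:
            raise ParseError(
                f"{path}: header must be {EVENT_COLUMNS}, got {names}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(delim)
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(parts)}"
                )
            try:
                rows.append(
                    (float(parts[0]), float(parts[1]), int(parts[2]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def load_metadata(path: str | Path) -> dict:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ParseError(f"{path}: metadata must be a key/value document")
    missing = {"cell_id"} - meta.keys()
    if missing:
        raise ValidationError(f"{path}: missing metadata keys: {sorted(missing)}")
    return meta


def load_event_series(
    path: str | Path, metadata_path: str | Path
) -> SpikeEventSeries:
    """Load and validate one cell's events plus its metadata document.

    Events are sorted by time; duplicate times (within 1 us) are rejected.
    If ``recording_duration_s`` is absent from the metadata, the spike span
    is used as a fallback with a logged warning.
    """
    table = load_event_table(path)
    meta = load_metadata(metadata_path)
    table = table.sort_values("time_s", kind="stable").reset_index(drop=True)
    duration = meta.get("recording_duration_s")
    if duration is None:
        if len(table) < 2:
            raise ValidationError(
                f"{metadata_path}: recording_duration_s missing and spike "
                "span undefined"
            )
        duration = float(table["time_s"].iloc[-1] - table["time_s"].iloc[0])
        logger.warning(
            "%s: recording_duration_s missing from metadata; falling back "
            "to spike span %.6f s",
            meta["cell_id"],
            duration,
        )
    return SpikeEventSeries(
        cell_id=str(meta["cell_id"]),
        times_s=table["time_s"].to_numpy(),
        amplitudes=table["amplitude"].to_numpy(),
        spikelet_counts=table["spikelet_count"].to_numpy(),
        recording_duration_s=float(duration),
        group_label=str(meta.get("group_label", "")),
        genotype=str(meta.get("genotype", "")),
    )


def save_event_series(
    series: SpikeEventSeries,
    path: str | Path,
    metadata_path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write one cell's events and metadata in the loadable text formats.

    Times are written with microsecond precision so that a save->load
    round trip reproduces the series exactly on the written representation.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(EVENT_COLUMNS) + "\n")
        for t, a, s in zip(
            series.times_s, series.amplitudes, series.spikelet_counts
        ):
            fh.write(f"{t:.6f}{delimiter}{a:.6g}{delimiter}{int(s)}\n")
    meta = {
        "cell_id": series.cell_id,
        "recording_duration_s": float(series.recording_duration_s),
        "group_label": series.group_label,
        "genotype": series.genotype,
    }
    with open(metadata_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def write_feature_table(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-cell feature table with the canonical column order."""
    df = pd.DataFrame(list(rows))
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    df = df[FEATURE_TABLE_COLUMNS]
    df["heterogeneous_cs"] = df["heterogeneous_cs"].astype(int)
    out = df.copy()
    # fixed decimal formatting keeps reruns byte-identical
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(lambda v: f"{v:.10g}" if math.isfinite(v) else "nan")
    out.to_csv(path, sep="\t", index=False)
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
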