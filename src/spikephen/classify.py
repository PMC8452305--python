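"""Rule-based event classification: simple spikes, complex spikes, doublets.

Classification precedence is complex > doublet > simple, since a complex
spike would also satisfy the doublet time-window pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpikeEventSeries
from .errors import InsufficientDataError

SIMPLE = "simple"
COMPLEX = "complex"
DOUBLET_PRIMARY = "doublet_primary"
DOUBLET_SECONDARY = "doublet_secondary"

LABELS = (SIMPLE, COMPLEX, DOUBLET_PRIMARY, DOUBLET_SECONDARY)


@dataclass
class ClassifierParams:
    """Thresholds of the rule-based classifier.

    doublet_window_s : a primary's smaller followers must occur within
        this window (default 20 ms).
    doublet_ratio : follower/primary amplitude ratio must be strictly
        below this to count as "smaller" (default 0.9; exact equality
        is "not smaller").
    cs_min_spikelets : events with at least this many spikelets are
        complex spikes (default 3).
    cs_train_max_gap_s : maximal gap between successive complex spikes
        inside one complex-spike train (default 100 ms).
    """

    doublet_window_s: float = 0.020
    doublet_ratio: float = 0.9
    cs_min_spikelets: int = 3
    cs_train_max_gap_s: float = 0.100


@dataclass
class CsTrain:
    start_s: float
    end_s: float
    n_complex_spikes: int


@dataclass
class ClassifiedEvents:
    """Per-event labels plus derived complex-spike-train intervals."""

    labels: np.ndarray  # dtype=object, one of LABELS per event
    cs_train_intervals: list[CsTrain] = field(default_factory=list)
    heterogeneous: bool = False
    params: ClassifierParams = field(default_factory=ClassifierParams)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))


def classify_events(
    series: SpikeEventSeries, params: ClassifierParams | None = None
) -> ClassifiedEvents:
    """Label every event as simple / complex / doublet primary / secondary.

    Rules, applied in order:

    1. an event with ``spikelet_count >= cs_min_spikelets`` is complex;
    2. an unlabeled event followed within ``doublet_window_s`` by one or
       more unlabeled events of strictly smaller amplitude (ratio below
       ``doublet_ratio``) is a doublet primary and those followers are
       doublet secondaries;
    3. everything else is simple.

    ``heterogeneous`` is set when the cell has both complex spikes and
    doublets. Complex-spike trains are detected afterwards.
    """
    params = params or ClassifierParams()
    n = series.n_events
    if n == 0:
        raise InsufficientDataError(f"{series.cell_id}: no events to classify")
    times = series.times_s
    amps = series.amplitudes
    labels = np.full(n, None, dtype=object)

    labels[series.spikelet_counts >= params.cs_min_spikelets] = COMPLEX

    # doublets: scan in time order over still-unlabeled events
    for i in range(n):
        if labels[i] is not None:
            continue
        j = i + 1
        followers = []
        while j < n and times[j] - times[i] <= params.doublet_window_s:
            if labels[j] is None and amps[j] < params.doublet_ratio * amps[i]:
                followers.append(j)
            j += 1
        if followers:
            labels[i] = DOUBLET_PRIMARY
            labels[followers] = DOUBLET_SECONDARY

    labels[labels == None] = SIMPLE  # noqa: E711 -- object array sentinel

    classified = ClassifiedEvents(labels=labels, params=params)
    classified.cs_train_intervals = detect_cs_trains(
        classified, times, params.cs_train_max_gap_s
    )
    classified.heterogeneous = (
        classified.count(COMPLEX) > 0 and classified.count(DOUBLET_PRIMARY) > 0
    )
    return classified


def detect_cs_trains(
    classified: ClassifiedEvents,
    times: np.ndarray,
    max_gap_s: float = 0.100,
) -> list[CsTrain]:
    """Maximal runs of >= 3 complex spikes with successive gaps <= max_gap_s."""
    cs_times = np.asarray(times, dtype=float)[classified.labels == COMPLEX]
    trains: list[CsTrain] = []
    if cs_times.size < 3:
        return trains
    # split at gaps exceeding max_gap_s; keep runs of length >= 3
    breaks = np.nonzero(np.diff(cs_times) > max_gap_s)[0]
    start = 0
    for b in list(breaks) + [cs_times.size - 1]:
        run = cs_times[start : b + 1]
        if run.size >= 3:
            trains.append(CsTrain(float(run[0]), float(run[-1]), int(run.size)))
        start = b + 1
    return trains


def event_class_frequencies(
    classified: ClassifiedEvents, recording_duration_s: float
) -> tuple[float, float, float]:
    """(complex, doublet, combined) event counts per second of recording."""
    if not recording_duration_s > 0:
        raise ValueError("recording_duration_s must be > 0")
    n_cs = classified.count(COMPLEX)
    n_db = classified.count(DOUBLET_PRIMARY)
    return (
        n_cs / recording_duration_s,
        n_db / recording_duration_s,
        (n_cs + n_db) / recording_duration_s,
    )
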