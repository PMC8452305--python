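"""Per-cell simple-spike firing statistics.

Six statistics per cell: firing frequency, frequency mode (center of the
most populated 2.5 Hz bin of the inverse-ISI distribution), CV, CV2,
pause percent, and an autocorrelogram-based rhythmicity index, plus the
complex-spike / doublet class frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classify as _cls
from .classify import ClassifiedEvents, ClassifierParams, event_class_frequencies
from .core import ISISequence, SpikeEventSeries, compute_isis
from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: tolerance (in bins) used when assigning lags to half-open bins
_BIN_EPS = 1e-9


@dataclass
class FeatureParams:
    """Tunable constants of the feature stage (defaults follow the method)."""

    frequency_mode_bin_hz: float = 2.5
    pause_threshold_multiple: float = 5.0
    acg_bin_width_s: float = 0.005
    acg_max_lag_s: float = 1.0
    min_simple_spikes: int = 10
    # acceptance clause 1 for peak/trough pairs. "difference" (default)
    # requires (peak - trough) > 4*tail_sd, the reading under which a flat
    # autocorrelogram is rejected; "sum" is the literal (peak + trough)
    # comparison, which accepts every pair on dense flat trains.
    ri_acceptance_mode: str = "difference"


@dataclass
class AutocorrelogramResult:
    """Binned ordered-pair lag histogram with baseline and tail statistics."""

    bin_width_s: float
    max_lag_s: float
    counts: np.ndarray  # length max_lag_s / bin_width_s
    baseline: float  # expected pair count per bin for a rate-matched train
    tail_sd: float  # SD of counts over lags in (0.96, 1.0] s
    accepted_pairs: list[tuple[float, float, float, float]] = field(
        default_factory=list
    )  # (peak_lag_s, peak_count, trough_lag_s, trough_count)

    @property
    def bin_centers_s(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 0.5) * self.bin_width_s


@dataclass
class FiringFeatureVector:
    """All per-cell outputs of the feature stage."""

    cell_id: str
    group_label: str
    frequency_hz: float
    frequency_mode_hz: float
    cv: float
    cv2: float
    pause_percent: float
    rhythmicity_index: float
    cs_frequency_hz: float
    doublet_frequency_hz: float
    combined_cs_frequency_hz: float
    heterogeneous_cs: bool

    def as_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "group_label": self.group_label,
            "frequency_hz": self.frequency_hz,
            "frequency_mode_hz": self.frequency_mode_hz,
            "cv": self.cv,
            "cv2": self.cv2,
            "pause_percent": self.pause_percent,
            "rhythmicity_index": self.rhythmicity_index,
            "cs_frequency_hz": self.cs_frequency_hz,
            "doublet_frequency_hz": self.doublet_frequency_hz,
            "combined_cs_frequency_hz": self.combined_cs_frequency_hz,
            "heterogeneous_cs": int(self.heterogeneous_cs),
        }


def compute_frequency(n_spikes: int, recording_duration_s: float) -> float:
    """Spike count divided by total analyzed recording time (spikes/s)."""
    if not recording_duration_s > 0:
        raise ValidationError("recording_duration_s must be > 0")
    return n_spikes / recording_duration_s


def compute_frequency_mode(
    isis: ISISequence, bin_width_hz: float = 2.5
) -> float:
    """Center of the most populated ``bin_width_hz`` bin of the inverse ISIs.

    Bins are left-closed, right-open, anchored at 0 Hz; ties are broken
    toward the lowest-frequency bin.
    """
    if isis.isis_s.size < 1:
        raise InsufficientDataError("frequency mode needs >= 1 ISI")
    inv = 1.0 / isis.isis_s
    idx = np.floor(inv / bin_width_hz).astype(int)
    counts = np.bincount(idx)
    mode_bin = int(np.argmax(counts))  # argmax takes the first (lowest) max
    return (mode_bin + 0.5) * bin_width_hz


def compute_cv(isis: ISISequence) -> float:
    """Coefficient of variation: stdev(ISI) / mean(ISI), population SD."""
    if isis.isis_s.size < 2:
        raise InsufficientDataError("CV needs >= 2 ISIs")
    return float(np.std(isis.isis_s) / np.mean(isis.isis_s))


def compute_cv2(isis: ISISequence) -> float:
    """Local irregularity: mean of 2|ISIn - ISIn-1| / (ISIn + ISIn-1)."""
    x = isis.isis_s
    if x.size < 2:
        raise InsufficientDataError("CV2 needs >= 2 ISIs")
    return float(np.mean(2.0 * np.abs(np.diff(x)) / (x[1:] + x[:-1])))


def compute_pause_percent(
    isis: ISISequence,
    recording_duration_s: float,
    threshold_multiple: float = 5.0,
) -> float:
    """Summed duration of ISIs exceeding threshold_multiple x mean(ISI),
    divided by the total recording time."""
    if not recording_duration_s > 0:
        raise ValidationError("recording_duration_s must be > 0")
    if isis.isis_s.size < 2:
        raise InsufficientDataError("pause percent needs >= 2 ISIs")
    thr = threshold_multiple * isis.mean_isi_s
    return float(np.sum(isis.isis_s[isis.isis_s > thr]) / recording_duration_s)


def compute_autocorrelogram(
    times_s: np.ndarray,
    recording_duration_s: float,
    bin_width_s: float = 0.005,
    max_lag_s: float = 1.0,
) -> AutocorrelogramResult:
    """Histogram of ordered spike-pair lags up to ``max_lag_s``.

    ``counts[b]`` is the number of ordered pairs (i < j) whose lag falls in
    the half-open bin ``(b*dt, (b+1)*dt]``.  Baseline is the expected pair
    count per bin, N^2 / (T / dt); tail_sd is the SD of counts over the bins
    covering the (0.96, 1.0] s lag range (the last 8 bins at dt = 5 ms).
    """
    times = np.asarray(times_s, dtype=float)
    if times.size < 2:
        raise InsufficientDataError("autocorrelogram needs >= 2 spikes")
    n_bins = int(round(max_lag_s / bin_width_s))
    counts = np.zeros(n_bins, dtype=np.int64)
    # pair lags by spike offset k: t[k:] - t[:-k]; stop once all exceed max_lag
    for k in range(1, times.size):
        lags = times[k:] - times[:-k]
        lags = lags[lags <= max_lag_s]
        if lags.size == 0:
            break
        idx = np.ceil(lags / bin_width_s - _BIN_EPS).astype(int) - 1
        np.clip(idx, 0, n_bins - 1, out=idx)
        counts += np.bincount(idx, minlength=n_bins)

    baseline = times.size**2 / (recording_duration_s / bin_width_s)
    tail_start = int(round(0.96 / bin_width_s))
    tail = counts[tail_start:n_bins]
    tail_sd = float(np.std(tail)) if tail.size else 0.0
    return AutocorrelogramResult(
        bin_width_s=bin_width_s,
        max_lag_s=max_lag_s,
        counts=counts,
        baseline=float(baseline),
        tail_sd=tail_sd,
    )


def _extreme_bin(
    centers: np.ndarray,
    counts: np.ndarray,
    lo: float,
    hi: float,
    take_max: bool,
) -> tuple[float, float] | None:
    """(lag, count) of the max/min bin whose center lies in (lo, hi]."""
    mask = (centers > lo + _BIN_EPS) & (centers <= hi + _BIN_EPS)
    if not mask.any():
        return None
    sub_counts = counts[mask]
    sub_centers = centers[mask]
    pos = int(np.argmax(sub_counts) if take_max else np.argmin(sub_counts))
    return float(sub_centers[pos]), float(sub_counts[pos])


def compute_rhythmicity_index(
    acg: AutocorrelogramResult,
    mean_isi_s: float,
    acceptance_mode: str = "difference",
) -> tuple[float, list[tuple[float, float, float, float]]]:
    """Iterative autocorrelogram peak/trough search and rhythmicity index.

    The first peak is the highest bin between 10 ms and 1.5x the mean ISI
    (lag a1).  Each trough is the lowest bin between its peak (lag a_n) and
    a_n + a1.  Each subsequent peak is the highest bin between the previous
    trough and a_n + a1 + 10 ms.  A (peak, trough) pair is accepted when its
    peak-trough contrast clears 4 x the tail SD (see ``acceptance_mode``),
    or when the peak exceeds baseline + 2 x tail SD and the trough falls
    below baseline - 2 x tail SD.  Iteration stops at the first rejected
    pair or when a search window's upper edge exceeds the maximal lag.
    RI = sum of accepted (peak - trough) differences divided by baseline.

    ``acceptance_mode="difference"`` (default) tests (peak - trough)
    > 4 x tail SD, under which a flat autocorrelogram is rejected;
    ``"sum"`` tests (peak + trough) > 4 x tail SD, which on dense trains
    accepts essentially every pair.
    """
    counts = np.asarray(acg.counts, dtype=float)
    accepted: list[tuple[float, float, float, float]] = []
    if not counts.any() or acg.baseline <= 0:
        return 0.0, accepted
    centers = acg.bin_centers_s
    sd = acg.tail_sd
    base = acg.baseline

    # first peak: highest bin in (10 ms, 1.5 * mean ISI]
    first = _extreme_bin(centers, counts, 0.010, 1.5 * mean_isi_s, take_max=True)
    if first is None:
        return 0.0, accepted
    a1, peak_count = first
    peak_lag = a1
    while True:
        trough_hi = peak_lag + a1
        if trough_hi > acg.max_lag_s:
            break
        trough = _extreme_bin(centers, counts, peak_lag, trough_hi, take_max=False)
        if trough is None:
            break
        trough_lag, trough_count = trough
        if acceptance_mode == "sum":
            clause1 = (peak_count + trough_count) > 4.0 * sd
        elif acceptance_mode == "difference":
            clause1 = (peak_count - trough_count) > 4.0 * sd
        else:
            raise ValidationError(
                f"acceptance_mode must be 'difference' or 'sum', "
                f"got {acceptance_mode!r}"
            )
        clause2 = (peak_count > base + 2.0 * sd) and (trough_count < base - 2.0 * sd)
        if not (clause1 or clause2) or trough_count > peak_count:
            break
        accepted.append((peak_lag, peak_count, trough_lag, trough_count))

        next_hi = peak_lag + a1 + 0.010
        if next_hi > acg.max_lag_s:
            break
        nxt = _extreme_bin(centers, counts, trough_lag, next_hi, take_max=True)
        if nxt is None:
            break
        peak_lag, peak_count = nxt

    ri = sum(p - t for _, p, _, t in accepted) / base
    return float(ri), accepted


def simple_spike_times(
    series: SpikeEventSeries, classified: ClassifiedEvents
) -> np.ndarray:
    """Times of events labeled simple; removed events leave one merged ISI."""
    return series.times_s[classified.labels == _cls.SIMPLE]


def extract_features(
    series: SpikeEventSeries,
    classified: ClassifiedEvents,
    params: FeatureParams | None = None,
) -> FiringFeatureVector:
    """Compute the full per-cell feature vector.

    Simple-spike statistics are computed on the simple-spike-only time
    sequence (complex spikes, doublet primaries and secondaries removed;
    the gap spanning a removed event is kept as a single ISI between the
    flanking simple spikes).

    Raises
    ------
    InsufficientDataError
        If the cell has fewer than ``params.min_simple_spikes`` simple
        spikes; callers should flag the cell, not drop it silently.
    """
    params = params or FeatureParams()
    ss_times = simple_spike_times(series, classified)
    if ss_times.size < params.min_simple_spikes:
        raise InsufficientDataError(
            f"{series.cell_id}: {ss_times.size} simple spikes "
            f"(< {params.min_simple_spikes})"
        )
    duration = series.recording_duration_s
    isis = compute_isis(ss_times)

    acg = compute_autocorrelogram(
        ss_times, duration, params.acg_bin_width_s, params.acg_max_lag_s
    )
    ri, accepted = compute_rhythmicity_index(
        acg, isis.mean_isi_s, params.ri_acceptance_mode
    )
    acg.accepted_pairs = accepted

    cs_f, db_f, comb_f = event_class_frequencies(classified, duration)
    return FiringFeatureVector(
        cell_id=series.cell_id,
        group_label=series.group_label,
        frequency_hz=compute_frequency(ss_times.size, duration),
        frequency_mode_hz=compute_frequency_mode(
            isis, params.frequency_mode_bin_hz
        ),
        cv=compute_cv(isis),
        cv2=compute_cv2(isis),
        pause_percent=compute_pause_percent(
            isis, duration, params.pause_threshold_multiple
        ),
        rhythmicity_index=ri,
        cs_frequency_hz=cs_f,
        doublet_frequency_hz=db_f,
        combined_cs_frequency_hz=comb_f,
        heterogeneous_cs=classified.heterogeneous,
    )
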