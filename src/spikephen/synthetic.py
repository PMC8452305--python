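"""Synthetic spike-train generators with ground-truth event labels.

Renewal (regular / Poisson / gamma), burst-pause, and oscillatory
(rate-modulated Poisson) base trains, plus injection of complex spikes,
doublets, and complex-spike trains whose amplitudes and spikelet counts
respect the classifier thresholds with margin, so end-to-end
classification of synthetic data is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import classify as _cls
from .core import SpikeEventSeries
from .errors import ValidationError

#: injected event amplitudes / spikelet counts (margins vs classifier defaults)
SIMPLE_AMP = 1.0
DOUBLET_SECONDARY_AMP = 0.5
COMPLEX_AMP = 2.0
COMPLEX_SPIKELETS = 4

#: minimal ISI enforced in all generators (well above the 1 us dup threshold)
_MIN_ISI_S = 1e-5

#: margin cleared around injected structures so base spikes cannot disturb
#: the doublet window rule (20 ms window + 1 ms slack before, 2 ms after)
_CLEAR_BEFORE_S = 0.021
_CLEAR_AFTER_S = 0.002

#: minimal spacing between injected structures; keeps lone complex spikes
#: from chaining into spurious complex-spike trains (max train gap 100 ms)
_STRUCT_SEPARATION_S = 0.120

Kind = Literal["regular", "poisson", "gamma_renewal", "burst_pause", "oscillatory"]


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic spike train."""

    kind: Kind = "poisson"
    rate_hz: float = 60.0
    gamma_shape: float = 1.0
    intra_burst_rate_hz: float = 150.0
    burst_duration_mean_s: float = 1.0
    pause_duration_mean_s: float = 0.3
    intra_burst_shape: float = 20.0
    oscillation_f_hz: float = 10.0
    oscillation_depth: float = 0.0
    cs_rate_hz: float = 0.0
    doublet_rate_hz: float = 0.0
    cs_train_rate_hz: float = 0.0
    duration_s: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.rate_hz < 0 or self.cs_rate_hz < 0 or self.doublet_rate_hz < 0:
            raise ValidationError("rates must be >= 0")
        if self.cs_train_rate_hz < 0:
            raise ValidationError("rates must be >= 0")
        if not 0.0 <= self.oscillation_depth <= 1.0:
            raise ValidationError("oscillation_depth must be in [0, 1]")
        if self.gamma_shape <= 0 or self.intra_burst_shape <= 0:
            raise ValidationError("gamma shapes must be > 0")


@dataclass
class LabeledSeries:
    """A SpikeEventSeries plus per-event ground-truth labels and provenance."""

    series: SpikeEventSeries
    true_labels: np.ndarray  # dtype=object, classify.LABELS entries
    provenance: dict = field(default_factory=dict)


def _renewal_isis(rng: np.random.Generator, spec: GeneratorSpec, n: int) -> np.ndarray:
    if spec.kind == "regular":
        return np.full(n, 1.0 / spec.rate_hz)
    if spec.kind == "poisson":
        return np.maximum(rng.exponential(1.0 / spec.rate_hz, n), _MIN_ISI_S)
    if spec.kind == "gamma_renewal":
        scale = 1.0 / (spec.rate_hz * spec.gamma_shape)
        return np.maximum(rng.gamma(spec.gamma_shape, scale, n), _MIN_ISI_S)
    raise ValidationError(f"not a renewal kind: {spec.kind}")


def _simple_series(
    spec: GeneratorSpec, times: np.ndarray, provenance: dict
) -> LabeledSeries:
    n = times.size
    series = SpikeEventSeries(
        cell_id=f"synth_{spec.kind}_{spec.seed}",
        times_s=times,
        amplitudes=np.full(n, SIMPLE_AMP),
        spikelet_counts=np.zeros(n, dtype=int),
        recording_duration_s=spec.duration_s,
    )
    return LabeledSeries(
        series=series,
        true_labels=np.full(n, _cls.SIMPLE, dtype=object),
        provenance=provenance,
    )


def generate_renewal(spec: GeneratorSpec) -> LabeledSeries:
    """I.i.d.-ISI train: degenerate, exponential, or gamma intervals."""
    spec.validate()
    if spec.kind not in ("regular", "poisson", "gamma_renewal"):
        raise ValidationError(f"generate_renewal cannot make kind {spec.kind!r}")
    if spec.rate_hz * spec.duration_s < 2:
        raise ValidationError("expected spike count < 2")
    rng = np.random.default_rng(spec.seed)
    chunk = int(spec.rate_hz * spec.duration_s * 1.3) + 50
    isis = _renewal_isis(rng, spec, chunk)
    times = np.cumsum(isis)
    while times[-1] < spec.duration_s:
        extra = _renewal_isis(rng, spec, chunk)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times <= spec.duration_s]
    return _simple_series(spec, times, {"spec": spec, "generator": "renewal"})


def generate_burst_pause(spec: GeneratorSpec) -> LabeledSeries:
    """Alternating exponential burst/pause states; gamma firing inside bursts."""
    spec.validate()
    if spec.kind != "burst_pause":
        raise ValidationError(f"generate_burst_pause cannot make kind {spec.kind!r}")
    if spec.pause_duration_mean_s < 0:
        raise ValidationError("pause_duration_mean_s must be >= 0")
    if spec.burst_duration_mean_s <= 0:
        raise ValidationError("burst_duration_mean_s must be > 0")
    rng = np.random.default_rng(spec.seed)
    scale = 1.0 / (spec.intra_burst_rate_hz * spec.intra_burst_shape)

    times: list[float] = []
    states: list[tuple[str, float, float]] = []
    t = 0.0
    while t < spec.duration_s:
        burst_end = min(
            t + rng.exponential(spec.burst_duration_mean_s), spec.duration_s
        )
        states.append(("burst", t, burst_end))
        while True:
            isi = max(rng.gamma(spec.intra_burst_shape, scale), _MIN_ISI_S)
            t += isi
            if t > burst_end:
                break
            times.append(t)
        t = burst_end
        if spec.pause_duration_mean_s > 0 and t < spec.duration_s:
            pause_end = min(
                t + rng.exponential(spec.pause_duration_mean_s), spec.duration_s
            )
            states.append(("pause", t, pause_end))
            t = pause_end
    return _simple_series(
        spec,
        np.asarray(times),
        {"spec": spec, "generator": "burst_pause", "states": states},
    )


def generate_oscillatory(spec: GeneratorSpec) -> LabeledSeries:
    """Inhomogeneous Poisson, rate r(t) = rate_hz * (1 + m sin 2 pi f t),
    sampled by thinning a homogeneous Poisson at the peak rate."""
    spec.validate()
    if spec.kind != "oscillatory":
        raise ValidationError(f"generate_oscillatory cannot make kind {spec.kind!r}")
    if spec.oscillation_f_hz <= 0:
        raise ValidationError("oscillation_f_hz must be > 0")
    rng = np.random.default_rng(spec.seed)
    lam_max = spec.rate_hz * (1.0 + spec.oscillation_depth)
    n_cand = rng.poisson(lam_max * spec.duration_s)
    cand = np.sort(rng.uniform(0.0, spec.duration_s, n_cand))
    rate = spec.rate_hz * (
        1.0
        + spec.oscillation_depth * np.sin(2.0 * np.pi * spec.oscillation_f_hz * cand)
    )
    keep = rng.uniform(0.0, lam_max, n_cand) < rate
    times = cand[keep]
    # enforce minimal separation (thinning can leave near-coincident events)
    if times.size:
        sep = np.concatenate([[True], np.diff(times) >= _MIN_ISI_S])
        times = times[sep]
    return _simple_series(spec, times, {"spec": spec, "generator": "oscillatory"})


def _sample_structures(
    rng: np.random.Generator, duration_s: float, cs_n: int, db_n: int, train_n: int
) -> list[dict]:
    """Place injected structures with rejection sampling; structures keep a
    separation of at least _STRUCT_SEPARATION_S between their spans."""
    structures: list[dict] = []
    spans: list[tuple[float, float]] = []

    def place(span_len: float) -> float:
        hi = duration_s - span_len - 0.05
        if hi <= 0.05:
            raise ValidationError("recording too short for injected structure")
        for _ in range(100):
            start = rng.uniform(0.05, hi)
            ok = all(
                not (
                    start - _STRUCT_SEPARATION_S < e
                    and s < start + span_len + _STRUCT_SEPARATION_S
                )
                for s, e in spans
            )
            if ok:
                spans.append((start, start + span_len))
                return start
        raise ValidationError("could not place injected event after 100 attempts")

    for _ in range(train_n):
        n_cs = int(rng.integers(3, 6))
        gaps = rng.uniform(0.020, 0.080, n_cs - 1)
        rel = np.concatenate([[0.0], np.cumsum(gaps)])
        start = place(float(rel[-1]))
        structures.append({"type": "cs_train", "times": start + rel})
    for _ in range(cs_n):
        start = place(0.0)
        structures.append({"type": "complex", "times": np.array([start])})
    for _ in range(db_n):
        gap = rng.uniform(0.002, 0.018)
        start = place(gap)
        structures.append({"type": "doublet", "times": np.array([start, start + gap])})
    return structures


def inject_events(
    base: LabeledSeries,
    cs_rate_hz: float = 0.0,
    doublet_rate_hz: float = 0.0,
    cs_train_rate_hz: float = 0.0,
    seed: int | None = None,
) -> LabeledSeries:
    """Merge complex spikes, doublets, and complex-spike trains into a train.

    Injected structures are placed at Poisson counts over the recording,
    mutually separated, and base simple spikes in a margin around each
    structure are removed so ground-truth labels satisfy the classifier
    rules exactly. With all rates zero the input is returned unchanged.
    """
    if min(cs_rate_hz, doublet_rate_hz, cs_train_rate_hz) < 0:
        raise ValidationError("injection rates must be >= 0")
    if cs_rate_hz == doublet_rate_hz == cs_train_rate_hz == 0:
        return base
    spec = base.provenance.get("spec")
    duration = base.series.recording_duration_s
    rng = np.random.default_rng(
        seed if seed is not None else (spec.seed + 1 if spec else 0)
    )
    cs_n = rng.poisson(cs_rate_hz * duration)
    db_n = rng.poisson(doublet_rate_hz * duration)
    train_n = rng.poisson(cs_train_rate_hz * duration)
    structures = _sample_structures(rng, duration, cs_n, db_n, train_n)

    inj_times, inj_amps, inj_spk, inj_lab = [], [], [], []
    for st in structures:
        if st["type"] == "doublet":
            inj_times.extend(st["times"])
            inj_amps.extend([SIMPLE_AMP, DOUBLET_SECONDARY_AMP])
            inj_spk.extend([0, 0])
            inj_lab.extend([_cls.DOUBLET_PRIMARY, _cls.DOUBLET_SECONDARY])
        else:
            for t in st["times"]:
                inj_times.append(t)
                inj_amps.append(COMPLEX_AMP)
                inj_spk.append(COMPLEX_SPIKELETS)
                inj_lab.append(_cls.COMPLEX)

    inj_times = np.asarray(inj_times)
    keep = np.ones(base.series.n_events, dtype=bool)
    for st in structures:
        lo = st["times"][0] - _CLEAR_BEFORE_S
        hi = st["times"][-1] + _CLEAR_AFTER_S
        keep &= ~((base.series.times_s >= lo) & (base.series.times_s <= hi))

    times = np.concatenate([base.series.times_s[keep], inj_times])
    amps = np.concatenate([base.series.amplitudes[keep], inj_amps])
    spks = np.concatenate([base.series.spikelet_counts[keep], inj_spk])
    labs = np.concatenate(
        [base.true_labels[keep], np.asarray(inj_lab, dtype=object)]
    )
    order = np.argsort(times, kind="stable")

    series = SpikeEventSeries(
        cell_id=base.series.cell_id,
        times_s=times[order],
        amplitudes=amps[order],
        spikelet_counts=spks[order].astype(int),
        recording_duration_s=duration,
        group_label=base.series.group_label,
        genotype=base.series.genotype,
    )
    prov = dict(base.provenance)
    prov["injection"] = {
        "cs_rate_hz": cs_rate_hz,
        "doublet_rate_hz": doublet_rate_hz,
        "cs_train_rate_hz": cs_train_rate_hz,
        "n_complex": int(cs_n),
        "n_doublets": int(db_n),
        "n_cs_trains": int(train_n),
    }
    return LabeledSeries(series=series, true_labels=labs[order], provenance=prov)


PRESETS = ("young_control", "old_control", "mutant")


def _cohort_cell(preset: str, rng_seed: int, duration_s: float) -> LabeledSeries:
    rng = np.random.default_rng(rng_seed)
    base_seed = int(rng.integers(0, 2**31))
    inj_seed = int(rng.integers(0, 2**31))
    if preset in ("young_control", "mutant"):
        spec = GeneratorSpec(
            kind="gamma_renewal",
            rate_hz=float(rng.uniform(40.0, 80.0)),
            gamma_shape=float(rng.uniform(1.5, 3.0)),
            duration_s=duration_s,
            seed=base_seed,
        )
        base = generate_renewal(spec)
        doublet_rate = 0.8 if preset == "mutant" else 0.3
        cs_rate = 0.2
    elif preset == "old_control":
        # intra-burst rate kept below 95 Hz so the oscillation period
        # (> 10.5 ms) is inside the first-peak search window, which opens
        # at a 10 ms lag; faster bursts are invisible to the rhythmicity
        # index at the 5 ms autocorrelogram resolution
        spec = GeneratorSpec(
            kind="burst_pause",
            intra_burst_rate_hz=float(rng.uniform(75.0, 95.0)),
            intra_burst_shape=float(rng.uniform(10.0, 20.0)),
            burst_duration_mean_s=1.5,
            pause_duration_mean_s=float(rng.uniform(0.15, 0.35)),
            duration_s=duration_s,
            seed=base_seed,
        )
        base = generate_burst_pause(spec)
        doublet_rate = 0.05
        cs_rate = 0.8
    else:
        raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    out = inject_events(
        base, cs_rate_hz=cs_rate, doublet_rate_hz=doublet_rate, seed=inj_seed
    )
    out.provenance["preset"] = preset
    out.provenance["cell_seed"] = rng_seed
    return out


def generate_cohort(
    preset: str,
    n_cells: int,
    seed: int,
    duration_s: float = 120.0,
    group_label: str | None = None,
) -> list[LabeledSeries]:
    """Generate ``n_cells`` labeled trains from one firing-phenotype preset.

    ``young_control``: gamma-renewal, rate U(40, 80) Hz, shape U(1.5, 3),
    doublets 0.3 Hz, complex spikes 0.2 Hz. ``old_control``: burst-pause,
    intra-burst 75-95 Hz, shape 10-20, bursts of 1.5 s mean, pause mean
    0.15-0.35 s, complex spikes 0.8 Hz, doublets 0.05 Hz. ``mutant``: the
    young parameter distributions with doublets at 0.8 Hz
    (arrested-maturation stand-in).
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    label = group_label if group_label is not None else preset
    children = np.random.SeedSequence(seed).spawn(n_cells)
    cohort = []
    for i, child in enumerate(children):
        cell_seed = int(child.generate_state(1)[0])
        cell = _cohort_cell(preset, cell_seed, duration_s)
        cell.series.cell_id = f"{label}_{i:03d}"
        cell.series.group_label = label
        cell.series.genotype = "mutant" if preset == "mutant" else "control"
        cohort.append(cell)
    return cohort
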