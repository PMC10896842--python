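"""Slow-oscillation (SO) event detection in stage-scored sleep EEG.

Detection runs per channel on the 0.1–4 Hz band-passed signal. Candidate
events are the segments between consecutive positive-to-negative and
negative-to-positive zero crossings; a candidate spans from the
positive-to-negative crossing through the negative half-wave and the
following positive half-wave, ending at the next positive-to-negative
crossing. Four criteria must hold:

1. trough amplitude ≤ −80 µV,
2. max − min over the event ≥ 80 µV,
3. negative half-wave duration (first to second zero crossing) within
   300–1000 ms,
4. total event duration ≤ 10 s.

Candidates overlapping scorer-excluded 30-s epochs or muscle-artifact
bins (Brunner 26.25–32 Hz / 4-s-bin rule; Wang 4–50 Hz / 5-s-bin rule)
are discarded, events must start and end inside epochs of the requested
sleep stage, and a two-pass amplitude-outlier screen (per electrode,
then pooled across electrodes) removes residual artifacts whose
trough-referenced amplitude exceeds mean + 4 SD.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

STAGES = ("Wake", "S1", "S2", "SWS", "REM")
EPOCH_S = 30.0

#: channel names treated as contralateral mastoid references
MASTOID_NAMES = ("A1", "A2", "M1", "M2")


@dataclass
class EEGRecording:
    """Multichannel EEG (µV) with a 30-s-epoch hypnogram.

    ``excluded_epochs`` marks scorer-identified artifact epochs; when
    omitted, no epochs are excluded.
    """

    signals: np.ndarray
    fs: float
    channel_names: list[str]
    hypnogram: list[str]
    excluded_epochs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be channels × samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.signals.shape[0]:
            raise ValueError("one channel name per signal row required")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signal values must be finite")
        n_epochs = math.ceil(self.signals.shape[1] / (EPOCH_S * self.fs))
        if len(self.hypnogram) != n_epochs:
            raise ValueError(
                f"hypnogram length {len(self.hypnogram)} does not match "
                f"{n_epochs} 30-s epochs"
            )
        unknown = set(self.hypnogram) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown hypnogram stages: {sorted(unknown)}")
        if self.excluded_epochs is None:
            self.excluded_epochs = np.zeros(n_epochs, dtype=bool)
        else:
            self.excluded_epochs = np.asarray(self.excluded_epochs, dtype=bool)
            if self.excluded_epochs.shape != (n_epochs,):
                raise ValueError("excluded_epochs must have one flag per epoch")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def epoch_of(self, t: float) -> int:
        return int(t // EPOCH_S)


@dataclass(frozen=True)
class SODetectionParams:
    """Thresholds of the SO detector; defaults follow standard criteria."""

    band: tuple[float, float] = (0.1, 4.0)
    trough_max: float = -80.0           # µV, criterion (1)
    min_range: float = 80.0             # µV, criterion (2)
    half_wave_bounds: tuple[float, float] = (0.3, 1.0)  # s, criterion (3)
    max_duration: float = 10.0          # s, criterion (4)
    outlier_sd: float = 4.0
    ref_halfwindow: float = 10.0        # s, trough-referencing window
    codetect_delay: float = 0.4         # s
    edge_exclude: float = 5.0           # s trimmed at record edges
    artifact_metric: str = "rms"        # bin statistic for artifact masks

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if self.trough_max >= 0:
            raise ValueError("trough_max is a negative voltage threshold")
        if self.min_range <= 0 or self.max_duration <= 0:
            raise ValueError("amplitude/duration thresholds must be positive")
        if not 0 < self.half_wave_bounds[0] < self.half_wave_bounds[1]:
            raise ValueError("half_wave_bounds must be increasing positives")


@dataclass(frozen=True)
class SOEvent:
    """One detected SO on one channel; all times in seconds."""

    channel: str
    t_start: float    # positive-to-negative zero crossing
    t_mid: float      # negative-to-positive zero crossing
    t_end: float      # next positive-to-negative crossing
    t_trough: float
    trough_amp: float  # µV, filtered signal at the trough
    range_amp: float   # µV, max − min over the event
    stage: str
    ref_amp: float = float("nan")  # |trough − local ±10 s mean|, screening only

    def __post_init__(self) -> None:
        if not self.t_start < self.t_trough < self.t_mid <= self.t_end:
            raise ValueError("event times must satisfy start < trough < mid <= end")


def _sos_bandpass(band: tuple[float, float], fs: float, order: int = 4):
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band {band} must lie strictly inside (0, {fs / 2}) Hz"
        )
    return signal.butter(order, band, btype="bandpass", output="sos", fs=fs)


def filter_slow(rec: EEGRecording, band: tuple[float, float] | None = None) -> EEGRecording:
    """Zero-phase band-pass (4th-order Butterworth, forward–backward)."""
    band = band or (0.1, 4.0)
    sos = _sos_bandpass(band, rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.signals, axis=1)
    return replace(rec, signals=filtered)


def rereference_mastoids(rec: EEGRecording) -> EEGRecording:
    """Contralateral-mastoid re-referencing when mastoid channels exist.

    Left-hemisphere channels (odd 10-20 suffix) are referenced to the
    right mastoid and vice versa; midline channels to the mastoid mean.
    Without mastoid channels the input is assumed pre-referenced.
    """
    names = rec.channel_names
    mastoids = {n for n in names if n in MASTOID_NAMES}
    if not mastoids:
        logger.warning("no mastoid channels found; assuming pre-referenced input")
        return rec
    left_m = next((n for n in ("A1", "M1") if n in mastoids), None)
    right_m = next((n for n in ("A2", "M2") if n in mastoids), None)
    sig = rec.signals.copy()
    both = [n for n in (left_m, right_m) if n]
    mean_m = np.mean([rec.signals[names.index(n)] for n in both], axis=0)
    for i, name in enumerate(names):
        if name in mastoids:
            continue
        digits = "".join(c for c in name if c.isdigit())
        if digits and int(digits) % 2 == 1 and right_m:      # left scalp
            ref = rec.signals[names.index(right_m)]
        elif digits and int(digits) % 2 == 0 and left_m:     # right scalp
            ref = rec.signals[names.index(left_m)]
        else:
            ref = mean_m
        sig[i] = rec.signals[i] - ref
    keep = [i for i, n in enumerate(names) if n not in mastoids]
    return EEGRecording(
        signals=sig[keep],
        fs=rec.fs,
        channel_names=[names[i] for i in keep],
        hypnogram=list(rec.hypnogram),
        excluded_epochs=rec.excluded_epochs.copy(),
    )


def _mask_bins(filtered: np.ndarray, fs: float, bin_s: float, metric: str) -> np.ndarray:
    """Per-channel per-bin amplitude statistic; (channels, n_bins)."""
    bin_len = int(round(bin_s * fs))
    n_bins = filtered.shape[1] // bin_len
    if n_bins == 0:
        return np.zeros((filtered.shape[0], 0))
    seg = filtered[:, :n_bins * bin_len].reshape(filtered.shape[0], n_bins, bin_len)
    if metric == "rms":
        return np.sqrt(np.mean(seg**2, axis=2))
    if metric == "power":
        return np.mean(seg**2, axis=2)
    if metric == "abs-sum":
        return np.sum(np.abs(seg), axis=2)
    raise ValueError(f"unknown bin metric {metric!r}")


#: µV; bins whose band-limited RMS stays below this cannot be a muscle
#: artifact (scalp EMG runs tens of µV) — guards the ratio rules against
#: numerically tiny medians on quiet or silent records
MASK_AMPLITUDE_FLOOR = 5.0


def brunner_mask(rec: EEGRecording, metric: str = "rms",
                 min_amplitude: float = MASK_AMPLITUDE_FLOOR) -> np.ndarray:
    """Muscle-artifact mask: 26.25–32 Hz band, 4-s bins.

    A bin is flagged when its amplitude statistic exceeds 4× the median
    of the 45 surrounding bins (the 3 minutes centred on it; truncated at
    record edges) and the absolute floor. Returns a (channels × bins)
    boolean array.
    """
    sos = _sos_bandpass((26.25, 32.0), rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.signals, axis=1)
    stats = _mask_bins(filtered, rec.fs, 4.0, metric)
    n_bins = stats.shape[1]
    mask = np.zeros_like(stats, dtype=bool)
    half = 22  # 45-bin window: bin ± 22
    for b in range(n_bins):
        lo, hi = max(0, b - half), min(n_bins, b + half + 1)
        med = np.median(stats[:, lo:hi], axis=1)
        mask[:, b] = (med > 0) & (stats[:, b] > 4.0 * med) & \
            (stats[:, b] > min_amplitude)
    return mask


def wang_mask(rec: EEGRecording, metric: str = "rms",
              min_amplitude: float = MASK_AMPLITUDE_FLOOR) -> np.ndarray:
    """Muscle-artifact mask: 4–50 Hz band, 5-s bins.

    A bin is flagged when its statistic exceeds 6× the median of all
    bins of the same channel and the absolute floor. Returns a
    (channels × bins) boolean array.
    """
    high = min(50.0, rec.fs / 2 * 0.98)
    sos = _sos_bandpass((4.0, high), rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.signals, axis=1)
    stats = _mask_bins(filtered, rec.fs, 5.0, metric)
    med = np.median(stats, axis=1, keepdims=True)
    return (med > 0) & (stats > 6.0 * med) & (stats > min_amplitude)


def _overlaps_masked(t0: float, t1: float, mask_row: np.ndarray, bin_s: float) -> bool:
    if mask_row.size == 0:
        return False
    b0 = max(0, int(t0 // bin_s))
    b1 = min(mask_row.size - 1, int(t1 // bin_s))
    if b0 > b1:
        return False
    return bool(mask_row[b0:b1 + 1].any())


def _referenced_amp(filtered_ch: np.ndarray, fs: float, trough_idx: int,
                    trough_val: float, halfwindow: float) -> float:
    lo = max(0, trough_idx - int(halfwindow * fs))
    hi = min(len(filtered_ch), trough_idx + int(halfwindow * fs) + 1)
    return abs(trough_val - float(np.mean(filtered_ch[lo:hi])))


def outlier_screen(events: list[SOEvent], params: SODetectionParams | None = None) -> list[SOEvent]:
    """Two-pass amplitude-outlier screening.

    Pass 1 works per electrode, pass 2 on the pooled survivors; both
    discard events whose trough-referenced amplitude exceeds
    mean + ``outlier_sd``·SD of the relevant distribution. Electrodes
    with a single event skip pass 1 (SD undefined).
    """
    params = params or SODetectionParams()
    k = params.outlier_sd

    def survivors(evts: list[SOEvent]) -> list[SOEvent]:
        amps = np.array([e.ref_amp for e in evts])
        if len(evts) < 2 or np.any(~np.isfinite(amps)):
            return list(evts)
        cut = amps.mean() + k * amps.std(ddof=0)
        return [e for e, a in zip(evts, amps) if a <= cut]

    by_channel: dict[str, list[SOEvent]] = {}
    for e in events:
        by_channel.setdefault(e.channel, []).append(e)
    pass1: list[SOEvent] = []
    for evts in by_channel.values():
        pass1.extend(survivors(evts))
    pass2 = survivors(pass1)
    return sorted(pass2, key=lambda e: (e.t_trough, e.channel))


def detect_sos(rec: EEGRecording, params: SODetectionParams | None = None,
               stage: str = "SWS", screen_outliers: bool = True) -> list[SOEvent]:
    """Detect SO events in epochs of the given sleep stage.

    Returns events sorted by trough time. The recording may be raw; the
    slow band-pass is applied internally.
    """
    params = params or SODetectionParams()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if rec.n_samples < 2:
        return []
    filt = filter_slow(rec, params.band)
    bmask = brunner_mask(rec, params.artifact_metric)
    wmask = wang_mask(rec, params.artifact_metric)
    if rec.duration < 180:
        warnings.warn(
            "recording shorter than 3 min: Brunner surrounding-window medians "
            "use fewer than 45 bins", stacklevel=2,
        )
    fs = rec.fs
    edge = params.edge_exclude
    events: list[SOEvent] = []
    for c, name in enumerate(rec.channel_names):
        x = filt.signals[c]
        sgn = np.where(x >= 0, 1, -1)
        flips = np.flatnonzero(np.diff(sgn))
        down = flips[sgn[flips] > 0]   # positive-to-negative, index before crossing
        up = flips[sgn[flips] < 0]     # negative-to-positive
        for i, d in enumerate(down[:-1]):
            d_next = down[i + 1]
            ups = up[(up > d) & (up < d_next)]
            if len(ups) == 0:
                continue
            u = ups[0]
            # crossing times at the midpoint between the straddling samples
            t_start, t_mid, t_end = (d + 0.5) / fs, (u + 0.5) / fs, (d_next + 0.5) / fs
            if t_start < edge or t_end > rec.duration - edge:
                continue
            half_wave = t_mid - t_start
            if not params.half_wave_bounds[0] <= half_wave <= params.half_wave_bounds[1]:
                continue
            if t_end - t_start > params.max_duration:
                continue
            seg = x[d + 1:d_next + 1]
            trough_off = int(np.argmin(x[d + 1:u + 1]))
            trough_idx = d + 1 + trough_off
            trough_amp = float(x[trough_idx])
            if trough_amp > params.trough_max:
                continue
            range_amp = float(seg.max() - seg.min())
            if range_amp < params.min_range:
                continue
            ep0, ep1 = rec.epoch_of(t_start), rec.epoch_of(min(t_end, rec.duration - 1 / fs))
            if rec.hypnogram[ep0] != stage or rec.hypnogram[ep1] != stage:
                continue
            if rec.excluded_epochs[ep0:ep1 + 1].any():
                continue
            if _overlaps_masked(t_start, t_end, bmask[c], 4.0):
                continue
            if _overlaps_masked(t_start, t_end, wmask[c], 5.0):
                continue
            ref_amp = _referenced_amp(x, fs, trough_idx, trough_amp,
                                      params.ref_halfwindow)
            events.append(SOEvent(
                channel=name, t_start=t_start, t_mid=t_mid, t_end=t_end,
                t_trough=trough_idx / fs, trough_amp=trough_amp,
                range_amp=range_amp, stage=stage, ref_amp=ref_amp,
            ))
    if screen_outliers and events:
        events = outlier_screen(events, params)
    return sorted(events, key=lambda e: (e.t_trough, e.channel))
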