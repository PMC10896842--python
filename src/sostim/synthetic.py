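"""Synthetic inputs for the whole pipeline.

Real overnight polysomnography and finite-element forward solves are
external to this package, so every input the pipeline consumes can be
generated here instead:

- multichannel sleep EEG with planted SO events of three spatial types
  (global: co-detected on nearly all channels within the 400 ms window;
  frontal: anterior channels only; local: a small channel neighbourhood)
  over 1/f-shaped background noise,
- labelled CD datasets whose class separation is concentrated in the
  bins near the SO trough,
- smooth, montage-dependent linear transfer operators standing in for a
  finite-element forward model.

All generators are deterministic given their seed. The defaults emulate
the study conditions: a ~1:2 global:non-global label imbalance, SO
troughs well below the −80 µV criterion, global propagation delays
within the 400 ms co-detection window, and discriminative CD structure
within ±100 ms of the trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cd import CDMatrix, TransferModel, make_cd
from .detection import EEGRecording, SOEvent
from .montage import Montage, QUARTILES
from .regions import DEFAULT_REGIONS, RegionSet

# approximate 2-D scalp projection of 10-20 positions
# (x: left→right in [−1, 1], y: posterior→anterior in [−1, 1])
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "AF7": (-0.59, 0.77), "AF3": (-0.33, 0.80),
    "AF4": (0.33, 0.80), "AF8": (0.59, 0.77),
    "F7": (-0.81, 0.59), "F5": (-0.66, 0.62), "F3": (-0.48, 0.65),
    "F1": (-0.25, 0.67), "Fz": (0.0, 0.67), "F2": (0.25, 0.67),
    "F4": (0.48, 0.65), "F6": (0.66, 0.62), "F8": (0.81, 0.59),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "P7": (-0.81, -0.59), "P5": (-0.66, -0.62), "P3": (-0.48, -0.65),
    "P1": (-0.25, -0.67), "Pz": (0.0, -0.67), "P2": (0.25, -0.67),
    "P4": (0.48, -0.65), "P6": (0.66, -0.62), "P8": (0.81, -0.59),
    "PO7": (-0.59, -0.77), "PO3": (-0.33, -0.80),
    "PO4": (0.33, -0.80), "PO8": (0.59, -0.77),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: default per-quartile montage candidate electrodes (central line excluded)
DEFAULT_QUARTILE_CANDIDATES: dict[str, list[str]] = {
    "left-anterior": ["Fp1", "AF7", "F7", "F3"],
    "right-anterior": ["Fp2", "AF8", "F8", "F4"],
    "left-posterior": ["P7", "P3", "PO7", "O1"],
    "right-posterior": ["P8", "P4", "PO8", "O2"],
}

#: default synthetic head-electrode set (one pool across all quartiles)
DEFAULT_CHANNELS: list[str] = [
    e for q in QUARTILES for e in DEFAULT_QUARTILE_CANDIDATES[q]
]


def frontal_posterior_partition(channels: list[str]) -> tuple[list[str], list[str]]:
    """Split channels into frontal (y > 0.2) and posterior (y < −0.2) groups."""
    frontal = [c for c in channels if ELECTRODE_POSITIONS[c][1] > 0.2]
    posterior = [c for c in channels if ELECTRODE_POSITIONS[c][1] < -0.2]
    return frontal, posterior


# ---------------------------------------------------------------------------
# EEG generation


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """Study-condition defaults for planted-SO EEG generation."""

    channels: tuple[str, ...] = tuple(DEFAULT_CHANNELS)
    duration: float = 300.0          # s
    fs: float = 128.0                # Hz
    events_per_minute: float = 6.0
    type_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # global, frontal, local
    global_delay_spread: float = 0.35    # s, max trough delay across channels
    trough_amp: float = -120.0       # µV
    peak_amp: float = 60.0           # µV, positive rebound
    neg_halfwave: float = 0.5        # s
    pos_halfwave: float = 0.5        # s
    noise_rms: float = 15.0          # µV, 1/f background
    stage: str = "SWS"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1) > 1e-9:
            raise ValueError("type mix proportions must sum to 1")
        if self.fs <= 8:
            raise ValueError("sampling rate must exceed twice the slow band top")
        if self.trough_amp >= 0:
            raise ValueError("trough amplitude must be negative")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, rms: float) -> np.ndarray:
    """1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1 / np.sqrt(freqs[1:])
    spec *= shape[None, :]
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    scale = rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x * scale


def _so_template(fs: float, neg_s: float, pos_s: float,
                 trough: float, peak: float) -> np.ndarray:
    """Biphasic SO: negative half-sine then positive half-sine."""
    n_neg = int(round(neg_s * fs))
    n_pos = int(round(pos_s * fs))
    neg = trough * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = peak * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def gen_eeg(spec: SyntheticEEGSpec | None = None,
            seed: int | None = None) -> tuple[EEGRecording, pd.DataFrame]:
    """Synthetic stage-scored EEG with planted SO events.

    Returns the recording and a ground-truth table with one row per
    (event, channel) deposit: columns ``event_id``, ``so_type``,
    ``channel``, ``t_trough``.
    """
    spec = spec or SyntheticEEGSpec()
    if seed is not None:
        spec = SyntheticEEGSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    channels = list(spec.channels)
    n_ch = len(channels)
    n_samples = int(round(spec.duration * spec.fs))
    signals = _pink_noise(rng, n_ch, n_samples, spec.fs, spec.noise_rms)

    n_events = int(round(spec.events_per_minute * spec.duration / 60))
    event_len = spec.neg_halfwave + spec.pos_halfwave
    margin = 8.0  # keep clear of filter-edge exclusion and ref windows
    min_gap = event_len + 2.5
    usable = spec.duration - 2 * margin - event_len
    if n_events > 0 and usable < (n_events - 1) * min_gap:
        raise ValueError(
            f"cannot place {n_events} non-overlapping events in "
            f"{spec.duration:.0f} s at {spec.events_per_minute}/min"
        )
    # jittered regular placement guarantees the minimum gap
    starts = np.array([]) if n_events == 0 else (
        margin + np.arange(n_events) * usable / max(n_events - 1, 1)
    )
    if n_events > 1:
        slack = usable / (n_events - 1) - min_gap
        starts = starts + rng.uniform(0, max(slack * 0.5, 1e-9), size=n_events)

    frontal, _ = frontal_posterior_partition(channels)
    template = _so_template(spec.fs, spec.neg_halfwave, spec.pos_halfwave,
                            spec.trough_amp, spec.peak_amp)
    trough_off = int(np.argmin(template))
    types = rng.choice(["global", "frontal", "local"], size=n_events,
                       p=spec.type_mix)
    truth_rows = []
    for eid, (t0, so_type) in enumerate(zip(starts, types)):
        if so_type == "global":
            targets = list(range(n_ch))
            delays = rng.uniform(0, spec.global_delay_spread, size=n_ch)
            delays[rng.integers(0, n_ch)] = 0.0
        elif so_type == "frontal":
            targets = [channels.index(c) for c in frontal]
            delays = rng.uniform(0, spec.global_delay_spread, size=len(targets))
        else:  # local: one seed channel plus its nearest neighbour
            seed_ch = int(rng.integers(0, n_ch))
            pos = np.array([ELECTRODE_POSITIONS[c] for c in channels])
            d = np.linalg.norm(pos - pos[seed_ch], axis=1)
            targets = list(np.argsort(d)[:2])
            delays = rng.uniform(0, 0.1, size=len(targets))
        amp_scale = rng.uniform(0.9, 1.3, size=len(targets))
        for ch_i, delay, a in zip(targets, delays, amp_scale):
            i0 = int(round((t0 + delay) * spec.fs))
            i1 = i0 + len(template)
            if i1 > n_samples:
                continue
            signals[ch_i, i0:i1] += a * template
            truth_rows.append({
                "event_id": eid, "so_type": so_type,
                "channel": channels[ch_i],
                "t_trough": (i0 + trough_off) / spec.fs,
            })
    n_epochs = int(np.ceil(n_samples / (30 * spec.fs)))
    rec = EEGRecording(signals=signals, fs=spec.fs, channel_names=channels,
                       hypnogram=[spec.stage] * n_epochs)
    truth = pd.DataFrame(truth_rows,
                         columns=["event_id", "so_type", "channel", "t_trough"])
    return rec, truth


def detection_scores(truth: pd.DataFrame, events: list[SOEvent],
                     tol: float = 0.25) -> tuple[float, float]:
    """(recall, precision) of detected events against the planted table.

    A planted (channel, trough) deposit is recalled when some detected
    event on that channel has its trough within ``tol`` seconds; a
    detected event is a true positive when it matches a planted deposit.
    """
    by_ch: dict[str, list[float]] = {}
    for ev in events:
        by_ch.setdefault(ev.channel, []).append(ev.t_trough)
    hits = 0
    for _, row in truth.iterrows():
        ts = by_ch.get(row["channel"], [])
        if any(abs(t - row["t_trough"]) <= tol for t in ts):
            hits += 1
    recall = hits / len(truth) if len(truth) else float("nan")
    truth_by_ch: dict[str, np.ndarray] = {
        ch: g["t_trough"].to_numpy() for ch, g in truth.groupby("channel")
    }
    tp = 0
    for ev in events:
        ts = truth_by_ch.get(ev.channel, np.array([]))
        if ts.size and np.min(np.abs(ts - ev.t_trough)) <= tol:
            tp += 1
    precision = tp / len(events) if events else float("nan")
    return recall, precision


# ---------------------------------------------------------------------------
# CD dataset generation


@dataclass(frozen=True)
class SyntheticCDSpec:
    """Labelled CD dataset with class separation near the trough."""

    n_global: int = 150
    n_nonglobal: int = 300
    dt: int = 20
    effect: float = 3.0              # class-mean shift, SD units, |t| ≤ 100 ms
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_global, self.n_nonglobal) < 10:
            raise ValueError("need at least 10 samples per class")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be ≥ 0 and noise SD > 0")


def trough_bump(dt: int, halfwidth_ms: float = 100.0) -> np.ndarray:
    """Cosine-tapered bump over bin centres, supported on |t| ≤ halfwidth."""
    m = 1000 // dt
    edges = np.linspace(-500, 500, m + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    bump = np.cos(np.pi * centers / (2 * halfwidth_ms)) ** 2
    bump[np.abs(centers) > halfwidth_ms] = 0.0
    return bump


def gen_cd_dataset(spec: SyntheticCDSpec | None = None,
                   regions: RegionSet = DEFAULT_REGIONS,
                   global_mean: CDMatrix | None = None,
                   nonglobal_mean: CDMatrix | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled flattened CD dataset (X, y) with y = 1 for global.

    By default the global class mean is a trough-centred bump (support
    |t| ≤ 100 ms) of height ``effect × noise_sd`` scaled by a smooth
    region profile, and the non-global mean is zero. Explicit class-mean
    CD matrices override the default pattern (the noise SD is then used
    as given).
    """
    spec = spec or SyntheticCDSpec()
    rng = np.random.default_rng(spec.seed)
    m = 1000 // spec.dt
    n = len(regions)
    if global_mean is not None:
        mu_g = global_mean.values
        if global_mean.dt != spec.dt:
            raise ValueError("global_mean dt does not match spec dt")
    else:
        region_profile = 0.5 + 0.5 * rng.random(n)
        mu_g = spec.effect * spec.noise_sd * np.outer(trough_bump(spec.dt),
                                                      region_profile)
    mu_n = nonglobal_mean.values if nonglobal_mean is not None else np.zeros((m, n))
    Xg = mu_g.reshape(-1)[None, :] + spec.noise_sd * rng.standard_normal(
        (spec.n_global, m * n))
    Xn = mu_n.reshape(-1)[None, :] + spec.noise_sd * rng.standard_normal(
        (spec.n_nonglobal, m * n))
    X = np.vstack([Xg, Xn])
    y = np.concatenate([np.ones(spec.n_global, int), np.zeros(spec.n_nonglobal, int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def cds_from_dataset(X: np.ndarray, dt: int,
                     regions: RegionSet = DEFAULT_REGIONS) -> list[CDMatrix]:
    m = 1000 // dt
    return [make_cd(row.reshape(m, len(regions)), dt, regions) for row in X]


# ---------------------------------------------------------------------------
# transfer operators


class SyntheticTransferModel(TransferModel):
    """Smooth random montage → region-CD linear operator.

    Each region's sensitivity to a scalp position is a seeded mixture of
    Gaussian radial basis functions, so nearby electrodes produce
    correlated transfer vectors; the montage vector is the
    polarity-weighted sum over its four electrodes (hence swapping
    anodes and cathodes negates it). Vectors are normalised so the mean
    absolute entry over the reference electrode set is 1.
    """

    provenance = "synthetic"

    def __init__(self, seed: int = 0, regions: RegionSet = DEFAULT_REGIONS,
                 n_rbf: int = 40, length_scale: float = 0.25):
        super().__init__(regions)
        rng = np.random.default_rng(seed)
        self._centers = rng.uniform(-1, 1, size=(n_rbf, 2))
        self._coefs = rng.standard_normal((len(regions), n_rbf))
        self._ls = length_scale
        self._scale = 1.0
        # normalise to unit mean |entry| over single reference electrodes
        mags = [np.abs(self._electrode_field(e)).mean()
                for e in DEFAULT_CHANNELS]
        self._scale = 1.0 / np.mean(mags)

    def _electrode_field(self, electrode: str) -> np.ndarray:
        if electrode not in ELECTRODE_POSITIONS:
            raise KeyError(f"unknown electrode {electrode!r}")
        pos = np.asarray(ELECTRODE_POSITIONS[electrode])
        d2 = np.sum((self._centers - pos) ** 2, axis=1)
        phi = np.exp(-d2 / (2 * self._ls**2))
        return self._scale * (self._coefs @ phi)

    def vector(self, montage: Montage) -> np.ndarray:
        out = np.zeros(len(self.regions))
        for e, p in zip(montage.electrodes, montage.polarities):
            out += p * self._electrode_field(e)
        return out


def gen_transfer(seed: int = 0,
                 regions: RegionSet = DEFAULT_REGIONS) -> SyntheticTransferModel:
    """Seeded synthetic transfer operator over the built-in electrode set."""
    return SyntheticTransferModel(seed=seed, regions=regions)
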