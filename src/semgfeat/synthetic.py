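"""Synthetic sEMG recordings with ground-truth activation schedules.

Emulates the structure of a guided movement-acquisition protocol:
movements are repeated several times, each repetition held for ~5 s and
followed by ~3 s of rest, with a leading rest block.  The signal is
envelope-modulated zero-mean Gaussian noise — the standard surrogate for
interference-pattern surface EMG: during rest the per-channel envelope
(noise standard deviation) sits at ``noise_floor``; during a repetition
of movement ``j`` it rises to ``noise_floor + amplitude_matrix[j-1, c]``
with a short linear ramp at the interval edges.

Every sample inside a scheduled interval carries the movement id in the
``stimulus`` vector and the repetition index in ``repetition``; rest
samples carry 0 in both.  ``generate_label_jitter`` shifts the label
boundaries relative to the signal, mimicking the misalignment between
instructed stimuli and actual movement that motivates purity filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import EMGRecording

__all__ = [
    "ProtocolConfig",
    "SyntheticGroundTruth",
    "generate_recording",
    "generate_label_jitter",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of a synthetic acquisition session.

    Defaults mirror a 2 kHz, 12-channel laboratory setup running the
    full 41-movement protocol with 6 repetitions of 5 s movement + 3 s
    rest.  ``amplitude_matrix`` (movements x channels, strictly
    positive) sets the envelope boost of each movement on each channel;
    when omitted it is drawn reproducibly from ``seed``, spread widely
    enough that movements are separable by window amplitude features.
    """

    n_movements: int = 41
    n_repetitions: int = 6
    movement_duration_s: float = 5.0
    rest_duration_s: float = 3.0
    n_channels: int = 12
    sampling_rate_hz: float = 2000.0
    amplitude_matrix: np.ndarray | None = None
    noise_floor: float = 0.1
    rise_time_s: float = 0.05
    bandpass_hz: tuple[float, float] | None = None
    rectify: bool = False
    quantization_bits: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_movements < 1 or self.n_repetitions < 1 or self.n_channels < 1:
            raise ValueError("counts must be >= 1")
        if self.movement_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be positive")
        if self.rise_time_s < 0 or self.rise_time_s >= self.movement_duration_s:
            raise ValueError("rise_time_s must be in [0, movement_duration_s)")
        if self.amplitude_matrix is not None:
            amp = np.asarray(self.amplitude_matrix, dtype=np.float64)
            if amp.shape != (self.n_movements, self.n_channels):
                raise ValueError(
                    "amplitude_matrix must be (n_movements, n_channels), "
                    f"got {amp.shape}"
                )
            if not np.all(amp.max(axis=1) > 0):
                raise ValueError(
                    "each movement needs a strictly positive amplitude on "
                    "at least one channel"
                )
            object.__setattr__(self, "amplitude_matrix", amp)
        if self.quantization_bits is not None and self.quantization_bits < 2:
            raise ValueError("quantization_bits must be >= 2")

    @classmethod
    def db1_style(cls, **overrides) -> "ProtocolConfig":
        """Rectified-envelope, low-rate preset (RMS-rectified electrodes
        sampled at 100 Hz, 10 channels, 10 repetitions)."""
        defaults = dict(
            n_channels=10,
            sampling_rate_hz=100.0,
            n_repetitions=10,
            rectify=True,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def db5_style(cls, **overrides) -> "ProtocolConfig":
        """Consumer-armband preset: 16 channels at 200 Hz quantized to
        8 bits."""
        defaults = dict(
            n_channels=16,
            sampling_rate_hz=200.0,
            quantization_bits=8,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """The activation schedule a synthetic recording was built from.

    ``schedule`` rows are ``(movement_id, repetition_id, onset, offset)``
    with half-open sample intervals ``[onset, offset)``, disjoint and
    ordered.
    """

    schedule: tuple[tuple[int, int, int, int], ...]
    amplitude_matrix: np.ndarray
    seed: int
    n_samples: int


def _default_amplitudes(cfg: ProtocolConfig, rng: np.random.Generator) -> np.ndarray:
    # wide spread relative to the noise floor keeps movements separable
    return rng.uniform(0.5, 2.0, size=(cfg.n_movements, cfg.n_channels))


def _build_schedule(cfg: ProtocolConfig) -> tuple[tuple[tuple[int, int, int, int], ...], int]:
    fs = cfg.sampling_rate_hz
    move = int(round(cfg.movement_duration_s * fs))
    rest = int(round(cfg.rest_duration_s * fs))
    schedule = []
    t = rest  # leading rest block
    for mov in range(1, cfg.n_movements + 1):
        for rep in range(1, cfg.n_repetitions + 1):
            schedule.append((mov, rep, t, t + move))
            t += move + rest
    return tuple(schedule), t


def generate_recording(
    cfg: ProtocolConfig,
) -> tuple[EMGRecording, SyntheticGroundTruth]:
    """Generate one synthetic recording plus its ground truth.

    The recording is reproducible: the same config (including ``seed``)
    yields a bit-identical signal and labels.
    """
    rng = np.random.default_rng(cfg.seed)
    amp = cfg.amplitude_matrix
    if amp is None:
        amp = _default_amplitudes(cfg, rng)
    schedule, m = _build_schedule(cfg)

    envelope = np.full((m, cfg.n_channels), cfg.noise_floor)
    stimulus = np.zeros(m, dtype=np.int64)
    repetition = np.zeros(m, dtype=np.int64)
    ramp_n = int(round(cfg.rise_time_s * cfg.sampling_rate_hz))
    for mov, rep, onset, offset in schedule:
        stimulus[onset:offset] = mov
        repetition[onset:offset] = rep
        boost = amp[mov - 1]  # (C,)
        shape = np.ones(offset - onset)
        if ramp_n > 0:
            ramp = np.linspace(0.0, 1.0, ramp_n, endpoint=False)
            shape[:ramp_n] = ramp
            shape[-ramp_n:] = ramp[::-1]
        envelope[onset:offset] += shape[:, None] * boost[None, :]

    noise = rng.standard_normal((m, cfg.n_channels))
    if cfg.bandpass_hz is not None:
        lo, hi = cfg.bandpass_hz
        nyq = cfg.sampling_rate_hz / 2.0
        sos = sps.butter(4, [lo / nyq, min(hi, 0.99 * nyq) / nyq], btype="band", output="sos")
        noise = sps.sosfiltfilt(sos, noise, axis=0)
        noise /= noise.std(axis=0, keepdims=True)  # restore unit variance
    signal = envelope * noise
    if cfg.rectify:
        signal = np.abs(signal)
    if cfg.quantization_bits is not None:
        # full scale covers +-4x the largest envelope; values snap to the grid
        full_scale = 4.0 * envelope.max()
        levels = 2 ** (cfg.quantization_bits - 1)
        step = full_scale / levels
        signal = np.clip(np.round(signal / step), -levels, levels - 1) * step

    rec = EMGRecording(
        signal=signal,
        stimulus=stimulus,
        repetition=repetition,
        sampling_rate=cfg.sampling_rate_hz,
    )
    truth = SyntheticGroundTruth(
        schedule=schedule, amplitude_matrix=amp, seed=cfg.seed, n_samples=m
    )
    return rec, truth


def generate_label_jitter(
    rec: EMGRecording,
    truth: SyntheticGroundTruth,
    max_shift_samples: int,
    seed: int = 0,
) -> EMGRecording:
    """Return a copy of ``rec`` whose label boundaries are jittered.

    Each interval's onset and offset are shifted by independent uniform
    integer offsets in ``[-max_shift, +max_shift]`` while the signal is
    left untouched, so some windows straddle a label change that no
    longer matches the signal envelope.  Raises if the shift could make
    intervals collide (the shift must be smaller than the rest gap).
    """
    if max_shift_samples < 0:
        raise ValueError("max_shift_samples must be >= 0")
    sched = truth.schedule
    gaps = [sched[0][2]]  # leading rest
    gaps += [b[2] - a[3] for a, b in zip(sched, sched[1:])]
    gaps.append(truth.n_samples - sched[-1][3])
    if max_shift_samples >= min(gaps):
        raise ValueError(
            f"max_shift_samples {max_shift_samples} must be smaller than the "
            f"smallest rest gap ({min(gaps)} samples)"
        )
    rng = np.random.default_rng(seed)
    shifted = []
    for mov, rep, onset, offset in sched:
        d_on = int(rng.integers(-max_shift_samples, max_shift_samples + 1))
        d_off = int(rng.integers(-max_shift_samples, max_shift_samples + 1))
        shifted.append((mov, rep, onset + d_on, offset + d_off))
    prev_end = 0
    for mov, rep, onset, offset in shifted:
        if onset < prev_end or offset <= onset or offset > truth.n_samples:
            raise ValueError("jittered intervals overlap or leave the recording")
        prev_end = offset
    stimulus = np.zeros(truth.n_samples, dtype=np.int64)
    repetition = np.zeros(truth.n_samples, dtype=np.int64)
    for mov, rep, onset, offset in shifted:
        stimulus[onset:offset] = mov
        repetition[onset:offset] = rep
    return EMGRecording(
        signal=rec.signal,
        stimulus=stimulus,
        repetition=repetition,
        sampling_rate=rec.sampling_rate,
    )
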