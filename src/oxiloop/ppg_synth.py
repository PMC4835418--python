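"""Synthetic two-wavelength PPG generation with known ground truth.

A transmissive pulse oximeter time-multiplexes its Red and Infra-red LEDs in
a four-slot cycle (RED_ON, BOTH_OFF, IR_ON, BOTH_OFF) and digitizes the
photodiode once per slot, so a 500 S/s acquisition yields 125 S/s per optical
channel plus a 250 S/s dark "reference" channel. This module inverts that
acquisition model: given a target oxygen saturation, heart rate and perfusion
index it emits the multiplexed detector stream a finger in the probe would
have produced, with the generating physiology carried alongside as a
per-sample truth trajectory.

The pulsatile waveform is a fixed, band-limited, asymmetric beat shape built
from three harmonics of the heart rate (fast systolic upstroke, slower
diastolic decay, all energy below 3x the cardiac fundamental, i.e. under
12 Hz at the band ceiling of 4 Hz). Because both channels share the same
shape, the ratio-of-ratios embedded in the stream depends only on the
channel amplitudes, which are solved algebraically from the calibration
SpO2 = 110 - 25 R: the Infra-red AC/DC contrast is pinned by the perfusion
index and the Red contrast is then R times it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

DEFAULT_SAMPLE_RATE = 500.0
SLOTS_PER_CYCLE = 4

#: Relative amplitudes and phases (radians) of the cardiac harmonics forming
#: one beat. Chosen for a plausible asymmetric systolic/diastolic morphology;
#: the exact shape cancels out of the ratio-of-ratios.
_HARMONIC_AMPS = (1.0, 0.5, 0.2)
_HARMONIC_PHASES = (0.0, 1.1, 2.2)


class SlotLabel(IntEnum):
    """Which LEDs are lit during an acquisition slot."""

    RED_ON = 0
    BOTH_OFF = 1
    IR_ON = 2


#: The four-slot LED cycle: Red on, dark, Infra-red on, dark.
SLOT_CYCLE = (SlotLabel.RED_ON, SlotLabel.BOTH_OFF, SlotLabel.IR_ON, SlotLabel.BOTH_OFF)


def _unit_pulse(phase: np.ndarray) -> np.ndarray:
    """Zero-mean beat waveform with unit peak-to-peak amplitude.

    ``phase`` is cardiac phase in radians (one beat per 2*pi).
    """
    w = np.zeros_like(phase, dtype=float)
    for k, (a, p) in enumerate(zip(_HARMONIC_AMPS, _HARMONIC_PHASES), start=1):
        w += a * np.cos(k * phase + p)
    return w / _PULSE_P2P


def _pulse_p2p() -> float:
    grid = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    w = np.zeros_like(grid)
    for k, (a, p) in enumerate(zip(_HARMONIC_AMPS, _HARMONIC_PHASES), start=1):
        w += a * np.cos(k * grid + p)
    return float(w.max() - w.min())


_PULSE_P2P = _pulse_p2p()


@dataclass(frozen=True)
class PhysioProfile:
    """Ground-truth physiology driving the generator.

    Parameters
    ----------
    true_spo2 : float
        Arterial oxygen saturation in percent, within [70, 100].
    heart_rate : float
        Beats per minute; the cardiac fundamental must sit inside the
        0.5-4.0 Hz PPG band, i.e. 30-240 bpm.
    perfusion_index : float
        Infra-red AC/DC contrast times 100 (percent). Typical fingertip
        values are 0.5-5 %.
    dc_red, dc_ir : float
        Non-pulsatile detector levels (dimensionless), > 0.
    noise_sd : float
        Standard deviation of additive white Gaussian noise on every slot.
    ambient_level : float
        Ambient light floor added to every slot (what the dark slots read).
    seed : int
        Seed for the noise generator.
    """

    true_spo2: float = 97.0
    heart_rate: float = 75.0
    perfusion_index: float = 2.0
    dc_red: float = 2.0
    dc_ir: float = 2.0
    noise_sd: float = 0.0
    ambient_level: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 70.0 <= self.true_spo2 <= 100.0:
            raise ValidationError(f"true_spo2 {self.true_spo2} outside [70, 100]")
        if not 30.0 <= self.heart_rate <= 240.0:
            raise ValidationError(f"heart_rate {self.heart_rate} outside [30, 240]")
        if self.perfusion_index <= 0:
            raise ValidationError("perfusion_index must be > 0")
        if self.dc_red <= 0 or self.dc_ir <= 0:
            raise ValidationError("dc levels must be > 0")
        if self.noise_sd < 0 or self.ambient_level < 0:
            raise ValidationError("noise_sd and ambient_level must be >= 0")

    @property
    def target_ratio(self) -> float:
        """Ratio-of-ratios implied by the calibration SpO2 = 110 - 25 R."""
        return (110.0 - self.true_spo2) / 25.0

    @property
    def ac_ir(self) -> float:
        """Infra-red pulsatile peak-to-peak amplitude."""
        return self.perfusion_index / 100.0 * self.dc_ir

    @property
    def ac_red(self) -> float:
        """Red pulsatile peak-to-peak amplitude solving the target ratio."""
        return self.target_ratio * self.perfusion_index / 100.0 * self.dc_red


@dataclass
class TruthTrajectory:
    """Per-sample generating physiology carried with a stream."""

    true_spo2: np.ndarray
    heart_rate: np.ndarray
    perfusion_index: np.ndarray
    valid: np.ndarray  # bool, False inside no-finger dropouts

    def __len__(self) -> int:
        return len(self.true_spo2)

    def copy(self) -> "TruthTrajectory":
        return TruthTrajectory(
            self.true_spo2.copy(),
            self.heart_rate.copy(),
            self.perfusion_index.copy(),
            self.valid.copy(),
        )


@dataclass
class MultiplexedStream:
    """Raw slot-multiplexed photodiode samples plus generating truth."""

    sample_rate: float
    samples: np.ndarray
    slot_labels: np.ndarray
    truth: TruthTrajectory
    ambient_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    t0: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sample_rate

    def copy(self) -> "MultiplexedStream":
        return MultiplexedStream(
            sample_rate=self.sample_rate,
            samples=self.samples.copy(),
            slot_labels=self.slot_labels.copy(),
            truth=self.truth.copy(),
            ambient_level=self.ambient_level,
            noise_sd=self.noise_sd,
            seed=self.seed,
            t0=self.t0,
        )


class StreamSynthesizer:
    """Stateful generator emitting multiplexed frames with phase continuity.

    Used directly by the closed-loop session, where the true SpO2 changes
    every second while the cardiac phase and noise stream must continue
    smoothly across the per-second chunks.
    """

    def __init__(self, profile: PhysioProfile, sample_rate: float = DEFAULT_SAMPLE_RATE):
        profile.validate()
        if sample_rate <= 0 or sample_rate % SLOTS_PER_CYCLE:
            raise ConfigurationError(
                f"sample_rate {sample_rate} must be positive and divisible by {SLOTS_PER_CYCLE}"
            )
        self.profile = profile
        self.sample_rate = float(sample_rate)
        self._phase = 0.0
        self._t = 0.0
        self._rng = np.random.default_rng(profile.seed)

    def update_profile(self, **changes) -> None:
        """Change physiology for subsequent frames (phase/noise continue)."""
        self.profile = replace(self.profile, **changes)
        self.profile.validate()

    def emit(self, duration: float) -> MultiplexedStream:
        """Generate ``duration`` seconds of multiplexed samples."""
        if duration <= 0:
            raise ConfigurationError("duration must be > 0")
        n_frames = int(round(duration * self.sample_rate / SLOTS_PER_CYCLE))
        if n_frames < 1:
            raise ConfigurationError("duration shorter than one LED cycle")
        n = n_frames * SLOTS_PER_CYCLE
        p = self.profile
        fs = self.sample_rate

        idx = np.arange(n)
        slots = np.array([s.value for s in SLOT_CYCLE])[idx % SLOTS_PER_CYCLE]
        phase = self._phase + 2.0 * np.pi * (p.heart_rate / 60.0) * idx / fs
        pulse = _unit_pulse(phase)

        values = np.full(n, p.ambient_level, dtype=float)
        red = slots == SlotLabel.RED_ON
        ir = slots == SlotLabel.IR_ON
        values[red] += p.dc_red + p.ac_red * pulse[red]
        values[ir] += p.dc_ir + p.ac_ir * pulse[ir]
        if p.noise_sd > 0:
            values += self._rng.normal(0.0, p.noise_sd, size=n)

        truth = TruthTrajectory(
            true_spo2=np.full(n, p.true_spo2),
            heart_rate=np.full(n, p.heart_rate),
            perfusion_index=np.full(n, p.perfusion_index),
            valid=np.ones(n, dtype=bool),
        )
        stream = MultiplexedStream(
            sample_rate=fs,
            samples=values,
            slot_labels=slots,
            truth=truth,
            ambient_level=p.ambient_level,
            noise_sd=p.noise_sd,
            seed=p.seed,
            t0=self._t,
        )
        self._phase = float(phase[-1] + 2.0 * np.pi * (p.heart_rate / 60.0) / fs) % (2.0 * np.pi)
        self._t += n / fs
        return stream


def synthesize_stream(
    profile: PhysioProfile,
    duration: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> MultiplexedStream:
    """One-shot synthesis of a multiplexed stream from a constant profile."""
    return StreamSynthesizer(profile, sample_rate).emit(duration)


def concatenate(streams: list[MultiplexedStream]) -> MultiplexedStream:
    """Join streams end to end (piecewise-constant physiology steps)."""
    if not streams:
        raise ValidationError("need at least one stream")
    first = streams[0]
    for s in streams[1:]:
        if s.sample_rate != first.sample_rate:
            raise ValidationError("sample rates differ")
    return MultiplexedStream(
        sample_rate=first.sample_rate,
        samples=np.concatenate([s.samples for s in streams]),
        slot_labels=np.concatenate([s.slot_labels for s in streams]),
        truth=TruthTrajectory(
            np.concatenate([s.truth.true_spo2 for s in streams]),
            np.concatenate([s.truth.heart_rate for s in streams]),
            np.concatenate([s.truth.perfusion_index for s in streams]),
            np.concatenate([s.truth.valid for s in streams]),
        ),
        ambient_level=first.ambient_level,
        noise_sd=first.noise_sd,
        seed=first.seed,
        t0=first.t0,
    )


# ---------------------------------------------------------------------------
# artifacts


@dataclass(frozen=True)
class NoFinger:
    """Probe empty: pulsatile light vanishes, detector falls to ambient."""

    start: float
    end: float


@dataclass(frozen=True)
class MotionBurst:
    """Additive interference tone (default mains-like 50 Hz) on all slots."""

    start: float
    end: float
    amplitude: float
    freq: float = 50.0


@dataclass(frozen=True)
class BaselineDrift:
    """Linear baseline ramp from 0 to ``delta`` across the interval."""

    start: float
    end: float
    delta: float


ArtifactSpec = list


def _check_intervals(events, kind: type) -> None:
    same = sorted((e.start, e.end) for e in events if isinstance(e, kind))
    for (s1, e1), (s2, _) in zip(same, same[1:]):
        if s2 < e1:
            raise ValidationError(f"overlapping {kind.__name__} intervals")
    for s, e in same:
        if e <= s:
            raise ValidationError(f"{kind.__name__} interval must have end > start")


def inject_artifacts(stream: MultiplexedStream, artifacts: ArtifactSpec) -> MultiplexedStream:
    """Overlay typed artifact events on a copy of ``stream``.

    No-finger dropouts zero the pulsatile component and collapse the DC to
    the ambient floor (fresh seeded noise replaces the original samples);
    the truth trajectory flags those samples invalid. Motion bursts and
    baseline drifts add to the recorded samples without touching validity.
    """
    for kind in (NoFinger, MotionBurst, BaselineDrift):
        _check_intervals(artifacts, kind)
    out = stream.copy()
    t = out.times
    rng = np.random.default_rng((stream.seed, 0xA57E))
    for ev in artifacts:
        mask = (t >= ev.start) & (t < ev.end)
        if isinstance(ev, NoFinger):
            out.samples[mask] = out.ambient_level
            if out.noise_sd > 0:
                out.samples[mask] += rng.normal(0.0, out.noise_sd, size=int(mask.sum()))
            out.truth.valid[mask] = False
        elif isinstance(ev, MotionBurst):
            out.samples[mask] += ev.amplitude * np.sin(2.0 * np.pi * ev.freq * t[mask])
        elif isinstance(ev, BaselineDrift):
            span = max(ev.end - ev.start, np.finfo(float).tiny)
            out.samples[mask] += ev.delta * (t[mask] - ev.start) / span
        else:
            raise ValidationError(f"unknown artifact type {type(ev).__name__}")
    return out


# ---------------------------------------------------------------------------
# truth aggregation and serialization


def truth_series(stream: MultiplexedStream) -> pd.DataFrame:
    """Per-second ground-truth vitals, one row per whole second [t, t+1).

    A second is valid only if every sample inside it is valid; physiology
    columns are the within-second means (exact for piecewise-constant truth).
    """
    n_sec = int(stream.duration)
    fs = stream.sample_rate
    rows = []
    for k in range(n_sec):
        lo, hi = int(round(k * fs)), int(round((k + 1) * fs))
        rows.append(
            {
                "t": stream.t0 + k,
                "true_spo2": float(stream.truth.true_spo2[lo:hi].mean()),
                "true_hr": float(stream.truth.heart_rate[lo:hi].mean()),
                "true_pi": float(stream.truth.perfusion_index[lo:hi].mean()),
                "valid": bool(stream.truth.valid[lo:hi].all()),
            }
        )
    return pd.DataFrame(rows, columns=["t", "true_spo2", "true_hr", "true_pi", "valid"])


def save_stream(stream: MultiplexedStream, prefix: str | Path) -> tuple[Path, Path]:
    """Write a stream as a JSON header + CSV sample table pair.

    The CSV columns are ``index,time_s,slot_label,value``; the header keeps
    the rate and generation metadata. The truth trajectory is regenerable
    from the profile and is not serialized.
    """
    prefix = Path(prefix)
    header_path = prefix.with_suffix(".json")
    csv_path = prefix.with_suffix(".csv")
    header = {
        "sample_rate": stream.sample_rate,
        "ambient_level": stream.ambient_level,
        "noise_sd": stream.noise_sd,
        "seed": stream.seed,
        "t0": stream.t0,
        "n_samples": len(stream.samples),
    }
    header_path.write_text(json.dumps(header, indent=1) + "\n")
    df = pd.DataFrame(
        {
            "index": np.arange(len(stream.samples)),
            "time_s": stream.times,
            "slot_label": [SlotLabel(s).name for s in stream.slot_labels],
            "value": stream.samples,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    return header_path, csv_path


def load_stream(prefix: str | Path) -> MultiplexedStream:
    """Read back a header+CSV pair written by :func:`save_stream`.

    The loaded stream carries a neutral all-valid truth trajectory (NaN
    physiology): serialized streams are signal data, not ground truth.
    """
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    labels = np.array([SlotLabel[name].value for name in df["slot_label"]])
    n = len(df)
    truth = TruthTrajectory(
        np.full(n, np.nan), np.full(n, np.nan), np.full(n, np.nan), np.ones(n, dtype=bool)
    )
    return MultiplexedStream(
        sample_rate=header["sample_rate"],
        samples=df["value"].to_numpy(float),
        slot_labels=labels,
        truth=truth,
        ambient_level=header["ambient_level"],
        noise_sd=header["noise_sd"],
        seed=header["seed"],
        t0=header["t0"],
    )
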