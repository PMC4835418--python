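"""LED-slot demultiplexing, ambient correction and signal-presence detection.

The acquisition contract: the A/D samples the photodiode once per LED slot
in the fixed cycle RED_ON, BOTH_OFF, IR_ON, BOTH_OFF, so each optical
channel runs at a quarter of the acquisition rate and the dark reference at
half of it. Synchronization between LED switching and sampling is critical;
when slot labels are missing the demultiplexer resynchronizes by scanning
the four possible cycle phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, StreamCorruptionError, ValidationError
from .ppg_synth import SLOT_CYCLE, SLOTS_PER_CYCLE, MultiplexedStream, SlotLabel


def led_slot(cycle_index: int) -> SlotLabel:
    """Slot label for acquisition sample ``cycle_index`` (0-based)."""
    if cycle_index < 0:
        raise ValidationError("cycle_index must be >= 0")
    return SLOT_CYCLE[cycle_index % SLOTS_PER_CYCLE]


@dataclass
class ChannelBundle:
    """Demultiplexed Red / Infra-red / dark-reference sample series.

    ``red`` and ``infrared`` run at ``fs_channel`` (acquisition rate / 4);
    ``reference`` holds the two dark slots per cycle, at twice that rate.
    """

    fs_channel: float
    red: np.ndarray
    infrared: np.ndarray
    reference: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if len(self.red) != len(self.infrared):
            raise ValidationError("red and infrared lengths differ")
        if len(self.reference) != 2 * len(self.red):
            raise ValidationError("reference must hold two samples per cycle")

    def __len__(self) -> int:
        return len(self.red)

    @property
    def duration(self) -> float:
        return len(self.red) / self.fs_channel

    def segment(self, start_s: float, end_s: float) -> "ChannelBundle":
        lo = int(round((start_s - self.t0) * self.fs_channel))
        hi = int(round((end_s - self.t0) * self.fs_channel))
        return ChannelBundle(
            fs_channel=self.fs_channel,
            red=self.red[lo:hi],
            infrared=self.infrared[lo:hi],
            reference=self.reference[2 * lo : 2 * hi],
            t0=self.t0 + lo / self.fs_channel,
        )

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: time, red, infrared, cycle-averaged reference."""
        ref = self.reference.reshape(-1, 2).mean(axis=1)
        t = self.t0 + np.arange(len(self.red)) / self.fs_channel
        return pd.DataFrame(
            {"time_s": t, "red": self.red, "infrared": self.infrared, "reference": ref}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _find_cycle_phase(labels: np.ndarray) -> int:
    """Cycle phase (0-3) minimizing label violations against SLOT_CYCLE."""
    expected = np.array([s.value for s in SLOT_CYCLE])
    best_phase, best_violations = 0, None
    n = len(labels)
    for phase in range(SLOTS_PER_CYCLE):
        want = expected[(np.arange(n) + phase) % SLOTS_PER_CYCLE]
        violations = int(np.count_nonzero(labels != want))
        if best_violations is None or violations < best_violations:
            best_phase, best_violations = phase, violations
    return best_phase


def demultiplex(stream: MultiplexedStream, strict: bool = True) -> ChannelBundle:
    """Split a multiplexed stream into per-channel series by LED slot.

    Streams must start on a RED_ON slot; a trailing partial cycle is
    discarded. With ``strict`` (default) any label deviating from the
    four-slot cycle raises :class:`StreamCorruptionError`; otherwise the
    cycle phase is re-derived by scanning for the alignment with fewest
    violations (the labels-absent / desynchronized case).
    """
    labels = np.asarray(stream.slot_labels)
    n_cycles = len(labels) // SLOTS_PER_CYCLE
    if n_cycles == 0:
        raise InsufficientDataError("stream shorter than one LED cycle")
    n = n_cycles * SLOTS_PER_CYCLE
    labels = labels[:n]
    samples = np.asarray(stream.samples)[:n]

    expected = np.array([s.value for s in SLOT_CYCLE])[np.arange(n) % SLOTS_PER_CYCLE]
    if strict:
        bad = np.nonzero(labels != expected)[0]
        if bad.size:
            got = int(labels[bad[0]])
            name = SlotLabel(got).name if got in SlotLabel._value2member_map_ else got
            raise StreamCorruptionError(
                f"slot label at index {bad[0]} breaks the LED cycle (got {name})"
            )
        phase = 0
    else:
        phase = _find_cycle_phase(labels)
        if phase:
            samples = samples[phase:]
            n_cycles = len(samples) // SLOTS_PER_CYCLE
            samples = samples[: n_cycles * SLOTS_PER_CYCLE]

    frames = samples.reshape(-1, SLOTS_PER_CYCLE)
    return ChannelBundle(
        fs_channel=stream.sample_rate / SLOTS_PER_CYCLE,
        red=frames[:, 0].copy(),
        infrared=frames[:, 2].copy(),
        reference=frames[:, [1, 3]].reshape(-1).copy(),
        t0=stream.t0 + phase / stream.sample_rate,
    )


def ambient_correct(bundle: ChannelBundle) -> ChannelBundle:
    """Subtract the temporally nearest dark-reference sample per channel.

    Within a cycle (r, a1, i, a2): the Red slot is equidistant from the
    previous cycle's a2 and this cycle's a1 — ties resolve to the earlier
    sample, except at the stream head where only a1 exists. The Infra-red
    slot ties between a1 and a2 and takes a1. The reference series is
    retained unchanged for diagnostics.
    """
    ref = bundle.reference.reshape(-1, 2)  # columns: a1 (slot 1), a2 (slot 3)
    red_ref = np.empty(len(bundle.red))
    red_ref[0] = ref[0, 0]  # no earlier cycle: use following a1
    red_ref[1:] = ref[:-1, 1]  # earlier of the equidistant pair: previous a2
    ir_ref = ref[:, 0]  # earlier of the equidistant pair: same-cycle a1
    return replace(
        bundle,
        red=bundle.red - red_ref,
        infrared=bundle.infrared - ir_ref,
        reference=bundle.reference.copy(),
    )


@dataclass(frozen=True)
class SignalThresholds:
    """Floors deciding whether a finger is in the probe.

    ``dc_floor`` is 5 % of the generator's nominal Infra-red DC level (2.0);
    ``pi_floor`` is the minimum believable perfusion index in percent.
    """

    dc_floor: float = 0.1
    pi_floor: float = 0.1

    def decide(self, dc_level: float, perfusion_pct: float) -> bool:
        return bool(dc_level >= self.dc_floor and perfusion_pct >= self.pi_floor)


def signal_present(
    window: ChannelBundle,
    thresholds: SignalThresholds | None = None,
) -> bool:
    """True iff the (ambient-corrected) window contains a pulsatile PPG.

    Requires at least one second of channel samples. The Infra-red DC level
    must clear ``dc_floor`` and the pulsatile contrast extracted by the
    filter cascade must clear ``pi_floor`` percent of that DC.
    """
    from .dsp_chain import extract_components  # local import: avoid cycle

    if thresholds is None:
        thresholds = SignalThresholds()
    if len(window) < window.fs_channel:
        raise InsufficientDataError("signal_present needs >= 1 s of samples")
    comp = extract_components(window.infrared, window.fs_channel)
    lo = min(comp.warmup_samples, max(len(window) - int(window.fs_channel), 0))
    dc_level = float(np.mean(comp.dc[lo:]))
    ac_pp = float(np.ptp(comp.ac[lo:]))
    if dc_level <= 0:
        return False
    return thresholds.decide(dc_level, 100.0 * ac_pp / dc_level)
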