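"""Per-second SpO2, heart-rate and perfusion-index estimation.

Each second the estimator takes the newly acquired, ambient-corrected Red
and Infra-red channel samples, pushes them through the streaming filter
cascade, and computes over a sliding analysis window:

* the ratio of ratios R = (AC_red/DC_red) / (AC_ir/DC_ir), with AC measured
  as the mean per-beat peak-to-peak amplitude and DC as the window mean of
  the baseline track;
* SpO2 from the empirical calibration SpO2 = 110 - 25 R, clamped to
  [0, 100] (the raw line exceeds 100 for R < 0.4 and saturation is a
  percentage of total haemoglobin);
* heart rate from the average number of samples per detected heart pulse,
  HR = fs * 60 / (n_samples / n_pulses);
* perfusion index PI = 100 * AC_ir / DC_ir.

SpO2 and heart rate are stabilized by a weighted moving average over the
last five per-second values with linearly increasing weights, so the most
recent second weighs most. Exactly one record is emitted per second;
seconds without a detectable finger signal yield invalid records carrying
no vitals.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .acquisition import ChannelBundle, SignalThresholds, ambient_correct, demultiplex
from .dsp_chain import ComponentExtractor
from .errors import InsufficientDataError, ParseError, ValidationError
from .ppg_synth import MultiplexedStream

#: Minimum believable inter-beat interval: the 4 Hz PPG band ceiling.
REFRACTORY_S = 0.25


def compute_ratio(ac_red: float, dc_red: float, ac_ir: float, dc_ir: float) -> float:
    """Ratio of ratios R = (AC_red/DC_red) / (AC_ir/DC_ir)."""
    if dc_red <= 0 or dc_ir <= 0 or ac_ir <= 0 or ac_red < 0:
        raise ValidationError("ratio inputs must be positive (ac_red >= 0)")
    return (ac_red / dc_red) / (ac_ir / dc_ir)


def spo2_from_ratio(r: float) -> float:
    """Empirical calibration SpO2 = 110 - 25 R, clamped to [0, 100] %."""
    if r < 0:
        raise ValidationError("R must be >= 0")
    return float(min(max(110.0 - 25.0 * r, 0.0), 100.0))


def detect_pulses(ac: np.ndarray, fs: float) -> np.ndarray:
    """Indices of systolic peaks in a pulsatile series.

    A 0.25 s refractory interval (the 4 Hz band ceiling) separates peaks;
    candidate peaks need prominence of a quarter of the window's
    peak-to-peak span, which rejects dicrotic ripple and noise wiggles.
    Flat input yields zero pulses.
    """
    ac = np.asarray(ac, float)
    span = float(np.ptp(ac)) if ac.size else 0.0
    if span <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(ac, distance=max(int(round(REFRACTORY_S * fs)), 1), prominence=0.25 * span)
    return peaks


def heart_rate(fs: float, n_samples: float, n_pulses: float) -> float:
    """Beats per minute from the average samples-per-pulse count."""
    if n_pulses < 1 or n_samples < 1:
        raise ValidationError("need n_pulses >= 1 and n_samples >= 1")
    return fs * 60.0 / (n_samples / n_pulses)


def perfusion_index(ac_ir: float, dc_ir: float) -> float:
    """PI = 100 * AC_ir / DC_ir, in percent."""
    if dc_ir <= 0:
        raise ValidationError("dc_ir must be > 0")
    return 100.0 * ac_ir / dc_ir


def smooth_wma(history, weights) -> float:
    """Weighted moving average; short histories truncate and renormalize.

    ``weights`` are ordered oldest to newest and must be positive; when the
    history is shorter than the weight vector the newest weights are used.
    """
    hist = np.asarray(list(history), float)
    w = np.asarray(list(weights), float)
    if hist.size == 0:
        raise ValidationError("history must be non-empty")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    if hist.size < w.size:
        w = w[-hist.size :]
    elif hist.size > w.size:
        raise ValidationError("history longer than weight vector")
    return float(np.dot(hist, w / w.sum()))


@dataclass
class VitalsRecord:
    """One-per-second wire record sent to the delivery subsystem."""

    t: float
    spo2: float | None
    heart_rate: float | None
    perfusion_index: float | None
    valid: bool
    r_ratio: float | None

    def __post_init__(self) -> None:
        if not self.valid:
            if any(v is not None for v in (self.spo2, self.heart_rate, self.perfusion_index, self.r_ratio)):
                raise ValidationError("invalid records carry no vitals values")
        else:
            if not 0.0 <= self.spo2 <= 100.0:
                raise ValidationError(f"spo2 {self.spo2} outside [0, 100]")
            if not 30.0 <= self.heart_rate <= 240.0:
                raise ValidationError(f"heart_rate {self.heart_rate} outside [30, 240]")
            if self.perfusion_index <= 0:
                raise ValidationError("perfusion_index must be > 0")

    @classmethod
    def invalid_at(cls, t: float) -> "VitalsRecord":
        return cls(t=t, spo2=None, heart_rate=None, perfusion_index=None, valid=False, r_ratio=None)


class VitalsEstimator:
    """Streaming per-second vitals pipeline for one two-wavelength sensor.

    Parameters
    ----------
    fs_channel : float
        Per-channel sample rate (125 at the default 500 S/s acquisition).
    window_s : float
        Sliding analysis window for pulse detection and amplitude
        aggregation; 8 s gives at least four beats at the 30 bpm floor.
    wma_window : int
        Seconds of history in the weighted moving average.
    thresholds : SignalThresholds
        Finger-presence floors applied to the latest one-second slice.
    """

    def __init__(
        self,
        fs_channel: float = 125.0,
        window_s: float = 8.0,
        wma_window: int = 5,
        thresholds: SignalThresholds | None = None,
    ):
        if window_s < 2.0:
            raise ValidationError("analysis window must span >= 2 s")
        self.fs = float(fs_channel)
        self.window_n = int(round(window_s * fs_channel))
        self.thresholds = thresholds or SignalThresholds()
        self._red = ComponentExtractor(fs_channel)
        self._ir = ComponentExtractor(fs_channel)
        maxlen = self.window_n
        self._buf = {
            k: deque(maxlen=maxlen) for k in ("ac_red", "dc_red", "ac_ir", "dc_ir")
        }
        self._wma_weights = np.arange(1, wma_window + 1, dtype=float)
        self._spo2_hist: deque = deque(maxlen=wma_window)
        self._hr_hist: deque = deque(maxlen=wma_window)

    def reset(self) -> None:
        """Drop all streaming state (used after a watchdog restart)."""
        self._red.reset()
        self._ir.reset()
        for b in self._buf.values():
            b.clear()
        self._spo2_hist.clear()
        self._hr_hist.clear()

    # -- per-second core ----------------------------------------------------

    def tick(self, t: float, red: np.ndarray, infrared: np.ndarray) -> VitalsRecord:
        """Consume one second of corrected channel samples, emit one record."""
        n_sec = int(round(self.fs))
        if len(red) != n_sec or len(infrared) != n_sec:
            raise InsufficientDataError("tick expects exactly one second per channel")
        red_pair = self._red.process(red)
        ir_pair = self._ir.process(infrared)
        for name, arr in (
            ("ac_red", red_pair.ac),
            ("dc_red", red_pair.dc),
            ("ac_ir", ir_pair.ac),
            ("dc_ir", ir_pair.dc),
        ):
            self._buf[name].extend(arr)

        if not self._finger_present(infrared):
            # restart the signal path: holding filter state across a probe
            # removal would leave a DC-step transient dwarfing the pulsatile
            # signal for many seconds after the finger returns
            self._red.reset()
            self._ir.reset()
            for b in self._buf.values():
                b.clear()
            return VitalsRecord.invalid_at(t)

        ac_ir = np.array(self._buf["ac_ir"])
        peaks = detect_pulses(ac_ir, self.fs)
        if len(peaks) < 2:
            return VitalsRecord.invalid_at(t)

        ac_red = np.array(self._buf["ac_red"])
        ac_red_amp = self._mean_beat_p2p(ac_red, peaks)
        ac_ir_amp = self._mean_beat_p2p(ac_ir, peaks)
        dc_red = float(np.mean(self._buf["dc_red"]))
        dc_ir = float(np.mean(self._buf["dc_ir"]))
        if min(dc_red, dc_ir, ac_ir_amp) <= 0:
            return VitalsRecord.invalid_at(t)

        r = compute_ratio(ac_red_amp, dc_red, ac_ir_amp, dc_ir)
        spo2_raw = spo2_from_ratio(r)
        # average samples per pulse over complete inter-beat intervals
        hr_raw = heart_rate(self.fs, float(peaks[-1] - peaks[0]), float(len(peaks) - 1))
        pi = perfusion_index(ac_ir_amp, dc_ir)
        if not 30.0 <= hr_raw <= 240.0:
            return VitalsRecord.invalid_at(t)

        self._spo2_hist.append(spo2_raw)
        self._hr_hist.append(hr_raw)
        return VitalsRecord(
            t=t,
            spo2=smooth_wma(self._spo2_hist, self._wma_weights),
            heart_rate=smooth_wma(self._hr_hist, self._wma_weights),
            perfusion_index=pi,
            valid=True,
            r_ratio=r,
        )

    def _finger_present(self, raw_ir_second: np.ndarray) -> bool:
        # DC from the raw corrected samples, not the 0.1 Hz track: the track
        # lags a probe removal by many seconds, the raw mean collapses at once.
        n_sec = int(round(self.fs))
        dc_level = float(np.mean(raw_ir_second))
        ac_last = np.array(self._buf["ac_ir"])[-n_sec:]
        if dc_level <= 0:
            return False
        return self.thresholds.decide(dc_level, 100.0 * float(np.ptp(ac_last)) / dc_level)

    @staticmethod
    def _mean_beat_p2p(ac: np.ndarray, peaks: np.ndarray) -> float:
        """Mean peak-to-peak amplitude across complete inter-beat intervals."""
        spans = [float(np.ptp(ac[a : b + 1])) for a, b in zip(peaks[:-1], peaks[1:])]
        return float(np.mean(spans))


def estimate_stream(
    stream: MultiplexedStream,
    estimator: VitalsEstimator | None = None,
) -> list[VitalsRecord]:
    """Run the full reader pipeline over a multiplexed stream.

    Demultiplexes, ambient-corrects, then emits one VitalsRecord per whole
    second of the recording.
    """
    bundle = ambient_correct(demultiplex(stream))
    if estimator is None:
        estimator = VitalsEstimator(fs_channel=bundle.fs_channel)
    n_sec = int(bundle.duration)
    fs = bundle.fs_channel
    records = []
    for k in range(n_sec):
        lo, hi = int(round(k * fs)), int(round((k + 1) * fs))
        records.append(
            estimator.tick(stream.t0 + k, bundle.red[lo:hi], bundle.infrared[lo:hi])
        )
    return records


# ---------------------------------------------------------------------------
# wire-format serialization (the payload handed to the controller transport)

_VITALS_COLUMNS = ["t", "spo2", "hr", "pi", "valid", "r_ratio"]


def records_to_frame(records: list[VitalsRecord]) -> pd.DataFrame:
    rows = [
        {
            "t": r.t,
            "spo2": r.spo2,
            "hr": r.heart_rate,
            "pi": r.perfusion_index,
            "valid": r.valid,
            "r_ratio": r.r_ratio,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_VITALS_COLUMNS)


def _record_from_row(row: dict) -> VitalsRecord:
    def _num(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    valid = bool(row["valid"])
    return VitalsRecord(
        t=float(row["t"]),
        spo2=_num(row["spo2"]) if valid else None,
        heart_rate=_num(row["hr"]) if valid else None,
        perfusion_index=_num(row["pi"]) if valid else None,
        valid=valid,
        r_ratio=_num(row["r_ratio"]) if valid else None,
    )


def write_vitals_csv(records: list[VitalsRecord], path: str | Path) -> None:
    # %.17g guarantees exact float round-trips through the text format
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_vitals_csv(path: str | Path) -> list[VitalsRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_VITALS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing vitals columns {sorted(missing)}")
    return [_record_from_row(row) for row in df.to_dict("records")]


def write_vitals_jsonl(records: list[VitalsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "t": r.t,
                        "spo2": r.spo2,
                        "hr": r.heart_rate,
                        "pi": r.perfusion_index,
                        "valid": r.valid,
                        "r_ratio": r.r_ratio,
                    }
                )
                + "\n"
            )


def read_vitals_jsonl(path: str | Path) -> list[VitalsRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        row = json.loads(line)
        missing = set(_VITALS_COLUMNS) - set(row)
        if missing:
            raise ParseError(f"{path}:{lineno}: missing fields {sorted(missing)}")
        records.append(_record_from_row(row))
    return records
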