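"""Delivery-side logic: display, titration, valve mapping and watchdog.

The delivery subsystem receives one vitals record per second. A record
without a PPG reading immediately stops oxygen delivery and shows
"Please Insert Your Finger"; a valid record updates the display with
(SpO2, HR, PI). The supplemental flow itself changes at most once per
minute: a simple fixed-step titration toward the 94-98 % saturation band
recommended for most acutely ill patients — below the band step the flow
up, above it step down, inside it hold, always clipped to [0, max_flow].
Commanded flow maps affinely to the proportional solenoid valve's drive
voltage. A watchdog stops delivery and resets the pipeline whenever no
record has arrived for over a minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import ParseError, ProtocolError, ValidationError
from .vitals_estimation import VitalsRecord

NO_FINGER_MESSAGE = "Please Insert Your Finger"


class CommandReason(str, Enum):
    TITRATE_UP = "titrate_up"
    TITRATE_DOWN = "titrate_down"
    HOLD = "hold"
    NO_SIGNAL_STOP = "no_signal_stop"
    WATCHDOG_STOP = "watchdog_stop"


@dataclass(frozen=True)
class ValveCommand:
    t: float
    flow: float  # L/min
    voltage: float  # V
    reason: CommandReason

    def __post_init__(self) -> None:
        if self.reason in (CommandReason.NO_SIGNAL_STOP, CommandReason.WATCHDOG_STOP):
            if self.flow != 0.0:
                raise ValidationError("stop commands must carry zero flow")


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable delivery-side parameters.

    step : titration increment, L/min per adjustment (default 0.5)
    max_flow : valve ceiling, L/min (default 15)
    v_max : valve drive voltage at max_flow, V (default 10)
    band : target saturation band, percent (default (94, 98))
    adjust_period_s : minimum spacing of flow adjustments (default 60 s)
    watchdog_s : staleness limit before a forced stop/restart (default 60 s)
    source_pressure_psi : supply pressure, recorded for realism only
    """

    step: float = 0.5
    max_flow: float = 15.0
    v_max: float = 10.0
    band: tuple[float, float] = (94.0, 98.0)
    adjust_period_s: float = 60.0
    watchdog_s: float = 60.0
    source_pressure_psi: float = 50.0

    def validate(self) -> None:
        if self.step <= 0 or self.max_flow <= 0 or self.v_max <= 0:
            raise ValidationError("step, max_flow and v_max must be > 0")
        lo, hi = self.band
        if not 0 < lo < hi <= 100:
            raise ValidationError(f"band {self.band} must satisfy 0 < low < high <= 100")
        if self.adjust_period_s <= 0 or self.watchdog_s <= 0:
            raise ValidationError("periods must be > 0")


@dataclass
class ControllerState:
    current_flow: float = 0.0
    last_adjust_t: float = 0.0
    last_record_t: float = 0.0
    display: str = ""
    stalled: bool = False


def decide_flow(state: ControllerState, smoothed_spo2: float, config: ControllerConfig) -> float:
    """Fixed-step titration toward the target band, clipped to [0, max_flow]."""
    lo, hi = config.band
    flow = state.current_flow
    if smoothed_spo2 < lo:
        flow += config.step
    elif smoothed_spo2 > hi:
        flow -= config.step
    return min(max(flow, 0.0), config.max_flow)


def valve_voltage(flow: float, config: ControllerConfig) -> float:
    """Affine flow-to-voltage map for the proportional solenoid valve."""
    if not 0.0 <= flow <= config.max_flow:
        raise ValidationError(f"flow {flow} outside [0, {config.max_flow}]")
    return config.v_max * flow / config.max_flow


def handle_record(
    state: ControllerState, record: VitalsRecord, config: ControllerConfig
) -> tuple[ControllerState, str, ValveCommand | None]:
    """Process one received vitals record.

    Invalid records stop delivery immediately (flow 0, no-signal reason).
    Valid records refresh the display; the flow is re-decided only once the
    per-minute adjustment boundary has passed, and a command (titrate or
    hold) is logged at each such boundary.
    """
    if record.t < state.last_record_t:
        raise ProtocolError(
            f"record at t={record.t} older than last seen t={state.last_record_t}"
        )
    state.last_record_t = record.t
    state.stalled = False

    if not record.valid:
        state.display = NO_FINGER_MESSAGE
        state.current_flow = 0.0
        return state, state.display, ValveCommand(
            t=record.t, flow=0.0, voltage=0.0, reason=CommandReason.NO_SIGNAL_STOP
        )

    state.display = (
        f"SpO2 {record.spo2:.1f}%  HR {record.heart_rate:.0f} bpm  "
        f"PI {record.perfusion_index:.2f}%"
    )
    command = None
    if record.t - state.last_adjust_t >= config.adjust_period_s:
        new_flow = decide_flow(state, record.spo2, config)
        if new_flow > state.current_flow:
            reason = CommandReason.TITRATE_UP
        elif new_flow < state.current_flow:
            reason = CommandReason.TITRATE_DOWN
        else:
            reason = CommandReason.HOLD
        state.current_flow = new_flow
        state.last_adjust_t = record.t
        command = ValveCommand(
            t=record.t, flow=new_flow, voltage=valve_voltage(new_flow, config), reason=reason
        )
    return state, state.display, command


def watchdog_check(
    state: ControllerState, now: float, config: ControllerConfig
) -> ValveCommand | None:
    """Stop delivery once the record stream is stale for over the limit.

    Fires exactly once per stall episode; a fresh record re-arms it.
    """
    if state.stalled or now - state.last_record_t <= config.watchdog_s:
        return None
    state.stalled = True
    state.current_flow = 0.0
    state.display = NO_FINGER_MESSAGE
    return ValveCommand(t=now, flow=0.0, voltage=0.0, reason=CommandReason.WATCHDOG_STOP)


# ---------------------------------------------------------------------------
# command-log serialization

_COMMAND_COLUMNS = ["t", "flow", "voltage", "reason"]


def commands_to_frame(commands: list[ValveCommand]) -> pd.DataFrame:
    rows = [
        {"t": c.t, "flow": c.flow, "voltage": c.voltage, "reason": c.reason.value}
        for c in commands
    ]
    return pd.DataFrame(rows, columns=_COMMAND_COLUMNS)


def write_commands_csv(commands: list[ValveCommand], path: str | Path) -> None:
    commands_to_frame(commands).to_csv(path, index=False, float_format="%.17g")


def read_commands_csv(path: str | Path) -> list[ValveCommand]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COMMAND_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing command columns {sorted(missing)}")
    return [
        ValveCommand(
            t=float(r["t"]),
            flow=float(r["flow"]),
            voltage=float(r["voltage"]),
            reason=CommandReason(r["reason"]),
        )
        for r in df.to_dict("records")
    ]


def write_commands_jsonl(commands: list[ValveCommand], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in commands:
            fh.write(
                json.dumps({"t": c.t, "flow": c.flow, "voltage": c.voltage, "reason": c.reason.value})
                + "\n"
            )
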