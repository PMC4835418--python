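"""Closed-loop session runner and log/config I/O.

Wires the two subsystems together through a transport abstraction standing
in for the Bluetooth link, against the virtual patient:

    patient -> PPG synthesis -> demux/correct -> filter -> estimate
            -> transmit -> controller -> valve flow -> patient

The simulation clock is a discrete 1 s controller tick (matching the
per-second record cadence), with the sample-rate signal work done inside
each tick. Every source of randomness is derived from the single session
seed, so a (config, seed) pair fully determines every log byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import ambient_correct, demultiplex
from .errors import ConfigurationError, ParseError
from .oxygen_controller import (
    CommandReason,
    ControllerConfig,
    ControllerState,
    ValveCommand,
    commands_to_frame,
    handle_record,
    watchdog_check,
    write_commands_csv,
)
from .patient_model import PatientState, VirtualPatient
from .ppg_synth import PhysioProfile, StreamSynthesizer
from .vitals_estimation import (
    VitalsEstimator,
    VitalsRecord,
    records_to_frame,
    write_vitals_csv,
)


@dataclass
class TransportLink:
    """Lossy, delaying record channel between the two subsystems.

    Each offered record is delivered after ``latency_s`` with probability
    1 - ``drop_prob`` (seeded). Dropped records feed the controller's
    staleness/watchdog path. Defaults are lossless and instantaneous.
    """

    drop_prob: float = 0.0
    latency_s: float = 0.0
    seed: int = 0
    delivered: int = 0
    dropped: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_prob <= 1.0:
            raise ConfigurationError("drop_prob must be in [0, 1]")
        if self.latency_s < 0:
            raise ConfigurationError("latency_s must be >= 0")
        self._rng = np.random.default_rng(self.seed)
        self._in_flight: list[tuple[float, VitalsRecord]] = []

    def transmit(self, record: VitalsRecord) -> None:
        """Offer one record to the link."""
        if self.drop_prob > 0 and self._rng.random() < self.drop_prob:
            self.dropped += 1
            return
        self.delivered += 1
        self._in_flight.append((record.t + self.latency_s, record))

    def poll(self, now: float) -> list[VitalsRecord]:
        """Records whose delivery time has arrived, in send order."""
        due = [r for dt, r in self._in_flight if dt <= now]
        self._in_flight = [(dt, r) for dt, r in self._in_flight if dt > now]
        return due


def transmit(link: TransportLink, record: VitalsRecord) -> VitalsRecord | None:
    """One-shot offer-and-poll convenience for zero-latency links."""
    link.transmit(record)
    due = link.poll(record.t + link.latency_s)
    return due[0] if due else None


@dataclass
class SessionConfig:
    """Everything needed to reproduce a closed-loop run."""

    duration_s: float = 1200.0
    sample_rate: float = 500.0
    seed: int = 0
    profile: PhysioProfile = field(default_factory=PhysioProfile)
    patient: PatientState = field(default_factory=PatientState)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    drop_prob: float = 0.0
    latency_s: float = 0.0
    steady_window_s: float = 300.0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        self.profile.validate()
        self.patient.validate()
        self.controller.validate()
        if not 0.0 <= self.drop_prob <= 1.0:
            raise ConfigurationError("drop_prob must be in [0, 1]")

    # -- YAML ----------------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "SessionConfig":
        data = dict(data)
        kwargs = {}
        for name, sub_cls in (
            ("profile", PhysioProfile),
            ("patient", PatientState),
            ("controller", ControllerConfig),
        ):
            block = data.pop(name, {})
            allowed = {f.name for f in dataclasses.fields(sub_cls)}
            unknown = set(block) - allowed
            if unknown:
                raise ConfigurationError(f"unknown {name} keys: {sorted(unknown)}")
            if sub_cls is ControllerConfig and "band" in block:
                block["band"] = tuple(block["band"])
            kwargs[name] = sub_cls(**block)
        allowed = {f.name for f in dataclasses.fields(cls)} - {"profile", "patient", "controller"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigurationError(f"unknown session keys: {sorted(unknown)}")
        cfg = cls(**kwargs, **data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: invalid YAML ({exc})") from exc
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["controller"]["band"] = list(d["controller"]["band"])
        return d


@dataclass
class SessionResult:
    config: SessionConfig
    vitals: list[VitalsRecord]
    commands: list[ValveCommand]
    patient_log: pd.DataFrame  # t, true_spo2, flow_in
    display_log: list[tuple[float, str]]
    summary: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all session logs under ``outdir``; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vitals": outdir / "vitals.csv",
            "commands": outdir / "commands.csv",
            "patient": outdir / "patient.csv",
            "display": outdir / "display.csv",
            "summary": outdir / "summary.json",
        }
        write_vitals_csv(self.vitals, paths["vitals"])
        write_commands_csv(self.commands, paths["commands"])
        self.patient_log.to_csv(paths["patient"], index=False, float_format="%.17g")
        pd.DataFrame(self.display_log, columns=["t", "display"]).to_csv(
            paths["display"], index=False
        )
        paths["summary"].write_text(json.dumps(self.summary, indent=1, sort_keys=True) + "\n")
        return paths


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from one session seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def run_closed_loop(config: SessionConfig) -> SessionResult:
    """Run one fully seeded closed-loop oxygen-titration session.

    Per simulated second: synthesize the sensor stream at the patient's
    current true saturation, run the reader pipeline to a vitals record,
    offer it to the transport, let the controller consume deliveries and
    the watchdog inspect staleness, then advance the patient one second
    under the commanded flow.
    """
    config.validate()
    synth_seed, patient_seed, link_seed = _derived_seeds(config.seed, 3)

    patient = VirtualPatient(dataclasses.replace(config.patient, seed=patient_seed))
    profile = dataclasses.replace(
        config.profile,
        seed=synth_seed,
        true_spo2=float(np.clip(patient.true_spo2, 70.0, 100.0)),
    )
    synth = StreamSynthesizer(profile, config.sample_rate)
    estimator = VitalsEstimator(fs_channel=config.sample_rate / 4.0)
    link = TransportLink(drop_prob=config.drop_prob, latency_s=config.latency_s, seed=link_seed)
    ctrl_state = ControllerState()

    vitals: list[VitalsRecord] = []
    commands: list[ValveCommand] = []
    patient_rows = []
    display_log: list[tuple[float, str]] = []
    last_display = None

    n_seconds = int(config.duration_s)
    for t in range(n_seconds):
        synth.update_profile(true_spo2=float(np.clip(patient.true_spo2, 70.0, 100.0)))
        stream = synth.emit(1.0)
        bundle = ambient_correct(demultiplex(stream))
        record = estimator.tick(float(t), bundle.red, bundle.infrared)
        vitals.append(record)

        link.transmit(record)
        for delivered in link.poll(float(t)):
            ctrl_state, display, command = handle_record(ctrl_state, delivered, config.controller)
            if command is not None:
                commands.append(command)
            if display != last_display:
                display_log.append((float(t), display))
                last_display = display
        wd_command = watchdog_check(ctrl_state, float(t), config.controller)
        if wd_command is not None:
            commands.append(wd_command)
            estimator.reset()

        flow = ctrl_state.current_flow
        patient_rows.append({"t": float(t), "true_spo2": patient.true_spo2, "flow_in": flow})
        patient.step(flow, 1.0)

    patient_log = pd.DataFrame(patient_rows, columns=["t", "true_spo2", "flow_in"])
    window = min(config.steady_window_s, config.duration_s)
    tail = patient_log[patient_log["t"] >= config.duration_s - window]
    measured = records_to_frame(vitals)
    measured_tail = measured[(measured["t"] >= config.duration_s - window) & measured["valid"]]
    lo, hi = config.controller.band
    summary = {
        "duration_s": config.duration_s,
        "steady_window_s": window,
        "steady_mean_true_spo2": float(tail["true_spo2"].mean()),
        "steady_sd_true_spo2": float(tail["true_spo2"].std(ddof=0)),
        "steady_mean_measured_spo2": (
            float(measured_tail["spo2"].mean()) if len(measured_tail) else None
        ),
        "steady_frac_in_band": float(
            ((tail["true_spo2"] >= lo) & (tail["true_spo2"] <= hi)).mean()
        ),
        "final_flow_l_min": float(patient_log["flow_in"].iloc[-1]),
        "n_vitals_records": len(vitals),
        "n_valid_records": int(sum(r.valid for r in vitals)),
        "n_commands": len(commands),
        "records_delivered": link.delivered,
        "records_dropped": link.dropped,
    }
    return SessionResult(
        config=config,
        vitals=vitals,
        commands=commands,
        patient_log=patient_log,
        display_log=display_log,
        summary=summary,
    )


def read_patient_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t", "true_spo2", "flow_in"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing patient columns {sorted(missing)}")
    return df
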