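"""Virtual hypoxaemic patient closing the control loop, plus the classical
oxygen-content and oxygen-delivery relations.

Arterial oxygen content combines haemoglobin-bound and dissolved oxygen,
CaO2 = k1 * Hb * SaO2 + k2 * PaO2 (k1 = 1.34 ml O2 per gram Hb, k2 =
0.023 ml O2 per litre per kPa — standard physiological constants), and
global oxygen delivery is DO2 = CO * CaO2.

The dynamic response to supplemental oxygen is a deliberately minimal
first-order model: sustained flow F sets an equilibrium saturation
s*(F) = min(100, baseline + gain * F) toward which the true SpO2 relaxes
exponentially with time constant tau, plus optional Gaussian jitter per
update. The update uses the exact exponential solution, so step size does
not change the noise-free trajectory. The default patient — baseline 85 %
untreated, gain 2 % per L/min, tau 45 s, jitter 0.3 % — needs 4.5-6.5 L/min
to sit in the 94-98 % target band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

K1_ML_PER_G = 1.34
K2_ML_PER_L_PER_KPA = 0.023


def oxygen_content(
    hb: float,
    sao2: float,
    pao2: float,
    k1: float = K1_ML_PER_G,
    k2: float = K2_ML_PER_L_PER_KPA,
) -> float:
    """Arterial oxygen content CaO2 in ml/l.

    ``hb`` in g/l, ``sao2`` as a fraction in [0, 1], ``pao2`` in kPa.
    """
    if not 0.0 <= sao2 <= 1.0:
        raise ValidationError(f"sao2 {sao2} must be a fraction in [0, 1]")
    if hb < 0 or pao2 < 0:
        raise ValidationError("hb and pao2 must be >= 0")
    return k1 * hb * sao2 + k2 * pao2


def oxygen_delivery(co: float, cao2: float) -> float:
    """Global oxygen delivery DO2 = CO * CaO2, in ml/min (co in l/min)."""
    if co < 0 or cao2 < 0:
        raise ValidationError("co and cao2 must be >= 0")
    return co * cao2


@dataclass
class PatientState:
    """Virtual-patient parameters and current oxygenation.

    baseline_spo2 : untreated equilibrium saturation, percent
    gain : equilibrium saturation rise per L/min of supplemental flow
    tau : first-order response time constant, seconds
    hb, cardiac_output, pao2 : static physiology for content/delivery sums
    noise_sd : per-update Gaussian jitter on the saturation, percent
    """

    true_spo2: float = 85.0
    baseline_spo2: float = 85.0
    gain: float = 2.0
    tau: float = 45.0
    hb: float = 150.0
    cardiac_output: float = 5.0
    pao2: float = 8.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.baseline_spo2 <= 100.0:
            raise ValidationError("baseline_spo2 must be in (0, 100]")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if self.gain < 0 or self.noise_sd < 0:
            raise ValidationError("gain and noise_sd must be >= 0")


class VirtualPatient:
    """Stateful integrator of the first-order oxygenation model."""

    def __init__(self, state: PatientState):
        state.validate()
        self.state = state
        self._rng = np.random.default_rng(state.seed)

    @property
    def true_spo2(self) -> float:
        return self.state.true_spo2

    def setpoint(self, flow: float) -> float:
        """Equilibrium saturation under sustained ``flow`` L/min."""
        return min(100.0, self.state.baseline_spo2 + self.state.gain * flow)

    def step(self, flow: float, dt: float) -> float:
        """Advance the patient by ``dt`` seconds under ``flow`` L/min.

        Exact exponential relaxation toward the flow's setpoint, then
        jitter, then a clamp to [0, 100]. Returns the new true SpO2.
        """
        if dt <= 0:
            raise ValidationError("dt must be > 0")
        if flow < 0:
            raise ValidationError("flow must be >= 0")
        s = self.state
        target = self.setpoint(flow)
        decay = np.exp(-dt / s.tau)
        new = target + (s.true_spo2 - target) * decay
        if s.noise_sd > 0:
            new += self._rng.normal(0.0, s.noise_sd)
        s.true_spo2 = float(min(max(new, 0.0), 100.0))
        return s.true_spo2

    def oxygen_delivery(self) -> float:
        """Current DO2 in ml/min from the patient's static physiology."""
        cao2 = oxygen_content(self.state.hb, self.state.true_spo2 / 100.0, self.state.pao2)
        return oxygen_delivery(self.state.cardiac_output, cao2)


def step_patient(state: PatientState, flow: float, dt: float) -> PatientState:
    """Functional single-step form of :meth:`VirtualPatient.step`.

    Noise uses the state's seed afresh each call; for an evolving noisy
    trajectory use :class:`VirtualPatient`, which carries its generator.
    """
    patient = VirtualPatient(state)
    patient.step(flow, dt)
    return patient.state
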