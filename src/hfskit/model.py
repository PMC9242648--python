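"""Physical constants and the load-dependent detachment model.

The central object is the Bell/Arrhenius detachment rate of a myosin head
under a harmonic (sinusoidally oscillating) load,

    k_det(F, dF) = k0 * I0(dF * delta / kBT) * exp(-F * delta / kBT)

where ``F`` is the mean load force felt during a binding event (positive =
resistive), ``dF`` the amplitude of the sinusoidal load component, ``k0``
the detachment rate at zero load, and ``delta`` the distance parameter that
sets force sensitivity.  The zero-order modified Bessel function ``I0`` is
the exact period-average of ``exp(-delta * dF * cos(wt) / kBT)`` over one
oscillation cycle, so the closed form is the cycle-averaged hazard of the
instantaneous Bell rate.

All forces are in pN, lengths in nm, energies in pN*nm, rates in 1/s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import i0 as _scipy_i0

#: Boltzmann constant in pN*nm/K.
BOLTZMANN_PN_NM = 1.380649e-2

#: Thermal energy at 23 degrees C, the temperature of the trap experiments.
KBT_23C = BOLTZMANN_PN_NM * (23.0 + 273.15)  # 4.0888 pN*nm


def kbt_from_celsius(temperature_C: float) -> float:
    """Thermal energy kB*T in pN*nm for a temperature in Celsius."""
    return BOLTZMANN_PN_NM * (temperature_C + 273.15)


@dataclass(frozen=True)
class TrapConstants:
    """Instrument and physical constants of the dual-beam trap.

    Defaults reflect a typical harmonic-force-spectroscopy configuration:
    sample at 23 C, 200 Hz stage oscillation, trap stiffnesses in the
    0.08-0.10 pN/nm range.
    """

    temperature_C: float = 23.0
    kBT: float = KBT_23C
    oscillation_freq: float = 200.0
    trap_stiffness_A: float = 0.09
    trap_stiffness_B: float = 0.09
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        expected = kbt_from_celsius(self.temperature_C)
        if abs(self.kBT - expected) / expected > 1e-3:
            raise ValueError(
                f"kBT={self.kBT:.4f} pN*nm inconsistent with "
                f"temperature {self.temperature_C} C (expected {expected:.4f})"
            )
        if not (0 < self.oscillation_freq < self.sampling_rate / 10):
            raise ValueError(
                "oscillation_freq must be positive and below sampling_rate/10"
            )
        for name in ("trap_stiffness_A", "trap_stiffness_B"):
            k = getattr(self, name)
            if not (0 < k < 1):
                raise ValueError(f"{name} must be in (0, 1) pN/nm")

    @property
    def system_stiffness(self) -> float:
        """Combined stiffness acting on a bound head, pN/nm.

        The two traps both pull on the dumbbell, so their stiffnesses add.
        This ignores actin and linkage compliance (a documented
        simplification).
        """
        return self.trap_stiffness_A + self.trap_stiffness_B

    @classmethod
    def at_temperature(cls, temperature_C: float, **kwargs) -> "TrapConstants":
        return cls(
            temperature_C=temperature_C,
            kBT=kbt_from_celsius(temperature_C),
            **kwargs,
        )


@dataclass
class MotorParams:
    """Kinetic and mechanical parameters of one myosin construct.

    Parameters
    ----------
    k0 : float
        Detachment rate at zero load, 1/s.
    delta : float
        Force-sensitivity distance, nm.
    kcat : float, optional
        Actin-activated maximal turnover rate, 1/s.  Must be below ``k0``
        for the attachment-rate algebra to be well defined.
    step_d : float, optional
        Working-stroke (step) size, nm, without compliance correction.
    sem_* / sd_step : float, optional
        Uncertainties in matching units (SEM across molecules for k0,
        delta, kcat; SD for the step).
    """

    k0: float
    delta: float
    kcat: Optional[float] = None
    step_d: Optional[float] = None
    sem_k0: Optional[float] = None
    sem_delta: Optional[float] = None
    sem_kcat: Optional[float] = None
    sd_step: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.kcat is not None:
            if self.kcat <= 0:
                raise ValueError("kcat must be positive")
            if self.kcat >= self.k0:
                raise ValueError(
                    "kcat must be below k0: a turnover rate at or above the "
                    "detachment rate leaves no time detached and the duty "
                    "ratio is ill-defined"
                )

    def to_json(self) -> str:
        """Serialize as a flat JSON object with unit-suffixed keys."""
        d = {
            "label": self.label,
            "k0_per_s": self.k0,
            "delta_nm": self.delta,
            "kcat_per_s": self.kcat,
            "step_nm": self.step_d,
            "k0_sem": self.sem_k0,
            "delta_sem": self.sem_delta,
            "kcat_sem": self.sem_kcat,
            "step_sd": self.sd_step,
        }
        return json.dumps({k: v for k, v in d.items() if v is not None})

    @classmethod
    def from_json(cls, text: str) -> "MotorParams":
        d = json.loads(text)
        return cls(
            k0=d["k0_per_s"],
            delta=d["delta_nm"],
            kcat=d.get("kcat_per_s"),
            step_d=d.get("step_nm"),
            sem_k0=d.get("k0_sem"),
            sem_delta=d.get("delta_sem"),
            sem_kcat=d.get("kcat_sem"),
            sd_step=d.get("step_sd"),
            label=d.get("label", ""),
        )


def bessel_i0(x):
    """Modified Bessel function of the first kind, order zero.

    Thin wrapper over the library special function; accepts scalars or
    arrays and is symmetric in ``x``.
    """
    return _scipy_i0(x)


def detachment_rate(F, dF, params: MotorParams, consts: TrapConstants):
    """Cycle-averaged detachment rate under mean load ``F`` and harmonic
    amplitude ``dF``.

    Positive ``F`` is resistive (detachment slowed), negative assistive.
    Vectorized over ``F`` and ``dF``.
    """
    dF = np.asarray(dF, dtype=float)
    if np.any(dF < 0):
        raise ValueError("force amplitude dF must be non-negative")
    F = np.asarray(F, dtype=float)
    scale = params.delta / consts.kBT
    out = params.k0 * bessel_i0(dF * scale) * np.exp(-F * scale)
    return out if out.ndim else float(out)


def attachment_rate(kcat: float, k0: float) -> float:
    """Force-independent attachment rate from the cycle-time algebra.

    The total cycle time 1/kcat is the attached time 1/k0 plus the detached
    time 1/k_attach, giving  k_attach = 1 / (1/kcat - 1/k0).
    """
    if not (0 < kcat < k0):
        raise ValueError("requires 0 < kcat < k0 (cycle time must exceed attached time)")
    return 1.0 / (1.0 / kcat - 1.0 / k0)
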