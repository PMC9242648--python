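"""Synthetic-data generators for the trap and bulk assays.

These generators stand in for the instrument and the wet lab.  The trap
generator draws single-molecule binding events whose dwell times follow the
exact inhomogeneous-exponential survival law of the instantaneous Bell
hazard under a sinusoidal load,

    k(t) = k0 * exp(-delta * (F + dF*cos(2*pi*f*t + phi)) / kBT),

sampled by thinning (rejection against the constant envelope hazard at the
most-assistive instant).  Its cycle-average is the Bessel-corrected closed
form in :mod:`hfskit.model`, which is what the fitting modules estimate.
The binding phase ``phi`` is uniform on [0, 2*pi): binding is stochastic
relative to the stage oscillation, which is exactly the condition under
which the period-averaged Bessel correction is valid.

Bulk generators produce Michaelis-Menten ATPase plates with multiplicative
replicate noise, biexponential single-turnover fluorescence decays, and
linear gel dilution series with optional top-load saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import MotorParams, TrapConstants, detachment_rate

EVENT_COLUMNS = [
    "molecule_id",
    "duration_s",
    "mean_force_pN",
    "force_amp_pN",
    "displacement_nm",
]


@dataclass
class InteractionEvent:
    """One myosin-actin binding event and its load descriptors."""

    molecule_id: str
    duration: float  # s
    mean_force: float  # pN, positive = resistive
    force_amp: float  # pN, >= 0
    displacement: float  # nm
    start_time: Optional[float] = None  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.force_amp < 0:
            raise ValueError("force_amp must be non-negative")


@dataclass
class SimConfig:
    """Configuration of a synthetic single-molecule experiment.

    ``events_per_molecule`` counts *attempted* binding events; events
    shorter than ``min_detectable_duration`` are dropped, emulating the
    detector's inability to score sub-window interactions.  The default
    detectability floor is two oscillation periods (10 ms at 200 Hz).
    """

    true_params: MotorParams
    n_molecules: int = 10
    events_per_molecule: int = 300
    force_range: tuple = (-5.0, 5.0)
    amp_range: tuple = (1.0, 4.0)
    min_detectable_duration: float = 0.010
    displacement_noise_sd: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1 or self.events_per_molecule < 1:
            raise ValueError("counts must be >= 1")
        if self.min_detectable_duration < 0:
            raise ValueError("min_detectable_duration must be >= 0")
        for name in ("force_range", "amp_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered (lo, hi)")
        if self.amp_range[0] < 0:
            raise ValueError("force amplitudes must be non-negative")


@dataclass
class TrapTrace:
    """Sampled dumbbell trace with optional ground truth.

    ``truth`` is a DataFrame with columns start_s, end_s, mean_force_pN,
    force_amp_pN, displacement_nm; retained for round-trip tests.
    """

    time: np.ndarray
    bead_A: np.ndarray
    bead_B: np.ndarray
    stage: np.ndarray
    consts: TrapConstants
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.bead_A) == len(self.bead_B) == len(self.stage) == n):
            raise ValueError("trace columns must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def sample_event_duration(
    F: float,
    dF: float,
    phase: float,
    params: MotorParams,
    consts: TrapConstants,
    rng: np.random.Generator,
) -> float:
    """Draw one dwell time from the sinusoidal-load hazard by thinning.

    Exact for the stated hazard: candidate detachment times are drawn at
    the envelope rate ``k0*exp(-delta*(F - dF)/kBT)`` (the hazard at the
    most load-relieved instant) and accepted with probability
    ``k(t)/envelope``.
    """
    durations = _sample_durations(
        np.asarray([F], float),
        np.asarray([dF], float),
        np.asarray([phase], float),
        params,
        consts,
        rng,
    )
    return float(durations[0])


def _sample_durations(F, dF, phase, params, consts, rng):
    """Vectorized thinning sampler; one dwell per (F, dF, phase) triple."""
    if np.any(dF < 0):
        raise ValueError("force amplitude must be non-negative")
    scale = params.delta / consts.kBT
    omega = 2 * np.pi * consts.oscillation_freq
    env = params.k0 * np.exp(-scale * (F - dF))  # max of hazard over phase
    n = len(F)
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        t[idx] += rng.exponential(1.0, size=len(idx)) / env[idx]
        inst = params.k0 * np.exp(
            -scale * (F[idx] + dF[idx] * np.cos(omega * t[idx] + phase[idx]))
        )
        accept = rng.uniform(size=len(idx)) < inst / env[idx]
        alive[idx[accept]] = False
    return t


def simulate_events(cfg: SimConfig, consts: Optional[TrapConstants] = None) -> pd.DataFrame:
    """Simulate an event table for ``cfg.n_molecules`` molecules.

    Per event, mean force, amplitude, and binding phase are drawn
    independently (forces vary event-to-event, not molecule-to-molecule,
    as in the real assay where binding occurs at random stage positions).
    Events shorter than the detectability floor are dropped.  Returns a
    tidy DataFrame with columns ``EVENT_COLUMNS``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.true_params
    if p.step_d is None:
        raise ValueError("true_params.step_d required to simulate displacements")
    consts = consts or TrapConstants()
    frames = []
    width = max(3, len(str(cfg.n_molecules - 1)))
    for m in range(cfg.n_molecules):
        n = cfg.events_per_molecule
        F = rng.uniform(*cfg.force_range, size=n)
        dF = rng.uniform(*cfg.amp_range, size=n)
        phase = rng.uniform(0, 2 * np.pi, size=n)
        dur = _sample_durations(F, dF, phase, p, consts, rng)
        disp = p.step_d + rng.normal(0, cfg.displacement_noise_sd, size=n)
        keep = dur >= cfg.min_detectable_duration
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": f"mol_{m:0{width}d}",
                    "duration_s": dur[keep],
                    "mean_force_pN": F[keep],
                    "force_amp_pN": dF[keep],
                    "displacement_nm": disp[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trace(
    events: pd.DataFrame,
    consts: TrapConstants,
    noise_sd: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    *,
    gap_mean_s: float = 0.080,
    unbound_amp_nm: float = 3.0,
    unbound_phase: float = -np.pi / 2,
    bound_phase: float = 0.0,
    stage_amp_nm: float = 25.0,
) -> TrapTrace:
    """Render one molecule's events as a sampled dumbbell trace.

    Unbound segments: both beads oscillate weakly at the stage frequency
    (fluid coupling) with amplitude ``unbound_amp_nm`` and a lagging
    phase.  Bound segments: the myosin couples the dumbbell to the stage,
    so the oscillation amplitude rises to ``force_amp / k_sys`` with an
    elastic (in-)phase, and the beads acquire a mean offset
    ``mean_force / k_sys``.  In this trace model the bound-state mean
    offset and the mean load are the same observable by construction
    (offset = F / k_sys); the working stroke is subsumed in where the
    dumbbell settles, so trace-derived displacements are load-proportional
    and are not an estimate of the step size.  Additive Gaussian position
    noise on each bead; the stage channel is noiseless.

    Events are laid out sequentially with exponential unbound gaps
    (mean ``gap_mean_s``), or at ``start_time_s`` if the column is present
    (must be non-overlapping).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ksys = consts.system_stiffness
    fs = consts.sampling_rate
    omega = 2 * np.pi * consts.oscillation_freq

    durs = events["duration_s"].to_numpy(float)
    n_ev = len(durs)
    if "start_time_s" in events.columns:
        starts = events["start_time_s"].to_numpy(float)
        order = np.argsort(starts)
        if np.any(starts[order][1:] < (starts + durs)[order][:-1]):
            raise ValueError("events overlap")
    else:
        gaps = rng.exponential(gap_mean_s, size=n_ev + 1) + 0.02
        starts = np.cumsum(gaps)[:n_ev] + np.concatenate([[0], np.cumsum(durs[:-1])])
    ends = starts + durs
    t_total = (ends.max() if n_ev else 1.0) + gap_mean_s + 0.05
    time = np.arange(0, t_total, 1.0 / fs)

    stage = stage_amp_nm * np.sin(omega * time)
    carrier_unbound = unbound_amp_nm * np.sin(omega * time + unbound_phase)
    beads = []
    for _ in range(2):
        bead = carrier_unbound.copy()
        for s, e, F, dF in zip(
            starts, ends, events["mean_force_pN"], events["force_amp_pN"]
        ):
            sel = (time >= s) & (time < e)
            bead[sel] = F / ksys + (dF / ksys) * np.sin(omega * time[sel] + bound_phase)
        bead += rng.normal(0, noise_sd, size=len(time))
        beads.append(bead)

    truth = pd.DataFrame(
        {
            "start_s": starts,
            "end_s": ends,
            "mean_force_pN": events["mean_force_pN"].to_numpy(float),
            "force_amp_pN": events["force_amp_pN"].to_numpy(float),
            "displacement_nm": events["displacement_nm"].to_numpy(float),
        }
    )
    return TrapTrace(time, beads[0], beads[1], stage, consts, truth)


# ---------------------------------------------------------------------------
# bulk-assay generators
# ---------------------------------------------------------------------------

DEFAULT_ACTIN_UM = (1.0, 2.5, 5.0, 10.0, 20.0, 30.0, 50.0, 80.0)


def simulate_atpase_plate(
    kcat: float,
    Kapp: float,
    actin_concs: Sequence[float] = DEFAULT_ACTIN_UM,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    basal_rate: float = 0.02,
    outlier_wells: Sequence[tuple] = (),
    outlier_factor: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis-Menten plate with multiplicative lognormal replicate noise.

    ``outlier_wells`` is a list of (actin_conc, replicate_index) whose rate
    is multiplied by ``outlier_factor``, emulating the occasional actin
    pipetting error that the >50% triplicate-rejection rule targets.
    A zero-actin basal row is included per replicate.
    """
    if kcat <= 0 or Kapp <= 0:
        raise ValueError("kcat and Kapp must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + noise_cv**2))
    rows = []
    for a in (0.0, *actin_concs):
        mean = basal_rate if a == 0 else kcat * a / (Kapp + a)
        for r in range(n_replicates):
            rate = mean * rng.lognormal(-sigma**2 / 2, sigma) if noise_cv > 0 else mean
            if (a, r) in set(outlier_wells):
                rate *= outlier_factor
            rows.append({"actin_uM": a, "replicate": r, "rate_per_s": rate})
    return pd.DataFrame(rows)


def simulate_turnover_trace(
    amp_fast: float = 0.43,
    rate_fast: float = 0.030,
    amp_slow: float = 0.57,
    rate_slow: float = 0.003,
    plateau: float = 0.05,
    duration_s: float = 960.0,
    dt_s: float = 2.0,
    dead_time_s: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single mant-ATP turnover fluorescence decay.

    Biexponential with plateau; the time axis starts at the dead time
    (the delay between the dark-ATP chase and the first plate read),
    matching how the real traces are assembled.  Default truth has a 57%
    slow-phase amplitude fraction, a fast (DRX-like) rate of 0.03/s and a
    slow (SRX-like) rate of 0.003/s over a 16-minute read.
    """
    for name, v in [
        ("amp_fast", amp_fast),
        ("rate_fast", rate_fast),
        ("amp_slow", amp_slow),
        ("rate_slow", rate_slow),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(dead_time_s, dead_time_s + duration_s, dt_s)
    f = amp_fast * np.exp(-rate_fast * t) + amp_slow * np.exp(-rate_slow * t) + plateau
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd, size=len(t))
    return pd.DataFrame({"time_s": t, "fluorescence_au": f})


def simulate_gel_series(
    hc_slope: float = 1000.0,
    elc_hc_ratio: float = 0.19,
    rlc_hc_ratio: float = 0.11,
    loads_pmol: Sequence[float] = (10.0, 5.0, 3.0, 2.0, 1.0),
    noise_cv: float = 0.02,
    saturate_chains: Sequence[str] = (),
    saturation_factor: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Dilution-series band densities for heavy and light chains.

    Densities are linear in load with multiplicative noise.  Chains named
    in ``saturate_chains`` have their highest load attenuated by
    ``saturation_factor``, emulating the heavy chain leaving the linear
    range at the 10 pmol load.
    """
    if hc_slope <= 0 or elc_hc_ratio <= 0 or rlc_hc_ratio <= 0:
        raise ValueError("slopes and ratios must be positive")
    rng = np.random.default_rng(seed)
    slopes = {
        "HC": hc_slope,
        "ELC": hc_slope * elc_hc_ratio,
        "RLC": hc_slope * rlc_hc_ratio,
    }
    top = max(loads_pmol)
    rows = []
    for chain, slope in slopes.items():
        for load in loads_pmol:
            dens = slope * load
            if chain in saturate_chains and load == top:
                dens *= saturation_factor
            if noise_cv > 0:
                sigma = np.sqrt(np.log(1 + noise_cv**2))
                dens *= rng.lognormal(-sigma**2 / 2, sigma)
            rows.append({"chain": chain, "load_pmol": load, "density_au": dens})
    return pd.DataFrame(rows)
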