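"""Ensemble mechanics: duty ratio, average force, velocity, and power.

From single-molecule parameters (k0, delta, kcat, step d) the ensemble
behavior of a motor under resistive load F follows from cycle algebra:

    k_attach = 1 / (1/kcat - 1/k0)            (force independent)
    r(F)     = k_attach / (k_attach + k_det(F))   duty ratio
    F_av(F)  = F * r(F)                       ensemble-average force/head
    vel(F)   = k_det(F) * d                   gliding velocity
    P_av(F)  = vel(F) * F_av(F)               average power/head

``k_det`` here uses dF = 0 by default: the sinusoidal load component is an
instrument artifact of the trap assay, not physiology.  Uncertainty bands
are propagated from the cross-molecule SEMs by Monte Carlo (independent
truncated Gaussians over the four parameters, pointwise 16th/84th
percentiles); a delta-method band is available as an analytic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import MotorParams, TrapConstants, attachment_rate, detachment_rate

DEFAULT_FORCE_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)

_QUANTITIES = ("duty_ratio", "avg_force", "velocity", "power")


@dataclass
class EnsembleCurves:
    """Force-gridded ensemble curves with percentile error bands."""

    force_grid: np.ndarray
    duty_ratio: np.ndarray
    avg_force: np.ndarray
    velocity: np.ndarray
    power: np.ndarray
    bands: dict = field(default_factory=dict)  # name -> (lo, hi) arrays
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        d = {"force_pN": self.force_grid}
        units = {
            "duty_ratio": "duty_ratio",
            "avg_force": "avg_force_pN",
            "velocity": "velocity_nm_s",
            "power": "power_pNnm_s",
        }
        for name, col in units.items():
            d[col] = getattr(self, name)
            if name in self.bands:
                d[col + "_lo"], d[col + "_hi"] = self.bands[name]
        return pd.DataFrame(d)


def duty_ratio(
    F,
    params: MotorParams,
    consts: TrapConstants,
    include_harmonic_amp: float = 0.0,
):
    """Fraction of the cycle spent attached under mean load ``F``.

    At F=0 this reduces exactly to kcat/k0.  ``include_harmonic_amp``
    optionally applies the Bessel factor for a nonzero oscillation
    amplitude (off by default; see module docstring)."""
    if params.kcat is None:
        raise ValueError("duty ratio requires kcat")
    katt = attachment_rate(params.kcat, params.k0)
    kdet = detachment_rate(F, include_harmonic_amp, params, consts)
    return katt / (katt + kdet)


def _curves(F, k0, delta, kcat, d, kBT):
    """Vectorized ensemble curves; parameters may be scalars or 1-D arrays
    of draws (then outputs have shape (n_draws, len(F)))."""
    scalar = np.ndim(k0) == 0
    k0, delta, kcat, d = (np.atleast_1d(np.asarray(x, float))[:, None] for x in (k0, delta, kcat, d))
    kdet = k0 * np.exp(-delta * F / kBT)
    katt = 1.0 / (1.0 / kcat - 1.0 / k0)
    r = katt / (katt + kdet)
    fav = F * r
    vel = kdet * d
    power = vel * fav
    if scalar:
        return r[0], fav[0], vel[0], power[0]
    return r, fav, vel, power


def ensemble_curves(
    params: MotorParams,
    consts: TrapConstants,
    force_grid: Optional[np.ndarray] = None,
    n_mc: int = 10_000,
    seed: int = 0,
) -> EnsembleCurves:
    """Central ensemble curves with Monte-Carlo error bands.

    Parameter draws are independent Gaussians at (mean, SEM) truncated to
    the validity region (k0 > kcat > 0, delta >= 0, d unconstrained);
    invalid draws are redrawn, and a redraw rate above 20% aborts since
    the Gaussian error model is then inconsistent with the parameters.
    Bands are pointwise 16th/84th percentiles.
    """
    if params.kcat is None or params.step_d is None:
        raise ValueError("ensemble curves require kcat and step_d")
    F = DEFAULT_FORCE_GRID if force_grid is None else np.asarray(force_grid, float)
    if np.any(F < 0):
        raise ValueError("force grid must be resistive (>= 0)")

    r, fav, vel, power = _curves(
        F,
        np.float64(params.k0),
        np.float64(params.delta),
        np.float64(params.kcat),
        np.float64(params.step_d),
        consts.kBT,
    )
    curves = EnsembleCurves(F, r, fav, vel, power, label=params.label)

    sems = (params.sem_k0, params.sem_delta, params.sem_kcat, params.sd_step)
    if any(s is None for s in sems):
        return curves
    if all(s == 0 for s in sems):
        curves.bands = {
            name: (getattr(curves, name).copy(), getattr(curves, name).copy())
            for name in _QUANTITIES
        }
        return curves

    rng = np.random.default_rng(seed)
    means = np.array([params.k0, params.delta, params.kcat, params.step_d])
    scales = np.array(sems, dtype=float)
    draws = np.empty((n_mc, 4))
    filled = 0
    attempts = 0
    while filled < n_mc:
        need = n_mc - filled
        cand = rng.normal(means, scales, size=(need, 4))
        attempts += need
        ok = (
            (cand[:, 0] > 0)
            & (cand[:, 1] >= 0)
            & (cand[:, 2] > 0)
            & (cand[:, 2] < cand[:, 0])
        )
        take = cand[ok]
        draws[filled : filled + len(take)] = take
        filled += len(take)
        if attempts > 10 * n_mc:
            raise RuntimeError("parameter draws keep violating kcat < k0")
    redraw_rate = 1.0 - n_mc / attempts
    if redraw_rate > 0.20:
        raise RuntimeError(
            f"{redraw_rate:.0%} of Gaussian parameter draws violate the "
            "validity region; SEMs are inconsistent with the means"
        )

    mc = _curves(F, draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3], consts.kBT)
    for name, arr in zip(_QUANTITIES, mc):
        lo, hi = np.percentile(arr, [16, 84], axis=0)
        curves.bands[name] = (lo, hi)
    return curves


def delta_method_bands(
    params: MotorParams,
    consts: TrapConstants,
    force_grid: Optional[np.ndarray] = None,
    rel_step: float = 1e-5,
) -> dict:
    """First-order (delta-method) 1-sigma half-widths for each quantity.

    Numeric central-difference gradients over (k0, delta, kcat, d) with
    independent errors; analytic cross-check for the Monte-Carlo bands.
    """
    F = DEFAULT_FORCE_GRID if force_grid is None else np.asarray(force_grid, float)
    theta = np.array([params.k0, params.delta, params.kcat, params.step_d], float)
    sems = np.array(
        [params.sem_k0, params.sem_delta, params.sem_kcat, params.sd_step], float
    )

    def eval_at(th):
        return _curves(F, th[0], th[1], th[2], th[3], consts.kBT)

    grads = {name: np.zeros((4, len(F))) for name in _QUANTITIES}
    for j in range(4):
        h = max(rel_step * abs(theta[j]), 1e-12)
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        vals_up, vals_dn = eval_at(up), eval_at(dn)
        for name, vu, vd in zip(_QUANTITIES, vals_up, vals_dn):
            grads[name][j] = (vu - vd) / (2 * h)
    return {
        name: np.sqrt(np.sum((grads[name] * sems[:, None]) ** 2, axis=0))
        for name in _QUANTITIES
    }


def compare_ensembles(a: EnsembleCurves, b: EnsembleCurves) -> dict:
    """Qualitative contractility comparison of two parameter sets.

    For each grid force, records the sign of the power difference (a - b)
    and whether the power bands overlap.  The summary label is decided by
    majority over grid points where the bands are disjoint: mostly
    positive -> "hyper", mostly negative -> "hypo"; if fewer than half the
    points separate, "within error".  ``label_high_force`` applies the
    same vote to the upper half of the force grid, where power differences
    concentrate.
    """
    if len(a.force_grid) != len(b.force_grid) or np.any(a.force_grid != b.force_grid):
        raise ValueError("ensemble curves must share a force grid")
    diff = a.power - b.power
    if "power" in a.bands and "power" in b.bands:
        a_lo, a_hi = a.bands["power"]
        b_lo, b_hi = b.bands["power"]
        disjoint = (a_lo > b_hi) | (a_hi < b_lo)
    else:
        disjoint = diff != 0

    def vote(mask):
        if mask.sum() < 0.5 * len(mask):
            return "within error"
        signs = np.sign(diff[mask])
        return "hyper" if signs.sum() > 0 else "hypo"

    half = len(diff) // 2
    high = np.zeros(len(diff), dtype=bool)
    high[half:] = True
    return {
        "label": vote(disjoint),
        "label_high_force": vote(disjoint & high),
        "power_diff": diff,
        "bands_disjoint": disjoint,
        "force_grid": a.force_grid,
    }
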