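"""Per-molecule detachment-rate fitting and cross-molecule statistics.

The estimation chain mirrors the single-molecule analysis of a harmonic
force spectroscopy experiment:

1. events are binned by mean load force;
2. each bin's detachment rate is the left-truncated exponential MLE of
   the event durations (truncation at the detector's detectability floor
   ``t_min`` — ignoring it provably biases rates, and hence k0, upward);
3. the bin rates are fitted against the Bessel-corrected Bell model
   ``k0 * I0(dF*delta/kBT) * exp(-F*delta/kBT)`` by weighted nonlinear
   least squares, giving per-molecule (k0, delta);
4. molecules are averaged to characteristic group values (mean +/- SEM;
   step size mean +/- SD) and compared by Welch's t-test with each
   molecule as one replicate.

A full per-event truncated-likelihood fit is provided as a cross-check
(:func:`fit_events_mle`) and must agree with the binned route on large
synthetic datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import MotorParams, TrapConstants, bessel_i0

__all__ = [
    "ForceBin",
    "MoleculeFit",
    "GroupSummary",
    "bin_events",
    "mle_bin_rate",
    "fit_force_dependence",
    "fit_events_mle",
    "fit_molecule",
    "fit_molecules",
    "estimate_step",
    "summarize_group",
    "compare_groups",
    "percent_change",
]


@dataclass
class ForceBin:
    f_lo: float
    f_hi: float
    mean_force: float
    mean_amp: float
    n_events: int
    rate: float
    rate_se: float


@dataclass
class MoleculeFit:
    molecule_id: str
    k0: float
    k0_se: float
    delta: float
    delta_se: float
    step: Optional[float]
    step_sd: Optional[float]
    n_events: int
    bins: list = field(default_factory=list)
    converged: bool = True
    residual_norm: float = np.nan


@dataclass
class GroupSummary:
    label: str
    n_molecules: int
    k0_mean: float
    k0_sem: float
    delta_mean: float
    delta_sem: float
    step_mean: Optional[float]
    step_sd: Optional[float]


def mle_bin_rate(durations: Sequence[float], t_min: float = 0.0):
    """Left-truncated exponential MLE of a detachment rate.

    For durations all exceeding the detectability floor ``t_min``, the
    memoryless property makes ``t - t_min`` exponential, so the MLE is
    ``n / sum(t - t_min)`` with SE ``rate / sqrt(n)``.
    """
    t = np.asarray(durations, dtype=float)
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    if len(t) == 0:
        raise ValueError("no durations")
    if np.any(t <= t_min):
        raise ValueError(
            "duration at or below t_min: censoring-inconsistent record "
            "(events shorter than the detectability floor cannot exist)"
        )
    rate = len(t) / float(np.sum(t - t_min))
    return rate, rate / np.sqrt(len(t))


def bin_events(
    events: pd.DataFrame,
    bin_width: float = 1.0,
    min_bin_events: int = 5,
    t_min: float = 0.0,
) -> list[ForceBin]:
    """Bin events by mean force; fixed-width bins anchored at multiples of
    ``bin_width``.  Bins with fewer than ``min_bin_events`` events are
    dropped; surviving bins carry the truncated-MLE rate of their durations
    and within-bin mean force and amplitude."""
    if len(events) == 0:
        raise ValueError("no events to bin")
    F = events["mean_force_pN"].to_numpy(float)
    lo = np.floor(F.min() / bin_width) * bin_width
    edges = np.arange(lo, F.max() + bin_width, bin_width)
    idx = np.digitize(F, edges) - 1
    out = []
    for b in range(len(edges)):
        sel = idx == b
        if sel.sum() < min_bin_events:
            continue
        rate, se = mle_bin_rate(events.loc[sel, "duration_s"], t_min)
        out.append(
            ForceBin(
                f_lo=float(edges[b]),
                f_hi=float(edges[b] + bin_width),
                mean_force=float(F[sel].mean()),
                mean_amp=float(events.loc[sel, "force_amp_pN"].mean()),
                n_events=int(sel.sum()),
                rate=rate,
                rate_se=se,
            )
        )
    return out


def fit_force_dependence(bins: Sequence[ForceBin], consts: TrapConstants):
    """Weighted NLS fit of bin rates to the harmonic-force Bell model.

    Returns ``(k0, delta, cov)``; weights are 1/rate_se^2.  Requires at
    least 3 bins spanning at least 2 pN of force.  A fit with delta pinned
    at zero raises (flat force dependence cannot be distinguished)."""
    if len(bins) < 3:
        raise ValueError("need >= 3 force bins")
    F = np.array([b.mean_force for b in bins])
    if F.max() - F.min() < 2.0:
        raise ValueError("bins must span >= 2 pN")
    dF = np.array([b.mean_amp for b in bins])
    rates = np.array([b.rate for b in bins])
    ses = np.array([b.rate_se for b in bins])

    def model(x, k0, delta):
        f, a = x
        s = delta / consts.kBT
        return k0 * bessel_i0(a * s) * np.exp(-f * s)

    # log-linear start ignoring the Bessel factor
    slope, intercept = np.polyfit(F, np.log(rates), 1)
    p0 = (float(np.exp(intercept)), max(1e-3, -slope * consts.kBT))
    popt, pcov = optimize.curve_fit(
        model,
        (F, dF),
        rates,
        p0=p0,
        sigma=ses,
        absolute_sigma=True,
        bounds=([1e-9, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    k0, delta = float(popt[0]), float(popt[1])
    if delta <= 1e-4:  # physically negligible: flat force dependence
        raise RuntimeError("delta pinned at zero: no resolvable force dependence")
    return k0, delta, pcov


def fit_events_mle(
    events: pd.DataFrame,
    consts: TrapConstants,
    t_min: float = 0.0,
    with_se: bool = False,
):
    """Per-event truncated-exponential maximum likelihood fit of (k0, delta).

    Each event contributes ``log k_i - k_i*(t_i - t_min)`` with
    ``k_i = k0*exp(-delta*F_i/kBT)*I0(delta*dF_i/kBT)``; maximized over
    (log k0, delta).  Unlike the binned route this uses every event's own
    force and amplitude and has no small-bin bias.  With ``with_se`` the
    observed-information standard errors are returned too.
    """
    t = events["duration_s"].to_numpy(float)
    if np.any(t <= t_min):
        raise ValueError("duration at or below t_min")
    F = events["mean_force_pN"].to_numpy(float)
    dF = events["force_amp_pN"].to_numpy(float)
    kBT = consts.kBT

    def nll(x):
        logk0, delta = x
        if delta < 0:
            # smooth finite barrier so numeric differentiation stays valid
            return nll([logk0, 0.0]) + 1e8 * delta**2
        s = delta / kBT
        logk = logk0 + np.log(bessel_i0(dF * s)) - F * s
        return -np.sum(logk - np.exp(logk) * (t - t_min))

    naive = len(t) / np.sum(t - t_min)
    res = optimize.minimize(
        nll, x0=[np.log(naive), 1.0], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    if not res.success:
        raise RuntimeError("per-event MLE did not converge")
    k0, delta = float(np.exp(res.x[0])), float(res.x[1])
    if not with_se:
        return k0, delta
    hess = _numeric_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(hess)
        se_logk0, se_delta = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se_logk0 = se_delta = np.nan
    return k0, delta, k0 * se_logk0, float(se_delta)


def _numeric_hessian(f, x, rel_step: float = 1e-4):
    x = np.asarray(x, float)
    n = len(x)
    h = np.maximum(np.abs(x) * rel_step, 1e-6)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def estimate_step(events: pd.DataFrame):
    """Mean and SD of per-event displacements (no compliance correction)."""
    d = events["displacement_nm"].dropna().to_numpy(float)
    if len(d) < 5:
        raise ValueError("need >= 5 events with displacement")
    return float(d.mean()), float(d.std(ddof=1))


def fit_molecule(
    events: pd.DataFrame,
    consts: TrapConstants,
    bin_width: float = 1.0,
    min_bin_events: int = 5,
    t_min: float = 0.0,
    molecule_id: Optional[str] = None,
    method: str = "events",
) -> MoleculeFit:
    """Full per-molecule fit: (k0, delta) plus step estimate.

    ``method="events"`` (default) is the per-event truncated-likelihood
    fit, which uses every event's own force and amplitude and is free of
    small-bin bias.  ``method="binned"`` reproduces the classic
    bin-then-fit route (weighted NLS of bin rates); the two agree within
    a few percent on well-populated data and the bins are always attached
    for inspection.
    """
    if method not in ("events", "binned"):
        raise ValueError("method must be 'events' or 'binned'")
    mol = molecule_id or str(events["molecule_id"].iloc[0])
    bins = []
    try:
        bins = bin_events(events, bin_width, min_bin_events, t_min)
        if method == "events":
            k0, delta, k0_se, delta_se = fit_events_mle(
                events, consts, t_min, with_se=True
            )
        else:
            k0, delta, cov = fit_force_dependence(bins, consts)
            k0_se, delta_se = np.sqrt(np.diag(cov))
        converged = True
        resid = float(
            np.sqrt(
                np.mean(
                    [
                        (
                            (b.rate - k0 * bessel_i0(b.mean_amp * delta / consts.kBT)
                             * np.exp(-b.mean_force * delta / consts.kBT))
                            / b.rate_se
                        )
                        ** 2
                        for b in bins
                    ]
                )
            )
        ) if bins else np.nan
    except (RuntimeError, ValueError) as err:
        warnings.warn(f"molecule {mol}: fit failed ({err}); excluded", stacklevel=2)
        k0 = delta = k0_se = delta_se = resid = np.nan
        converged = False
    try:
        step, step_sd = estimate_step(events)
    except ValueError:
        step = step_sd = None
    return MoleculeFit(
        molecule_id=mol,
        k0=k0,
        k0_se=float(k0_se),
        delta=delta,
        delta_se=float(delta_se),
        step=step,
        step_sd=step_sd,
        n_events=len(events) if method == "events" else int(sum(b.n_events for b in bins)),
        bins=bins,
        converged=converged,
        residual_norm=resid,
    )


def fit_molecules(
    events: pd.DataFrame,
    consts: TrapConstants,
    **kwargs,
) -> list[MoleculeFit]:
    """Fit every molecule in an event table (grouped by molecule_id)."""
    return [
        fit_molecule(g, consts, molecule_id=str(m), **kwargs)
        for m, g in events.groupby("molecule_id", sort=True)
    ]


def summarize_group(fits: Sequence[MoleculeFit], label: str = "") -> GroupSummary:
    """Characteristic group values: molecule-level mean +/- SEM for k0 and
    delta, mean +/- SD for step.  Non-converged molecules are excluded."""
    ok = [f for f in fits if f.converged]
    if len(ok) < 2:
        raise ValueError("need >= 2 converged molecules for a group summary")
    k0s = np.array([f.k0 for f in ok])
    deltas = np.array([f.delta for f in ok])
    steps = np.array([f.step for f in ok if f.step is not None], dtype=float)
    n = len(ok)
    return GroupSummary(
        label=label,
        n_molecules=n,
        k0_mean=float(k0s.mean()),
        k0_sem=float(k0s.std(ddof=1) / np.sqrt(n)),
        delta_mean=float(deltas.mean()),
        delta_sem=float(deltas.std(ddof=1) / np.sqrt(n)),
        step_mean=float(steps.mean()) if len(steps) else None,
        step_sd=float(steps.std(ddof=1)) if len(steps) > 1 else None,
    )


def compare_groups(
    a: Sequence[MoleculeFit],
    b: Sequence[MoleculeFit],
) -> pd.DataFrame:
    """Welch's t-test on molecule-level k0, delta, and step between two
    groups; each molecule is one replicate.  Returns a tidy report with
    Welch-Satterthwaite df and two-sided p per parameter."""
    rows = []
    for param in ("k0", "delta", "step"):
        xa = np.array(
            [getattr(f, param) for f in a if f.converged and getattr(f, param) is not None],
            dtype=float,
        )
        xb = np.array(
            [getattr(f, param) for f in b if f.converged and getattr(f, param) is not None],
            dtype=float,
        )
        if len(xa) < 2 or len(xb) < 2:
            continue
        t, df, p = welch_from_values(xa, xb)
        rows.append(
            {
                "parameter": param,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def welch_from_values(xa: np.ndarray, xb: np.ndarray):
    """Welch's unequal-variance t-test on two samples (t, df, p)."""
    if np.array_equal(xa, xb) and np.var(xa) == 0:
        return 0.0, float(len(xa) + len(xb) - 2), 1.0
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def percent_change(
    mutant: float,
    wt: float,
    sem_mutant: Optional[float] = None,
    sem_wt: Optional[float] = None,
):
    """Percent change of a mutant value relative to wild type,
    ``100*(mutant/wt - 1)``, with optional SEM by ratio propagation."""
    if wt == 0:
        raise ValueError("wild-type value must be nonzero")
    pct = 100.0 * (mutant / wt - 1.0)
    if sem_mutant is None or sem_wt is None:
        return pct
    ratio = mutant / wt
    sem = 100.0 * abs(ratio) * np.sqrt(
        (sem_mutant / mutant) ** 2 + (sem_wt / wt) ** 2
    )
    return pct, sem
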