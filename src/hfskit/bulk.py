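"""Bulk-solution kinetics: ATPase, single-turnover SRX, gel stoichiometry.

Covers the plate- and cuvette-scale computations around the trap work:

* Michaelis-Menten fitting of actin-activated ATPase rates, with the
  triplicate outlier rule (reject a technical replicate that differs from
  *both* of its two companions by more than 50%) and same-day control
  normalization;
* ratio statistics (2-hep/25-hep kcat ratios) with standard-error
  propagation for ratios and averages of ratios;
* five-parameter biexponential fitting of single mant-ATP turnover decays,
  giving the slow-phase (SRX) amplitude fraction, with an explicit
  ambiguity criterion standing in for by-eye fit rejection;
* light-chain stoichiometry from gel dilution-series slopes, with greedy
  top-load pruning of saturated (non-linear) points;
* paired and Welch t-tests used throughout the comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# triplicate rejection and Michaelis-Menten
# ---------------------------------------------------------------------------

def reject_triplicate_outliers(rates: Sequence[float]):
    """Apply the >50% triplicate rejection rule.

    A value is rejected iff it differs from each of the other two values
    by more than 50% *of that companion value* (the companions, not their
    mean, are the reference).  At most one of three values is rejected; if
    several qualify, the one with the largest worst-case relative
    deviation goes.  Inputs that are not exactly three values pass through
    unfiltered with a warning.

    Returns (kept_values, rejected_mask).
    """
    x = np.asarray(rates, dtype=float)
    if len(x) != 3:
        warnings.warn("triplicate rule needs exactly 3 values; passing through")
        return x, np.zeros(len(x), dtype=bool)
    rejected = np.zeros(3, dtype=bool)
    scores = []
    for i in range(3):
        others = np.delete(x, i)
        devs = np.abs(x[i] - others) / np.abs(others)
        if np.all(devs > 0.5):
            scores.append((devs.min(), i))
    if scores:
        _, worst = max(scores)
        rejected[worst] = True
    return x[~rejected], rejected


def _mm(a, kcat, Kapp):
    return kcat * a / (Kapp + a)


@dataclass
class MMFit:
    kcat: float
    kcat_se: float
    Kapp: float
    Kapp_se: float
    n_points: int
    rejected_points: list = field(default_factory=list)
    basal_rate: Optional[float] = None
    kapp_exceeds_range: bool = False


def fit_michaelis_menten(
    dataset: pd.DataFrame,
    apply_rejection: bool = True,
) -> MMFit:
    """Fit actin-activated rates to v = kcat*[A]/(Kapp + [A]).

    Expects columns ``actin_uM``, ``rate_per_s`` (and ``replicate`` if the
    triplicate rule is to apply).  Zero-actin rows are the basal rate:
    they are averaged and reported separately, never fitted.  Unweighted
    least squares in rate space; parameter SEs from the fit covariance.
    """
    basal = dataset[dataset["actin_uM"] == 0]
    basal_rate = float(basal["rate_per_s"].mean()) if len(basal) else None
    data = dataset[dataset["actin_uM"] > 0]
    if data["actin_uM"].nunique() < 4:
        raise ValueError("need >= 4 distinct actin concentrations")

    rejected = []
    if apply_rejection:
        kept_frames = []
        for a, grp in data.groupby("actin_uM"):
            vals = grp["rate_per_s"].to_numpy()
            if len(vals) == 3:
                _, mask = reject_triplicate_outliers(vals)
                kept_frames.append(grp[~mask])
                for idx in grp.index[mask]:
                    rejected.append((float(a), float(grp.loc[idx, "rate_per_s"])))
            else:
                kept_frames.append(grp)
        data = pd.concat(kept_frames)

    a = data["actin_uM"].to_numpy(float)
    v = data["rate_per_s"].to_numpy(float)
    p0 = (float(v.max()), float(np.median(a)))
    popt, pcov = optimize.curve_fit(_mm, a, v, p0=p0, bounds=(0, np.inf), maxfev=10000)
    ses = np.sqrt(np.diag(pcov))
    return MMFit(
        kcat=float(popt[0]),
        kcat_se=float(ses[0]),
        Kapp=float(popt[1]),
        Kapp_se=float(ses[1]),
        n_points=len(v),
        rejected_points=rejected,
        basal_rate=basal_rate,
        kapp_exceeds_range=bool(popt[1] > a.max()),
    )


def normalize_to_control(fit: MMFit, control: MMFit) -> MMFit:
    """Express a fit relative to a same-day control kcat.

    Rates (and hence kcat and its SE) are divided by the control kcat;
    Kapp is a concentration and is unchanged.  Normalizing a control by
    itself gives kcat = 1 exactly.
    """
    c = control.kcat
    return MMFit(
        kcat=fit.kcat / c,
        kcat_se=fit.kcat_se / c,
        Kapp=fit.Kapp,
        Kapp_se=fit.Kapp_se,
        n_points=fit.n_points,
        rejected_points=list(fit.rejected_points),
        basal_rate=None if fit.basal_rate is None else fit.basal_rate / c,
        kapp_exceeds_range=fit.kapp_exceeds_range,
    )


def propagate_ratio_se(a: float, se_a: float, b: float, se_b: float):
    """Ratio a/b with first-order SE propagation."""
    if a <= 0 or b <= 0:
        raise ValueError("ratio propagation requires positive values")
    r = a / b
    return r, r * np.sqrt((se_a / a) ** 2 + (se_b / b) ** 2)


def average_ratios(ratios: Sequence[tuple]):
    """Average of independent ratios; SE = sqrt(sum se_i^2)/n."""
    vals = np.array([r for r, _ in ratios], float)
    ses = np.array([s for _, s in ratios], float)
    n = len(vals)
    return float(vals.mean()), float(np.sqrt(np.sum(ses**2)) / n)


# ---------------------------------------------------------------------------
# single-turnover biexponential
# ---------------------------------------------------------------------------

@dataclass
class BiexpFit:
    amp_fast: float
    rate_fast: float
    amp_slow: float
    rate_slow: float
    plateau: float
    percent_slow: float
    ambiguous: bool
    ambiguous_reason: str = ""
    cov: Optional[np.ndarray] = None

    @property
    def percent_fast(self) -> float:
        return 100.0 - self.percent_slow

    def curve(self, t):
        t = np.asarray(t, float)
        return (
            self.amp_fast * np.exp(-self.rate_fast * t)
            + self.amp_slow * np.exp(-self.rate_slow * t)
            + self.plateau
        )

    def normalized_curve(self, t):
        """Fitted curve rescaled so Y(0) = 1 and the plateau is 0."""
        return (self.curve(t) - self.plateau) / (self.amp_fast + self.amp_slow)


def _biexp(t, af, rf, as_, rs, c):
    return af * np.exp(-rf * t) + as_ * np.exp(-rs * t) + c


def fit_biexponential(
    trace: pd.DataFrame,
    min_rate_separation: float = 3.0,
) -> BiexpFit:
    """Five-parameter biexponential fit of a single-turnover decay.

    Expects columns ``time_s`` (dead time already included) and
    ``fluorescence_au``.  The slow-phase percentage is the slow amplitude
    as a fraction of the total decaying amplitude,
    ``100*amp_slow/(amp_fast+amp_slow)`` (the plateau is excluded, since
    normalized traces map the plateau to zero).

    A fit is flagged ambiguous — not raised — when the two rates separate
    by less than ``min_rate_separation``-fold or either amplitude's 95% CI
    crosses zero; these are the cases a practitioner would discard by eye.
    """
    t = trace["time_s"].to_numpy(float)
    f = trace["fluorescence_au"].to_numpy(float)
    if len(t) < 50:
        warnings.warn("fewer than 50 time points: biexponential fit may be fragile")
    span = t.max() - t.min()
    c0 = float(f.min())
    amp0 = max(float(f[0] - c0), 1e-12)
    p0 = (0.5 * amp0, 10.0 / span, 0.5 * amp0, 1.0 / span, c0)
    try:
        popt, pcov = optimize.curve_fit(
            _biexp, t, f, p0=p0,
            bounds=([0, 1e-12, 0, 1e-12, -np.inf], np.inf),
            maxfev=20000,
        )
    except RuntimeError:
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                        ambiguous=True, ambiguous_reason="fit did not converge")
    af, rf, as_, rs, c = popt
    if rf < rs:  # order phases: fast first
        af, rf, as_, rs = as_, rs, af, rf
        popt = np.array([af, rf, as_, rs, c])
    ses = np.sqrt(np.diag(pcov))
    total = af + as_
    pct_slow = 100.0 * as_ / total if total > 0 else np.nan

    reason = ""
    if rs <= 0 or rf / rs < min_rate_separation:
        reason = f"rate separation {rf/max(rs,1e-300):.2f} < {min_rate_separation}"
    elif af - 1.96 * ses[0] <= 0 or as_ - 1.96 * ses[2] <= 0:
        reason = "amplitude confidence interval includes zero"
    return BiexpFit(
        amp_fast=float(af),
        rate_fast=float(rf),
        amp_slow=float(as_),
        rate_slow=float(rs),
        plateau=float(c),
        percent_slow=float(pct_slow),
        ambiguous=bool(reason),
        ambiguous_reason=reason,
        cov=pcov,
    )


def srx_difference(group_a: Sequence[float], group_b: Sequence[float], welch: bool = False):
    """Difference in mean slow-phase percentage between two replicate sets.

    Returns (mean_a - mean_b in percentage points, SEM of the difference
    by quadrature, two-sided unpaired t-test p).  Pooled-variance t by
    default; Welch optional.
    """
    xa = np.asarray(group_a, float)
    xb = np.asarray(group_b, float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 replicates per group")
    diff = float(xa.mean() - xb.mean())
    sem = float(
        np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
    )
    if np.array_equal(xa, xb) and xa.var() == 0:
        return diff, sem, 1.0
    res = stats.ttest_ind(xa, xb, equal_var=not welch)
    return diff, sem, float(res.pvalue)


# ---------------------------------------------------------------------------
# gel dilution-series stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class ChainFit:
    chain: str
    slope: float
    slope_se: float
    r_squared: float
    loads_used: list = field(default_factory=list)
    loads_pruned: list = field(default_factory=list)


@dataclass
class GelStoichiometry:
    chains: dict  # chain -> ChainFit
    elc_hc: Optional[tuple] = None  # (ratio, se)
    rlc_hc: Optional[tuple] = None


def _linfit(load, dens):
    res = stats.linregress(load, dens)
    return res.slope, res.stderr, res.rvalue**2


def fit_gel_stoichiometry(
    series: pd.DataFrame,
    r2_improvement: float = 0.02,
) -> GelStoichiometry:
    """Light-chain:heavy-chain stoichiometry from dilution-series slopes.

    Expects columns ``chain`` (HC/ELC/RLC), ``load_pmol``, ``density_au``.
    Per chain, the highest load is greedily pruned while removing it
    improves the linear fit R^2 by more than ``r2_improvement`` (the heavy
    chain's top load typically saturates the stain), keeping at least 3
    points.  Ratios are light-chain slope over heavy-chain slope with
    propagated SE.  Chains left with fewer than 3 usable points are
    excluded with a warning.
    """
    chains = {}
    for chain, grp in series.groupby("chain"):
        grp = grp.sort_values("load_pmol")
        load = grp["load_pmol"].to_numpy(float)
        dens = grp["density_au"].to_numpy(float)
        if len(load) < 3:
            warnings.warn(f"chain {chain}: fewer than 3 points; excluded")
            continue
        if len(load) < 4:
            warnings.warn(f"chain {chain}: <4 loads, pruning disabled")
        pruned = []
        while len(load) > 3:
            _, _, r2_full = _linfit(load, dens)
            _, _, r2_drop = _linfit(load[:-1], dens[:-1])
            if r2_drop - r2_full > r2_improvement:
                pruned.append(float(load[-1]))
                load, dens = load[:-1], dens[:-1]
            else:
                break
        slope, se, r2 = _linfit(load, dens)
        if slope <= 0:
            warnings.warn(f"chain {chain}: non-positive slope; excluded")
            continue
        chains[chain] = ChainFit(
            chain=chain,
            slope=float(slope),
            slope_se=float(se),
            r_squared=float(r2),
            loads_used=[float(x) for x in load],
            loads_pruned=pruned,
        )
    out = GelStoichiometry(chains=chains)
    if "HC" in chains:
        hc = chains["HC"]
        for lc, attr in (("ELC", "elc_hc"), ("RLC", "rlc_hc")):
            if lc in chains:
                setattr(
                    out,
                    attr,
                    propagate_ratio_se(
                        chains[lc].slope, chains[lc].slope_se, hc.slope, hc.slope_se
                    ),
                )
    return out


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def paired_t_test(x: Sequence[float], y: Sequence[float]):
    """Paired two-sided t-test; returns (t, df, p).

    Zero-variance identical pairs return (0, n-1, 1) rather than NaN.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if len(xa) != len(ya):
        raise ValueError("paired test needs matched vectors")
    d = xa - ya
    if np.all(d == d[0]) and d[0] == 0:
        return 0.0, float(len(d) - 1), 1.0
    res = stats.ttest_rel(xa, ya)
    return float(res.statistic), float(len(d) - 1), float(res.pvalue)


def welch_t_test(x: Sequence[float], y: Sequence[float]):
    """Welch's unequal-variance t-test; returns (t, df, p) with
    Welch-Satterthwaite degrees of freedom."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.array_equal(xa, ya) and xa.var() == 0:
        return 0.0, float(len(xa) + len(ya) - 2), 1.0
    res = stats.ttest_ind(xa, ya, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
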