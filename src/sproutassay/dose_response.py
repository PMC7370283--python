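"""Four-parameter logistic (4PL) dose-response fitting and IC50 estimation.

The inhibition model is the standard Hill form

    R(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

fitted by nonlinear least squares.  The curve is evaluated in linear
concentration so vehicle controls (c = 0) sit exactly on the top plateau,
while IC50 itself is optimised on a log10 scale for conditioning; on
plots, vehicle controls are conventionally drawn two decades below the
lowest nonzero dose.  Confidence intervals on IC50 come from a
case-resampling bootstrap with a percentile interval on log10(IC50),
because per-concentration replicate numbers in chip-based screens are too
small for Wald intervals to be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "fit_4pl",
    "ic50_confidence_interval",
    "normalize_responses",
]

# pseudo-log plotting position of vehicle controls: decades below lowest dose
_ZERO_DOSE_DECADES = 2.0


@dataclass
class DoseResponseFit:
    """Result of a 4PL fit.

    ``ci_low``/``ci_high`` are NaN until :func:`ic50_confidence_interval`
    fills them in.  ``converged`` is False when the optimiser failed or the
    data carry no dose dependence; the parameter fields then hold the best
    available values and should not be interpreted.
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    ci_low: float
    ci_high: float
    n_points: int
    converged: bool
    residual_sd: float
    message: str = ""

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        """Fitted response at the given concentration(s)."""
        c = np.asarray(conc, dtype=float)
        out = _four_pl(c, self.top, self.bottom, np.log10(self.ic50), self.hill)
        return float(out) if np.isscalar(conc) else out


def _four_pl(c: np.ndarray, top: float, bottom: float,
             log_ic50: float, hill: float) -> np.ndarray:
    """Hill inhibition curve in linear concentration; exact at c = 0."""
    ratio = np.zeros_like(c, dtype=float)
    pos = c > 0
    ratio[pos] = (c[pos] / 10.0 ** log_ic50) ** hill
    return bottom + (top - bottom) / (1.0 + ratio)


def log_position(c: np.ndarray) -> np.ndarray:
    """Plotting positions: log10 dose, with c=0 two decades below the minimum."""
    c = np.asarray(c, dtype=float)
    pos = c[c > 0]
    floor = np.log10(pos.min()) - _ZERO_DOSE_DECADES if pos.size else 0.0
    logc = np.full_like(c, floor, dtype=float)
    logc[c > 0] = np.log10(c[c > 0])
    return logc


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
) -> DoseResponseFit:
    """Fit the 4PL inhibition model to per-chip responses.

    Parameters
    ----------
    concentrations
        One concentration per observation (replicates repeat the value);
        at least 4 distinct concentrations are required for identifiability.
    responses
        Per-chip readout values (same length).

    Returns
    -------
    DoseResponseFit
        Non-convergence is reported through ``converged=False`` rather than
        an exception, so a screen over many compounds can continue.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c < 0):
        raise ValueError("negative concentrations are not physical")
    distinct = np.unique(c)
    if distinct.size < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations for a 4PL fit, got {distinct.size}"
        )

    # initialisation: top at the low-dose mean, bottom at the high-dose mean
    # (floored at 0), IC50 at the geometric mean of the positive doses
    pos = c[c > 0]
    top0 = float(r[c == c.min()].mean())
    bottom0 = max(0.0, float(r[c == c.max()].mean()))
    log_ic50_0 = float(np.log10(pos).mean()) if pos.size else 0.0
    span = max(top0 - bottom0, 1e-12)

    pos_log = np.log10(pos) if pos.size else np.array([0.0])
    lower = [-np.inf, 0.0, pos_log.min() - 3.0, 1e-3]
    upper = [np.inf, np.inf, pos_log.max() + 3.0, 10.0]
    p0 = [top0, bottom0, np.clip(log_ic50_0, lower[2], upper[2]), 1.0]

    try:
        popt, _ = curve_fit(
            _four_pl, c, r, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return DoseResponseFit(
            top=top0, bottom=bottom0, ic50=10.0 ** p0[2], hill=np.nan,
            ci_low=np.nan, ci_high=np.nan, n_points=int(c.size),
            converged=False, residual_sd=np.nan, message=str(exc),
        )

    top, bottom, log_ic50, hill = popt
    resid = r - _four_pl(c, *popt)
    dof = max(c.size - 4, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))

    # a fit whose plateaus are indistinguishable, or whose span is buried in
    # the residual noise, carries no dose information
    span_floor = max(0.02 * max(abs(top), span), 2.0 * residual_sd)
    identifiable = (top - bottom) > span_floor and hill > 2e-3
    # IC50 extrapolated beyond the sampled dose range is not trustworthy
    in_range = pos_log.min() - 1.5 <= log_ic50 <= pos_log.max() + 1.5
    converged = bool(identifiable and in_range)

    return DoseResponseFit(
        top=float(top), bottom=float(bottom), ic50=float(10.0 ** log_ic50),
        hill=float(hill), ci_low=np.nan, ci_high=np.nan,
        n_points=int(c.size), converged=converged, residual_sd=residual_sd,
        message="" if converged else "dose dependence not identifiable",
    )


def ic50_confidence_interval(
    fit: DoseResponseFit,
    concentrations: Sequence[float],
    responses: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """95% percentile bootstrap interval on IC50 (case resampling).

    Observations (concentration, response pairs) are resampled with
    replacement ``n_boot`` times and refitted; the interval is taken from
    the 2.5/97.5 percentiles of the bootstrap log10(IC50) distribution.
    If more than 20% of the resamples fail to produce a usable fit, a
    warning is raised because the interval is then optimistic.
    """
    if not fit.converged:
        raise ValueError("confidence interval requires a converged fit")
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    rng = np.random.default_rng(seed)
    boots: list[float] = []
    n_fail = 0
    for _ in range(n_boot):
        idx = rng.integers(0, c.size, size=c.size)
        if np.unique(c[idx]).size < 4:
            n_fail += 1
            continue
        try:
            bf = fit_4pl(c[idx], r[idx])
        except ValueError:
            n_fail += 1
            continue
        if bf.converged:
            boots.append(np.log10(bf.ic50))
        else:
            n_fail += 1
    if n_fail > 0.2 * n_boot:
        warnings.warn(
            f"{n_fail}/{n_boot} bootstrap refits failed; interval may be "
            "too narrow",
            RuntimeWarning,
            stacklevel=2,
        )
    if not boots:
        return (fit.ic50, fit.ic50)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    fit.ci_low, fit.ci_high = float(10.0 ** lo), float(10.0 ** hi)
    return fit.ci_low, fit.ci_high


def normalize_responses(
    metrics: pd.DataFrame,
    readout: str,
    control_label: str = "max_control",
    role_column: str = "role",
) -> pd.Series:
    """Express a readout as fraction of the mean of the vehicle-control group.

    Normalisation cancels units (a readout in pixels scaled by pixel size
    gives the same fractions as one in µm) and places the control plateau
    at 1 for cross-readout comparison.

    Raises
    ------
    ValueError
        If the control group is absent or has zero mean.
    """
    if role_column not in metrics.columns:
        raise ValueError(f"metrics table has no '{role_column}' column")
    ctrl = metrics.loc[metrics[role_column] == control_label, readout]
    if ctrl.empty:
        raise ValueError(f"no rows with role '{control_label}' in metrics table")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control group mean is zero; cannot normalise")
    return metrics[readout] / ctrl_mean
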