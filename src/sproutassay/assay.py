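"""Plate-level assay-performance statistics and acceptance criteria.

The screening readouts of the sprouting assay are characterised against
max-signal (vehicle, 0 nM inhibitor) and min-signal (saturating inhibitor)
control groups.  The statistics implemented here follow the assay-guidance
convention in which the 3-standard-error guard bands are subtracted from
each control group before comparing them:

    SW = [(AVGmax - 3*SDmax/sqrt(n_max)) - (AVGmin + 3*SDmin/sqrt(n_min))]
         / (SDmax/sqrt(n_max))

    Z' = [(AVGmax - 3*SDmax/sqrt(n_max)) - (AVGmin + 3*SDmin/sqrt(n_min))]
         / (AVGmax - AVGmin)

    AVR = 3*(SDmax + SDmin) / (AVGmax - AVGmin)

Group sizes enter per group (n_max, n_min) because screening plates rarely
carry identical numbers of max- and min-controls (e.g. 15 vs 14 after a
failed chip).  The assay variability ratio (AVR) complements Z' without the
sqrt(n) scaling; it equals 1 minus the classic plate-level Z-factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GroupStats",
    "AssayPerformance",
    "group_stats",
    "signal_window",
    "z_factor",
    "assay_variability_ratio",
    "evaluate_acceptance",
    "reconstruct_group_params",
]


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one metric for one treatment group.

    Attributes
    ----------
    mean : float
        Sample mean (AVG).
    sd : float
        Sample standard deviation (n-1 denominator).
    n : int
        Number of chips in the group.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2 measurements, got n={self.n}")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")

    @property
    def cv(self) -> float:
        """Coefficient of variation SD/AVG as a fraction; undefined at mean 0."""
        if self.mean == 0:
            raise ZeroDivisionError("CV undefined for zero mean")
        return self.sd / self.mean

    @property
    def sem(self) -> float:
        """Standard error of the mean, SD/sqrt(n)."""
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class AssayPerformance:
    """Assay-performance report for one readout on one plate.

    CVs are reported in percent; ``flags`` holds the individual acceptance
    booleans and ``passed`` their conjunction.
    """

    sw: float
    z_factor: float
    avr: float
    cv_max_pct: float
    cv_min_pct: float
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.flags.values())


def group_stats(values: Sequence[float]) -> GroupStats:
    """Sample mean, SD (n-1) and n of a control group.

    Raises
    ------
    ValueError
        If fewer than two finite values are supplied.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in group")
    return GroupStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


def _guard_banded_separation(gmax: GroupStats, gmin: GroupStats) -> float:
    return (gmax.mean - 3.0 * gmax.sem) - (gmin.mean + 3.0 * gmin.sem)


def signal_window(gmax: GroupStats, gmin: GroupStats) -> float:
    """Signal window: guard-banded group separation in units of SE of the max group.

    May be negative for a non-separating assay; that is diagnostic
    information and is deliberately not clamped.

    Raises
    ------
    ZeroDivisionError
        If the max group has zero standard deviation (SW undefined).
    """
    if gmax.sd == 0:
        raise ZeroDivisionError("signal window undefined: SDmax is zero")
    return _guard_banded_separation(gmax, gmin) / gmax.sem


def z_factor(gmax: GroupStats, gmin: GroupStats) -> float:
    """Z-factor: guard-banded separation normalised by the difference of means.

    Equals 1 for a noiseless assay and decreases as the guard bands eat into
    the dynamic range.  Uses per-group n in the standard errors.

    Raises
    ------
    ZeroDivisionError
        If the two group means coincide.
    """
    denom = gmax.mean - gmin.mean
    if denom == 0:
        raise ZeroDivisionError(
            "Z-factor undefined: max- and min-control means are equal "
            "(no dynamic range)"
        )
    return _guard_banded_separation(gmax, gmin) / denom


def assay_variability_ratio(gmax: GroupStats, gmin: GroupStats) -> float:
    """Assay variability ratio AVR = 3*(SDmax + SDmin)/(AVGmax - AVGmin).

    The combined 3-SD spread of both control groups relative to their mean
    separation; equals 1 minus the classic plate-level Z-factor (the variant
    without the sqrt(n) scaling).  Values below 0.6 are conventionally
    recommended for screening.
    """
    denom = gmax.mean - gmin.mean
    if denom == 0:
        raise ZeroDivisionError("AVR undefined: group means are equal")
    return 3.0 * (gmax.sd + gmin.sd) / denom


def evaluate_acceptance(
    gmax: GroupStats,
    gmin: GroupStats,
    *,
    z_min: float = 0.4,
    sw_min: float = 2.0,
    cv_max_limit: float = 0.20,
) -> AssayPerformance:
    """Compute all performance statistics and the plate acceptance flags.

    The acceptance criteria are: Z' >= 0.4, SW >= 2, CV of the max-signal
    group <= 20%, and SDmin <= SDmax for the min-signal group.
    """
    sw = signal_window(gmax, gmin)
    zf = z_factor(gmax, gmin)
    avr = assay_variability_ratio(gmax, gmin)
    cv_max = gmax.cv
    cv_min = gmin.cv if gmin.mean != 0 else float("nan")
    flags = {
        "z_ok": zf >= z_min,
        "sw_ok": sw >= sw_min,
        "cv_ok": cv_max <= cv_max_limit,
        "sd_ok": gmin.sd <= gmax.sd,
    }
    return AssayPerformance(
        sw=sw,
        z_factor=zf,
        avr=avr,
        cv_max_pct=100.0 * cv_max,
        cv_min_pct=100.0 * cv_min,
        flags=flags,
    )


def reconstruct_group_params(
    zp: float,
    cv_max: float,
    cv_min: float,
    n_max: int,
    n_min: int,
) -> tuple[GroupStats, GroupStats]:
    """Invert the Z-factor formula to recover normalised control-group parameters.

    Given a reported Z-factor and the two control-group CVs (as fractions),
    solve for the group means and SDs on a scale where AVGmax = 1.  With
    SDmax = cv_max and SDmin = cv_min * AVGmin, the Z' definition is linear
    in AVGmin:

        AVGmin = (1 - 3*cv_max/sqrt(n_max) - Z')
                 / (1 + 3*cv_min/sqrt(n_min) - Z')

    This makes published summary tables (Z', CVs, group sizes) sufficient to
    recompute the signal window and assay variability ratio they imply, even
    when the underlying per-chip data are not available.

    Returns
    -------
    (gmax, gmin) : tuple of GroupStats
        Normalised group parameters satisfying ``z_factor(gmax, gmin) == zp``
        and the given CVs exactly.

    Raises
    ------
    ValueError
        If the inputs are infeasible (AVGmin outside (0, 1), or a degenerate
        denominator).
    """
    denom = 1.0 + 3.0 * cv_min / math.sqrt(n_min) - zp
    if denom == 0:
        raise ValueError("degenerate inputs: AVGmin is unconstrained")
    avg_min = (1.0 - 3.0 * cv_max / math.sqrt(n_max) - zp) / denom
    if not 0.0 < avg_min < 1.0:
        raise ValueError(
            f"infeasible inputs: reconstructed AVGmin={avg_min:.4g} "
            "outside (0, 1)"
        )
    gmax = GroupStats(mean=1.0, sd=cv_max, n=n_max)
    gmin = GroupStats(mean=avg_min, sd=cv_min * avg_min, n=n_min)
    return gmax, gmin
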