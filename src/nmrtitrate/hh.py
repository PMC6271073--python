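"""Henderson–Hasselbalch stage: semilog linearization and pKa extraction.

For a fast-exchange two-state site the observed shift interpolates the
limiting shifts with the deprotonated fraction, so

    log10[(δ_max − δ_obs) / (δ_obs − δ_min)] = ±(pKa − pH)

and the transformed titration curve is a straight line of unit absolute
slope crossing zero at pH = pKa.  The stage therefore consists of
(1) estimating the limiting shifts from the titration plateaus,
(2) applying the semilog transform, and (3) an ordinary least-squares
line whose zero crossing −intercept/slope is the pKa.  Regressing the
log ratio on pH (rather than reading the crossing off a plot) leaves the
zero crossing unchanged and gives well-behaved error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import DegenerateDataError, TitrationError, TitrationSeries

__all__ = [
    "LimitingShifts",
    "HHTable",
    "HHFit",
    "FitError",
    "NoTransitionError",
    "ka_to_pka",
    "pka_to_ka",
    "extract_limits",
    "hh_transform",
    "fit_pka",
]

#: |slope| below which the transformed data shows no usable transition.
MIN_SLOPE = 0.1
#: |slope| outside this band flags deviation from ideal two-state behaviour.
SLOPE_BAND = (0.8, 1.2)
#: Plateau spread above this fraction of the shift range flags truncation.
PLATEAU_SPREAD_TOL = 0.05


class FitError(TitrationError):
    """The regression could not be performed (singular design)."""


class NoTransitionError(FitError):
    """The transformed data carries no resolvable acid-base transition."""


def ka_to_pka(Ka: float) -> float:
    """pKa = −log10(Ka).  Ka must be strictly positive."""
    if Ka <= 0:
        raise ValueError("Ka must be positive")
    return -math.log10(Ka)


def pka_to_ka(pKa: float) -> float:
    """Ka = 10^(−pKa)."""
    if not math.isfinite(pKa):
        raise ValueError("pKa must be finite")
    return 10.0 ** (-pKa)


@dataclass(frozen=True)
class LimitingShifts:
    """Limiting (plateau) shifts of one probe.

    ``delta_min``/``delta_max`` are assigned by value ordering, not by
    titration direction.  ``spread_low``/``spread_high`` are the in-plateau
    peak-to-peak spreads of the two endpoint windows; ``truncated`` is set
    when either spread exceeds :data:`PLATEAU_SPREAD_TOL` of the range —
    the sign of a titration stopped before the curve levelled off.
    """

    delta_min: float
    delta_max: float
    probe: str
    n_plateau: int
    spread_low: float = 0.0
    spread_high: float = 0.0
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.delta_min < self.delta_max:
            raise ValueError(
                f"degenerate limits for probe {self.probe!r}: "
                f"delta_min={self.delta_min} must be < delta_max={self.delta_max}"
            )


@dataclass(frozen=True)
class HHTable:
    """Semilog-transformed titration data for one probe."""

    pH: np.ndarray
    y: np.ndarray
    n_excluded: int
    probe: str


@dataclass(frozen=True)
class HHFit:
    """Result of the semilog line fit.

    pKa is the pH at which the fitted line crosses zero; ``slope_deviation``
    is set when |slope| falls outside :data:`SLOPE_BAND`, indicating the
    data departs from ideal single-site two-state behaviour.
    """

    pKa: float
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int
    pKa_stderr: float
    slope_deviation: bool


def extract_limits(
    series: TitrationSeries, probe: str, n_plateau: int = 3
) -> LimitingShifts:
    """Estimate the limiting shifts from the two titration plateaus.

    The value at each end is the mean of the first/last ``n_plateau``
    observations of *probe* (titration order).  Needs at least
    ``2 * n_plateau`` points carrying the probe.
    """
    if n_plateau < 1:
        raise ValueError("n_plateau must be at least 1")
    values = [s for _, s in series.shifts_for(probe)]
    if len(values) < 2 * n_plateau:
        raise DegenerateDataError(
            f"probe {probe!r}: need at least {2 * n_plateau} observed points, "
            f"got {len(values)}"
        )
    head = np.array(values[:n_plateau])
    tail = np.array(values[-n_plateau:])
    lo_mean, hi_mean = sorted((head.mean(), tail.mean()))
    rng = hi_mean - lo_mean
    spreads = sorted((np.ptp(head), np.ptp(tail)))
    truncated = bool(rng > 0 and max(spreads) > PLATEAU_SPREAD_TOL * rng)
    # spread_low/high follow the value ordering of the plateau means
    if head.mean() <= tail.mean():
        spread_low, spread_high = float(np.ptp(head)), float(np.ptp(tail))
    else:
        spread_low, spread_high = float(np.ptp(tail)), float(np.ptp(head))
    return LimitingShifts(
        delta_min=float(lo_mean),
        delta_max=float(hi_mean),
        probe=probe,
        n_plateau=n_plateau,
        spread_low=spread_low,
        spread_high=spread_high,
        truncated=truncated,
    )


def hh_transform(
    series: TitrationSeries, probe: str, limits: LimitingShifts
) -> HHTable:
    """Tabulate log10[(δ_max − δ_obs)/(δ_obs − δ_min)] against pH.

    Points where the ratio is not strictly positive (observations at or
    beyond a limiting shift, typical of plateau points) are excluded and
    counted, not treated as errors.
    """
    pH_list: list[float] = []
    y_list: list[float] = []
    excluded = 0
    for pH, obs in series.shifts_for(probe):
        num = limits.delta_max - obs
        den = obs - limits.delta_min
        if num <= 0.0 or den <= 0.0:
            excluded += 1
            continue
        pH_list.append(pH)
        y_list.append(math.log10(num / den))
    if len(y_list) < 2:
        raise DegenerateDataError(
            f"probe {probe!r}: only {len(y_list)} transformable point(s) "
            f"({excluded} excluded)"
        )
    return HHTable(np.array(pH_list), np.array(y_list), excluded, probe)


def fit_pka(table: HHTable) -> HHFit:
    """Ordinary least squares of the semilog ordinate on pH.

    pKa = −intercept/slope (the zero crossing).  Its standard error comes
    from first-order propagation through the full slope/intercept
    covariance.  A fit with |slope| < 0.1 is refused: such data shows no
    transition, only noise around a plateau.
    """
    x, y = table.pH, table.y
    n = x.size
    if n < 2:
        raise DegenerateDataError("need at least 2 transformed points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise FitError("singular design: all pH values equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if abs(slope) < MIN_SLOPE:
        raise NoTransitionError(
            f"|slope| = {abs(slope):.3g} < {MIN_SLOPE}: no resolvable transition"
        )
    pKa = -intercept / slope

    # parameter covariance of the straight-line fit
    sigma2 = ss_res / (n - 2) if n > 2 else 0.0
    var_slope = sigma2 / sxx
    var_intercept = sigma2 * (1.0 / n + x.mean() ** 2 / sxx)
    cov_si = -sigma2 * x.mean() / sxx
    # pKa = -b0/b1: gradient (-1/b1, b0/b1^2)
    g0, g1 = -1.0 / slope, intercept / slope**2
    var_pka = g0 * g0 * var_intercept + g1 * g1 * var_slope + 2 * g0 * g1 * cov_si
    pKa_stderr = math.sqrt(max(var_pka, 0.0))

    lo, hi = SLOPE_BAND
    return HHFit(
        pKa=pKa,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_used=int(n),
        n_excluded=table.n_excluded,
        pKa_stderr=pKa_stderr,
        slope_deviation=not lo <= abs(slope) <= hi,
    )
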