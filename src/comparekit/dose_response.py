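"""IC50 estimation from viability curves and degree-of-resistance ratios.

The primary estimator fits a four-parameter logistic (4PL) to viability
versus log10 concentration.  Because viability is normalised to the
untreated control, the IC50 is defined as the concentration at which the
*fitted* curve crosses 50% of control (absolute), not the curve midpoint.
If the least-squares fit fails, a log-linear interpolation between the
points bracketing 50% serves as fallback; if viability never reaches 50%
the estimate is censored at the highest tested concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_formats import ValidationError

log = logging.getLogger("comparekit")

#: viability may rise this much between successive concentrations before a
#: non-monotonicity warning is logged (assay noise is expected)
MONOTONE_TOL = 0.15


@dataclass
class DoseResponseCurve:
    """Mean viability (fraction of untreated control) per concentration (uM)."""

    concentrations: np.ndarray
    viability: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if len(np.unique(self.concentrations)) < 4:
            raise ValidationError("need >= 4 distinct concentrations")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError("concentrations must be strictly ascending")
        if self.concentrations.shape != self.viability.shape:
            raise ValidationError("concentration/viability length mismatch")
        if np.any(self.viability < 0):
            raise ValidationError("viability must be non-negative")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DoseResponseCurve":
        """Aggregate a tidy replicate table (concentration_uM, viability)."""
        grouped = table.groupby("concentration_uM")["viability"]
        mean = grouped.mean().sort_index()
        sd = grouped.std(ddof=1).reindex(mean.index)
        return cls(
            concentrations=mean.index.to_numpy(),
            viability=mean.to_numpy(),
            replicate_sd=sd.to_numpy(),
        )


@dataclass
class IC50Estimate:
    """Point estimate (uM) or a censored bound when 50% is never reached."""

    ic50: float | None
    method: str  # "4PL" or "interpolation"
    censored: bool = False
    censor_bound: str | None = None  # e.g. "> 500 uM"
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.censored and (self.ic50 is None or self.ic50 <= 0):
            raise ValidationError("non-censored IC50 must be positive")


@dataclass
class ResistanceRatio:
    """Degree of resistance: resistant-line IC50 over parental-line IC50."""

    ratio: float
    resistant_id: str
    parental_id: str
    collateral_sensitive: bool

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValidationError("resistance ratio must be positive")


def _four_pl(logc: np.ndarray, top: float, bottom: float,
             log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def interpolate_ic50(concentrations: np.ndarray | list[float],
                     viability: np.ndarray | list[float]) -> float:
    """Log-linear interpolation of the 50%-of-control crossing.

    Uses the first adjacent pair of points bracketing 0.5.  Works on any
    bracket of >= 2 points; :func:`fit_dose_response` uses it as the fallback
    when the 4PL fit does not converge.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viability, dtype=float)
    for i in range(len(conc) - 1):
        v1, v2 = viab[i], viab[i + 1]
        if (v1 - 0.5) * (v2 - 0.5) <= 0 and v1 != v2:
            lc1, lc2 = np.log10(conc[i]), np.log10(conc[i + 1])
            frac = (v1 - 0.5) / (v1 - v2)
            return float(10.0 ** (lc1 + frac * (lc2 - lc1)))
    raise ValidationError("viability does not bracket 0.5")


def fit_dose_response(curve: DoseResponseCurve) -> IC50Estimate:
    """Estimate the IC50 of a viability curve.

    4PL least squares on log10 concentration with bottom constrained >= 0 and
    top free near 1; falls back to log-linear interpolation, and returns a
    censored estimate when viability stays above 50% up to the highest
    concentration tested.
    """
    conc, viab = curve.concentrations, curve.viability
    rises = np.diff(viab)
    if np.any(rises > MONOTONE_TOL):
        log.warning(
            "viability rises by up to %.2f with concentration; "
            "proceeding (noise expected)", float(rises.max()),
        )

    if viab.min() > 0.5:
        bound = f"> {conc.max():g} uM"
        log.info("viability never crosses 0.5; censored estimate %s", bound)
        return IC50Estimate(ic50=None, method="4PL", censored=True,
                            censor_bound=bound)
    if viab.max() < 0.5:
        bound = f"< {conc.min():g} uM"
        log.info("viability below 0.5 everywhere; censored estimate %s", bound)
        return IC50Estimate(ic50=None, method="4PL", censored=True,
                            censor_bound=bound)

    logc = np.log10(conc)
    # initial log IC50: concentration whose viability is closest to 0.5
    x0 = np.array([1.0, 0.0, logc[np.argmin(np.abs(viab - 0.5))], 1.0])
    bounds = (
        np.array([0.55, 0.0, logc.min() - 2.0, 0.05]),
        np.array([1.5, 0.45, logc.max() + 2.0, 10.0]),
    )
    x0 = np.clip(x0, bounds[0], bounds[1])
    try:
        fit = least_squares(
            lambda p: _four_pl(logc, *p) - viab, x0, bounds=bounds,
        )
        if not fit.success:
            raise RuntimeError(fit.message)
        top, bottom, log_ic50, hill = fit.x
        # absolute 50%-of-control crossing of the fitted curve
        x = (top - bottom) / (0.5 - bottom) - 1.0
        if x <= 0:
            raise RuntimeError("fitted curve does not cross 0.5")
        ic50 = float(10.0 ** (log_ic50 + np.log10(x) / hill))
        return IC50Estimate(ic50=ic50, method="4PL")
    except (RuntimeError, ValueError) as exc:
        log.warning("4PL fit failed (%s); falling back to interpolation", exc)
        return IC50Estimate(
            ic50=interpolate_ic50(conc, viab), method="interpolation"
        )


def resistance_ratio(
    ic50_resistant: float | IC50Estimate,
    ic50_parental: float | IC50Estimate,
    resistant_id: str = "resistant",
    parental_id: str = "parental",
) -> ResistanceRatio:
    """Degree of resistance, rounded half-up to 2 decimals.

    A ratio below 1 flags collateral sensitivity (the resistant line is
    hypersensitive relative to its parental line).  Censored estimates are
    rejected: only a bound on the ratio can be reported for those.
    """
    values = []
    for est, label in ((ic50_resistant, resistant_id),
                       (ic50_parental, parental_id)):
        if isinstance(est, IC50Estimate):
            if est.censored:
                raise ValidationError(
                    f"IC50 of {label} is censored ({est.censor_bound}); "
                    "report a ratio bound instead of a point ratio"
                )
            est = est.ic50
        if est is None or est <= 0:
            raise ValidationError(f"IC50 of {label} must be positive")
        values.append(float(est))
    raw = values[0] / values[1]
    rounded = float(
        Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
    return ResistanceRatio(
        ratio=rounded,
        resistant_id=resistant_id,
        parental_id=parental_id,
        collateral_sensitive=raw < 1.0,
    )
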