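"""Starch-iodine amylase assay analysis.

Pipeline: absorbance pairs (blank, sample) → activity units →
% inhibition relative to a no-inhibitor control → probit regression of
inhibition proportion on log10(concentration) → IC50 with replicate
summary (mean ± SEM).

The activity unit is ``(E_B1 − E_S) / E_B1 × 800`` where E_S is the
absorbance of the starch-iodine complex with sample and E_B1 the blank; the
factor 800 is an opaque assay scale and cancels out of % inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ACTIVITY_SCALE",
    "PROPORTION_EPS",
    "AssayReading",
    "ActivityResult",
    "DoseResponsePoint",
    "ProbitFit",
    "ReplicateSummary",
    "activity_units",
    "percent_inhibition",
    "fit_probit",
    "ic50_replicate_summary",
    "plate_to_dose_response",
]

ACTIVITY_SCALE = 800.0
#: proportions are clipped into [EPS, 1-EPS] so that 0%/100% observations
#: remain usable on the probit scale
PROPORTION_EPS = 1e-6

_MAX_ITER = 100
_DEVIANCE_TOL = 1e-10


@dataclass(frozen=True)
class AssayReading:
    """One absorbance pair at 581 nm; ``concentration`` 0 marks a
    no-inhibitor control."""

    replicate_id: str
    concentration: float  # mg/mL
    absorbance_blank_EB1: float
    absorbance_sample_ES: float

    def __post_init__(self) -> None:
        if not self.replicate_id:
            raise ValueError("replicate_id must be non-empty")
        if not (math.isfinite(self.concentration) and self.concentration >= 0):
            raise ValueError(f"concentration must be >= 0, got {self.concentration!r}")
        if not (math.isfinite(self.absorbance_blank_EB1) and self.absorbance_blank_EB1 > 0):
            raise ValueError(
                f"absorbance_blank_EB1 must be positive, got {self.absorbance_blank_EB1!r}"
            )
        if not (math.isfinite(self.absorbance_sample_ES) and self.absorbance_sample_ES >= 0):
            raise ValueError(
                f"absorbance_sample_ES must be >= 0, got {self.absorbance_sample_ES!r}"
            )


@dataclass(frozen=True)
class ActivityResult:
    replicate_id: str
    concentration: float
    activity_units: float
    warning: str | None = None


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration: float  # mg/mL, > 0
    percent_inhibition: float  # may be negative (activation); capped at 100 by construction

    def __post_init__(self) -> None:
        if not (math.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"concentration must be > 0, got {self.concentration!r}")
        if not math.isfinite(self.percent_inhibition):
            raise ValueError("percent_inhibition must be finite")


@dataclass(frozen=True)
class ProbitFit:
    """Maximum-likelihood probit fit of inhibition proportion on
    log10(concentration); IC50 = 10^(−intercept/slope)."""

    intercept: float
    slope: float
    ic50: float
    converged: bool
    n_points: int
    standard_errors: tuple[float, float]
    n_iterations: int = 0
    message: str = ""
    extrapolated: bool = False
    covariance: tuple[tuple[float, float], tuple[float, float]] | None = None


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sem: float
    values: tuple[float, ...]
    n_converged: int
    n_excluded: int
    single_replicate: bool = False


def activity_units(reading: AssayReading) -> ActivityResult:
    """Activity units = (E_B1 − E_S)/E_B1 × 800.

    Linear and monotone decreasing in E_S: 800 units at E_S = 0, 0 at
    E_S = E_B1. E_S > E_B1 is allowed (negative units) but flagged.
    """
    eb1 = reading.absorbance_blank_EB1
    es = reading.absorbance_sample_ES
    units = (eb1 - es) / eb1 * ACTIVITY_SCALE
    warning = None
    if es > eb1:
        warning = (
            f"sample absorbance {es:g} exceeds blank {eb1:g}; "
            "activity is negative"
        )
    return ActivityResult(
        replicate_id=reading.replicate_id,
        concentration=reading.concentration,
        activity_units=units,
        warning=warning,
    )


def percent_inhibition(
    activity_with_inhibitor: float,
    activity_without: float,
    printed_sign: bool = False,
) -> float:
    """% inhibition = (B − A)/B × 100 for activity A with inhibitor and B
    without.

    ``printed_sign`` flips to the (A − B)/B × 100 compatibility form, which
    returns negative values for inhibitors. Negative results (activation)
    pass through either way.
    """
    if not (math.isfinite(activity_without) and activity_without > 0):
        raise ValueError(
            f"activity_without must be positive, got {activity_without!r}"
        )
    if not math.isfinite(activity_with_inhibitor):
        raise ValueError("activity_with_inhibitor must be finite")
    diff = activity_with_inhibitor - activity_without
    if not printed_sign:
        diff = -diff
    return diff / activity_without * 100.0


def _failed_fit(n: int, message: str) -> ProbitFit:
    return ProbitFit(
        intercept=math.nan,
        slope=math.nan,
        ic50=math.nan,
        converged=False,
        n_points=n,
        standard_errors=(math.nan, math.nan),
        message=message,
    )


def fit_probit(points: Sequence[DoseResponsePoint]) -> ProbitFit:
    """Fit a probit dose-response curve by iteratively reweighted least
    squares (Fisher scoring), initialized from OLS on probit-transformed
    proportions.

    Deterministic; degenerate inputs (identical proportions, singular
    design) yield ``converged=False`` with a diagnostic instead of raising.
    """
    points = list(points)
    n = len(points)
    if n < 2:
        raise ValueError(f"fit_probit requires at least 2 points, got {n}")
    conc = np.array([p.concentration for p in points], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("fit_probit requires at least 2 distinct concentrations")
    x = np.log10(conc)
    y = np.clip(np.array([p.percent_inhibition for p in points]) / 100.0,
                PROPORTION_EPS, 1.0 - PROPORTION_EPS)

    if np.allclose(y, y[0], rtol=0.0, atol=1e-12):
        return _failed_fit(n, "all proportions identical; no dose-response to fit")

    X = np.column_stack([np.ones(n), x])
    # OLS on the probit scale as a starting value
    beta, *_ = np.linalg.lstsq(X, stats.norm.ppf(y), rcond=None)

    def deviance(mu: np.ndarray) -> float:
        return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))

    dev_old = math.inf
    cov = None
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        eta = np.clip(X @ beta, -8.0, 8.0)
        mu = np.clip(stats.norm.cdf(eta), PROPORTION_EPS, 1.0 - PROPORTION_EPS)
        dmu = stats.norm.pdf(eta)
        w = dmu * dmu / (mu * (1.0 - mu))
        z = eta + (y - mu) / dmu
        xtw = X.T * w
        try:
            fisher = xtw @ X
            beta = np.linalg.solve(fisher, xtw @ z)
            cov = np.linalg.inv(fisher)
        except np.linalg.LinAlgError:
            return _failed_fit(n, "singular weighted design matrix")
        dev = deviance(np.clip(stats.norm.cdf(np.clip(X @ beta, -8.0, 8.0)),
                               PROPORTION_EPS, 1.0 - PROPORTION_EPS))
        if abs(dev_old - dev) < _DEVIANCE_TOL * (abs(dev) + 1.0):
            dev_old = dev
            break
        dev_old = dev
    else:
        return _failed_fit(n, f"IRLS did not converge in {_MAX_ITER} iterations")

    intercept, slope = float(beta[0]), float(beta[1])
    se = (float(math.sqrt(max(cov[0, 0], 0.0))), float(math.sqrt(max(cov[1, 1], 0.0))))
    if slope > 0:
        ic50 = 10.0 ** (-intercept / slope)
        message = ""
    else:
        ic50 = math.nan
        message = f"non-positive slope {slope:g}; IC50 undefined"
    extrapolated = bool(
        math.isfinite(ic50) and not (conc.min() <= ic50 <= conc.max())
    )
    return ProbitFit(
        intercept=intercept,
        slope=slope,
        ic50=ic50,
        converged=True,
        n_points=n,
        standard_errors=se,
        n_iterations=n_iter,
        message=message,
        extrapolated=extrapolated,
        covariance=((float(cov[0, 0]), float(cov[0, 1])),
                    (float(cov[1, 0]), float(cov[1, 1]))),
    )


def ic50_replicate_summary(fits: Iterable[ProbitFit]) -> ReplicateSummary:
    """Mean and SEM (SD/√n, n−1 denominator) of converged replicate IC50s.

    Non-converged fits and fits without a finite IC50 are excluded and
    counted; zero usable fits is an error. A single usable fit reports
    SEM = 0 with ``single_replicate`` set.
    """
    fits = list(fits)
    usable = [f.ic50 for f in fits if f.converged and math.isfinite(f.ic50)]
    n_excluded = len(fits) - len(usable)
    if not usable:
        raise ValueError("ic50_replicate_summary requires at least one converged fit")
    values = np.asarray(usable, dtype=float)
    mean = float(values.mean())
    if values.size == 1:
        return ReplicateSummary(mean=mean, sem=0.0, values=tuple(usable),
                                n_converged=1, n_excluded=n_excluded,
                                single_replicate=True)
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    return ReplicateSummary(mean=mean, sem=sem, values=tuple(usable),
                            n_converged=values.size, n_excluded=n_excluded)


def plate_to_dose_response(
    readings: Iterable[AssayReading],
    printed_sign: bool = False,
) -> dict[str, list[DoseResponsePoint]]:
    """Reduce a plate of readings to per-replicate dose-response points.

    Within each replicate, readings at concentration 0 define the
    no-inhibitor control activity B (averaged if several); every positive
    concentration becomes a :class:`DoseResponsePoint` against that control.
    """
    by_rep: dict[str, list[AssayReading]] = {}
    for r in readings:
        by_rep.setdefault(r.replicate_id, []).append(r)
    out: dict[str, list[DoseResponsePoint]] = {}
    for rep_id, rows in by_rep.items():
        controls = [activity_units(r).activity_units for r in rows if r.concentration == 0]
        if not controls:
            raise ValueError(f"replicate {rep_id!r} has no concentration-0 control readings")
        control_activity = float(np.mean(controls))
        points = []
        for r in sorted(rows, key=lambda r: r.concentration):
            if r.concentration == 0:
                continue
            act = activity_units(r).activity_units
            points.append(DoseResponsePoint(
                concentration=r.concentration,
                percent_inhibition=percent_inhibition(act, control_activity,
                                                      printed_sign=printed_sign),
            ))
        if not points:
            raise ValueError(f"replicate {rep_id!r} has no inhibitor readings")
        out[rep_id] = points
    return out
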