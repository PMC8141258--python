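"""Percent-inhibition normalization against vehicle controls and the
sigmoidal (Hill) exposure-response layer.

percent inhibition = 100 - (Y/K1)*100, with K1 the positive-minus-negative
control mean difference and Y the treated-minus-negative difference.
Values above 100% or below 0% are representable and never clipped in the
raw results; display flooring at 0% exists only in the profile report.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import NEGATIVE_CONTROL, POSITIVE_CONTROL, PDTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class InhibitionResult:
    endpoint: str
    group: str
    percent_inhibition: float
    K1: float  # positive-control mean minus negative-control mean
    Y: float  # treated mean minus negative-control mean


@dataclass
class HillFit:
    """Fitted sigmoid I(c) = I_max * c^h / (EC50^h + c^h)."""

    i_max: float
    ec50: float
    h: float
    fixed_imax: bool
    rss: float
    n_points: int


@dataclass
class EfficacyProfile:
    """Endpoints x treatment groups percent-inhibition matrix.

    ``display`` floors negatives at 0% (table convention); ``raw`` keeps the
    exact values. Per-cell failures are NaN with the message collected.
    """

    raw: pd.DataFrame
    display: pd.DataFrame
    errors: list[str]


def percent_inhibition(table: PDTable, endpoint: str, group: str) -> InhibitionResult:
    """Percent inhibition of one treated group for one endpoint."""
    neg = table.group_mean(endpoint, NEGATIVE_CONTROL)
    pos = table.group_mean(endpoint, POSITIVE_CONTROL)
    treated = table.group_mean(endpoint, group)
    k1 = pos - neg
    if k1 == 0:
        raise ValidationError(
            f"endpoint {endpoint!r}: positive and negative control means are equal (K1 = 0)"
        )
    y = treated - neg
    return InhibitionResult(
        endpoint=endpoint,
        group=group,
        percent_inhibition=100.0 - (y / k1) * 100.0,
        K1=k1,
        Y=y,
    )


def _hill(c: np.ndarray, i_max: float, ec50: float, h: float) -> np.ndarray:
    ch = np.power(c, h)
    return i_max * ch / (np.power(ec50, h) + ch)


def fit_hill(
    points: Sequence[tuple[float, float]],
    fix_imax: bool = True,
    i_max: float = 100.0,
) -> HillFit:
    """Least-squares Hill fit of inhibition (%) against exposure.

    Deterministic start: EC50 at the geometric mean of the exposures, slope 1.
    EC50 and slope are optimized on the log scale so both stay positive.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("points must be (exposure, inhibition) pairs")
    c, y = arr[:, 0], arr[:, 1]
    if (c <= 0).any():
        raise ValidationError("exposures must be > 0")
    n_distinct = len(np.unique(c))
    needed = 3 if fix_imax else 4
    if n_distinct < needed:
        raise ValidationError(f"need >= {needed} distinct exposures, got {n_distinct}")
    if np.ptp(y) == 0:
        raise ValidationError("all inhibition values equal; nothing to fit")
    log_ec50_0 = float(np.mean(np.log(c)))

    if fix_imax:
        def model(cc, log_ec50, log_h):
            return _hill(cc, i_max, np.exp(log_ec50), np.exp(log_h))

        p0 = [log_ec50_0, 0.0]
    else:
        def model(cc, log_ec50, log_h, im):
            return _hill(cc, im, np.exp(log_ec50), np.exp(log_h))

        p0 = [log_ec50_0, 0.0, float(max(y.max(), 1.0))]

    try:
        popt, _ = optimize.curve_fit(model, c, y, p0=p0, maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise ValidationError(f"Hill fit did not converge: {exc}") from exc
    ec50 = float(np.exp(popt[0]))
    h = float(np.exp(popt[1]))
    imax_hat = i_max if fix_imax else float(popt[2])
    rss = float(np.sum((model(c, *popt) - y) ** 2))
    return HillFit(i_max=imax_hat, ec50=ec50, h=h, fixed_imax=fix_imax, rss=rss, n_points=len(c))


def inhibition_at(fit: HillFit, exposure: float) -> float:
    """Predicted percent inhibition at an exposure (> 0)."""
    if exposure <= 0:
        raise ValidationError(f"exposure must be > 0, got {exposure}")
    return float(_hill(np.asarray(exposure, float), fit.i_max, fit.ec50, fit.h))


def exposure_at(fit: HillFit, inhibition: float) -> float:
    """Exposure producing a given inhibition; inverse of :func:`inhibition_at`."""
    if not (0 < inhibition < fit.i_max):
        raise ValidationError(
            f"inhibition must be in (0, {fit.i_max}) for the inverse, got {inhibition}"
        )
    return float(fit.ec50 * (inhibition / (fit.i_max - inhibition)) ** (1.0 / fit.h))


def efficacy_profile(
    table: PDTable,
    endpoints: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> EfficacyProfile:
    """Percent-inhibition matrix over endpoints and treated groups.

    Per-cell control problems are reported and leave a NaN cell; the rest of
    the matrix is still produced.
    """
    endpoints = list(endpoints) if endpoints is not None else table.endpoints
    if groups is None:
        groups = [g for g in table.groups if g not in (NEGATIVE_CONTROL, POSITIVE_CONTROL)]
    raw = pd.DataFrame(np.nan, index=list(endpoints), columns=list(groups))
    errors: list[str] = []
    for endpoint in endpoints:
        for group in groups:
            try:
                raw.loc[endpoint, group] = percent_inhibition(table, endpoint, group).percent_inhibition
            except ValidationError as exc:
                errors.append(f"{endpoint}/{group}: {exc}")
    display = raw.clip(lower=0.0)
    if errors:
        log.warning("efficacy profile: %d cells failed: %s", len(errors), errors)
    return EfficacyProfile(raw=raw, display=display, errors=errors)


def trough_exposures(table: PDTable, group: str) -> float:
    """Mean trough exposure of a treated group (NaN rows ignored)."""
    sub = table.data[table.data["group"] == group]
    if sub.empty:
        raise ValidationError(f"no rows for group {group!r}")
    vals = sub["trough_exposure"].dropna()
    if vals.empty:
        raise ValidationError(f"group {group!r} has no trough exposures")
    return float(vals.mean())


def exposure_response_points(table: PDTable, endpoint: str) -> list[tuple[float, float]]:
    """(trough exposure, percent inhibition) per treated group for one endpoint."""
    points = []
    for group in table.groups:
        if group in (NEGATIVE_CONTROL, POSITIVE_CONTROL):
            continue
        res = percent_inhibition(table, endpoint, group)
        points.append((trough_exposures(table, group), res.percent_inhibition))
    return points
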