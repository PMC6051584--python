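"""Diel and seasonal vocal-activity analysis.

Male koala bellowing is tied to the solar day rather than the clock: activity
rises a few hours before sunset and peaks roughly four hours after it.  This
module converts clock timestamps to sunset-relative hour bins, standardises
per-site bellow counts to proportions (sites differ by two orders of
magnitude in bellow rate), and smooths the resulting diel and weekly profiles
with a penalized B-spline (P-spline) regression.

Sunset is computed from standard NOAA solar geometry at minute resolution; a
user-supplied sunset table can override the computation.  All times are local
clock times; daylight-saving shifts are ignored (the local standard clock is
assumed continuous).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "sunset_time",
    "hours_from_sunset",
    "diel_profile",
    "weekly_profile",
    "week_index",
    "SmoothFit",
    "fit_smooth",
]

# ---------------------------------------------------------------------------
# solar geometry

_ZENITH_OFFICIAL = 90.833  # degrees; accounts for refraction + solar radius


def _solar_parameters(day_of_year: int) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def sunset_time(
    latitude: float,
    longitude: float,
    date: dt.date,
    utc_offset_hours: float | None = None,
) -> dt.datetime:
    """Local clock time of sunset, minute resolution.

    Parameters
    ----------
    latitude, longitude
        Decimal degrees; longitude positive east.  ``|latitude|`` must stay
        below the polar circles (no midnight-sun handling).
    utc_offset_hours
        Offset of the local clock from UTC.  Defaults to the nominal
        time-zone offset ``round(longitude / 15)``; daylight saving is never
        applied.
    """
    if abs(latitude) > 66.0:
        raise ValueError(f"latitude {latitude} is inside a polar circle; sunset undefined")
    if utc_offset_hours is None:
        utc_offset_hours = round(longitude / 15.0)
    eqtime, decl = _solar_parameters(date.timetuple().tm_yday)
    lat_r = math.radians(latitude)
    cos_ha = math.cos(math.radians(_ZENITH_OFFICIAL)) / (
        math.cos(lat_r) * math.cos(decl)
    ) - math.tan(lat_r) * math.tan(decl)
    if not -1.0 <= cos_ha <= 1.0:  # no sunset on this date at this latitude
        raise ValueError(f"no sunset at latitude {latitude} on {date}")
    ha_deg = math.degrees(math.acos(cos_ha))
    minutes_utc = 720.0 - 4.0 * (longitude - ha_deg) - eqtime
    minutes_local = minutes_utc + utc_offset_hours * 60.0
    base = dt.datetime.combine(date, dt.time(0, 0))
    return base + dt.timedelta(minutes=round(minutes_local) % 1440)


def hours_from_sunset(timestamp: dt.datetime, sunset: dt.datetime) -> int:
    """Sunset-relative hour bin in [-12, +11].

    The hour starting at sunset is bin 0; bins are ``floor`` of the signed
    hour difference, wrapped so that every instant of the 24-h day falls in
    exactly one of the 24 bins.
    """
    delta_h = (timestamp - sunset).total_seconds() / 3600.0
    b = math.floor(delta_h)
    return (b + 12) % 24 - 12


SunsetLookup = Callable[[str, dt.date], dt.datetime]


def _resolve_sunsets(
    sunsets: SunsetLookup | Mapping[tuple[str, dt.date], dt.datetime],
) -> SunsetLookup:
    if callable(sunsets):
        return sunsets
    return lambda site, date: sunsets[(site, date)]


def diel_profile(
    sample_counts: pd.DataFrame,
    sunsets: SunsetLookup | Mapping[tuple[str, dt.date], dt.datetime],
) -> pd.DataFrame:
    """Per-site proportion of bellows in each sunset-relative hour bin.

    ``sample_counts`` holds the five-minute systematic samples (one row per
    recording window) with columns ``site_id``, ``start`` (datetime) and
    ``n_bellows``.  Counts are pooled by ``hours_from_sunset`` bin and
    standardised to the proportion of the site's 24-h total, so sites with
    very different bellow rates are comparable.  Sites with zero bellows are
    excluded (their proportions are undefined).

    Returns a frame with columns ``site_id, bin, proportion`` covering all 24
    bins per retained site.
    """
    lookup = _resolve_sunsets(sunsets)
    df = sample_counts.copy()
    starts = pd.to_datetime(df["start"])
    df["bin"] = [
        hours_from_sunset(t.to_pydatetime(), lookup(s, t.date()))
        for s, t in zip(df["site_id"], starts)
    ]
    out = []
    for site, grp in df.groupby("site_id", sort=True):
        total = grp["n_bellows"].sum()
        if total == 0:
            continue
        by_bin = grp.groupby("bin")["n_bellows"].sum()
        for b in range(-12, 12):
            out.append((site, b, float(by_bin.get(b, 0)) / float(total)))
    return pd.DataFrame(out, columns=["site_id", "bin", "proportion"])


def week_index(date: dt.date, origin: dt.date) -> int:
    """ISO-style week index: whole Monday-aligned weeks since the origin's week."""
    monday = origin - dt.timedelta(days=origin.weekday())
    return (date - monday).days // 7


def weekly_profile(
    night_counts: pd.DataFrame,
    min_total_bellows: int = 225,
    week_origin: dt.date | None = None,
    night_hours: float = 6.0,
) -> pd.DataFrame:
    """Per-site weekly proportion of mean bellows per night hour.

    ``night_counts`` has one row per site-night with columns ``site_id``,
    ``night`` (date) and ``n_bellows`` — the count in the full six-hour night
    block.  For each site and week the mean bellows per night hour is
    computed and standardised to per-site proportions over weeks.  Sites with
    fewer than ``min_total_bellows`` over the whole study (default 225) are
    dropped: their profiles are dominated by sampling noise.
    """
    df = night_counts.copy()
    df["night"] = pd.to_datetime(df["night"]).dt.date
    if week_origin is None:
        week_origin = min(df["night"])
    df["week"] = [week_index(d, week_origin) for d in df["night"]]
    out = []
    for site, grp in df.groupby("site_id", sort=True):
        if grp["n_bellows"].sum() < min_total_bellows:
            continue
        weekly = grp.groupby("week")["n_bellows"].mean() / night_hours
        total = weekly.sum()
        if total == 0:
            continue
        for w, v in weekly.items():
            out.append((site, int(w), float(v) / float(total)))
    return pd.DataFrame(out, columns=["site_id", "week", "proportion"])


# ---------------------------------------------------------------------------
# penalized-spline smoothing

_DEGREE = 3


@dataclasses.dataclass(frozen=True)
class SmoothFit:
    """A penalized B-spline fit to a 1-d activity profile."""

    knots: np.ndarray
    degree: int
    coefficients: np.ndarray
    lam: float
    fitted: np.ndarray
    r_squared: float
    edf: float

    def predict(self, x: Sequence[float]) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.knots[self.degree],
                    self.knots[-self.degree - 1])
        return BSpline(self.knots, self.coefficients, self.degree)(x)


def _bspline_basis(x: np.ndarray, basis_size: int) -> tuple[np.ndarray, np.ndarray]:
    # Uniform (unclamped) knots: with equal spacing the Greville abscissae
    # are equidistant, so the difference-penalty null space is exactly the
    # polynomials of degree < penalty_order (a straight line for order 2).
    lo, hi = float(x.min()), float(x.max())
    span = (hi - lo) or 1.0
    lo -= 1e-9 * span
    hi += 1e-9 * span
    h = (hi - lo) / (basis_size - _DEGREE)
    knots = lo + h * (np.arange(basis_size + _DEGREE + 1) - _DEGREE)
    B = BSpline.design_matrix(x, knots, _DEGREE).toarray()
    return B, knots


def fit_smooth(
    x: Sequence[float],
    y: Sequence[float],
    variance_weights: Sequence[float] | None = None,
    basis_size: int = 10,
    penalty_order: int = 2,
    lam: float | None = None,
) -> SmoothFit:
    """Penalized least-squares smooth of ``y`` on ``x`` (P-spline).

    A cubic B-spline basis of ``basis_size`` functions on equally spaced
    knots is fit by weighted least squares with a difference penalty of order
    ``penalty_order`` on adjacent coefficients.  When ``lam`` is ``None`` the
    smoothing parameter is chosen by generalized cross-validation over a log
    grid.  As ``lam`` grows, the fit shrinks to the penalty's polynomial null
    space (a straight line for order 2).

    ``variance_weights`` are inverse-variance observation weights (all
    positive); ``r_squared`` is the weighted 1 − RSS/TSS, defined as 0 when
    the response is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    w = (
        np.ones_like(y)
        if variance_weights is None
        else np.asarray(variance_weights, dtype=float)
    )
    if np.any(w <= 0):
        raise ValueError("variance_weights must be strictly positive")
    n_distinct = np.unique(x).size
    if lam is not None and lam == 0 and n_distinct < basis_size:
        raise ValueError(
            f"unpenalized fit needs >= {basis_size} distinct x values, got {n_distinct}"
        )

    B, knots = _bspline_basis(x, basis_size)
    D = np.diff(np.eye(basis_size), n=penalty_order, axis=0)
    P = D.T @ D
    BtW = B.T * w
    BtWB = BtW @ B
    BtWy = BtW @ y

    sqw = np.sqrt(w)

    def solve(l: float) -> tuple[np.ndarray, np.ndarray, float]:
        # augmented least squares (QR) is stable even for extreme penalties
        aug_A = np.vstack([B * sqw[:, None], math.sqrt(l) * D])
        aug_b = np.concatenate([y * sqw, np.zeros(D.shape[0])])
        coef = np.linalg.lstsq(aug_A, aug_b, rcond=None)[0]
        fitted = B @ coef
        # effective degrees of freedom: trace of the hat matrix
        H_diag = np.einsum(
            "ij,jk,ik->i", B, np.linalg.pinv(BtWB + l * P), BtW.T
        )
        return coef, fitted, float(H_diag.sum())

    if lam is None:
        grid = np.logspace(-6, 8, 43)
        best, best_gcv = grid[0], np.inf
        n = len(y)
        for l in grid:
            _, fitted, edf = solve(l)
            rss = float(np.sum(w * (y - fitted) ** 2))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if gcv < best_gcv:
                best, best_gcv = l, gcv
        lam = float(best)

    coef, fitted, edf = solve(lam)
    if not np.all(np.isfinite(fitted)):
        raise FloatingPointError("smooth fit produced non-finite values")
    wmean = float(np.sum(w * y) / np.sum(w))
    tss = float(np.sum(w * (y - wmean) ** 2))
    rss = float(np.sum(w * (y - fitted) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return SmoothFit(
        knots=knots,
        degree=_DEGREE,
        coefficients=coef,
        lam=float(lam),
        fitted=fitted,
        r_squared=r2,
        edf=edf,
    )
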