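"""Single-season occupancy modelling and survey-effort power analysis.

The constant-parameter single-season occupancy model treats each site i as
occupied with probability psi; given occupancy, each valid survey night is an
independent detection with probability p.  With K_i valid nights and d_i
detected nights the likelihood is

    L(psi, p) = prod_i  psi * p^d_i * (1-p)^(K_i - d_i)          if d_i > 0
                        psi * (1-p)^K_i + (1 - psi)              if d_i = 0

(the zero-inflated binomial).  Fitting is by maximum likelihood on the logit
scale with Wald standard errors from the observed information; boundary fits
(all sites detected forces psi-hat = 1) are returned in closed form with a
profile-likelihood standard error, since the Wald SE diverges there.

Survey design rests on the cumulative detection probability over n nights,
P = 1 - (1-p)^n: ``nights_required`` inverts it for the smallest n giving a
stated confidence in a site-specific absence, and ``design_table`` assembles
the season x density x schedule design table.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .scheduling import DetectionHistory

__all__ = [
    "OccupancyFit",
    "Stratum",
    "DesignRow",
    "fit_occupancy",
    "cumulative_detection",
    "nights_required",
    "design_table",
    "one_way_anova",
    "pearson_correlation",
    "simulate_detection_history",
    "season_stage_of_month",
    "density_class",
    "SEASON_MONTHS",
]

# breeding-season thirds (southern koala): early Aug/Sep, mid Oct/Nov, late Dec/Jan
SEASON_MONTHS = {"early": (8, 9), "mid": (10, 11), "late": (12, 1)}

_LOGIT_BOUNDARY = 10.0  # |logit| beyond this is treated as a boundary estimate


def season_stage_of_month(month: int) -> str:
    for stage, months in SEASON_MONTHS.items():
        if month in months:
            return stage
    raise ValueError(f"month {month} is outside the breeding season")


def density_class(density: float, threshold: float = 1.0) -> str:
    """Low (< threshold koalas/ha) vs high (>= threshold) density class."""
    return "high" if density >= threshold else "low"


@dataclasses.dataclass(frozen=True)
class Stratum:
    season_stage: str  # early | mid | late
    density_class: str  # low | high


@dataclasses.dataclass(frozen=True)
class OccupancyFit:
    """MLE of (psi, p) for one stratum, with uncertainty and diagnostics."""

    psi_hat: float
    p_hat: float
    se_psi: float
    se_p: float
    loglik: float
    n_sites: int
    n_nights_total: int
    boundary: bool = False
    degenerate: bool = False
    message: str = ""


@dataclasses.dataclass(frozen=True)
class DesignRow:
    season_stage: str
    density_class: str
    schedule: str
    p_hat: float
    se_p: float
    nights_80: float
    nights_95: float
    note: str = ""


def _suff_stats(history: DetectionHistory) -> tuple[np.ndarray, np.ndarray]:
    K = history.valid.sum(axis=1).astype(float)
    d = np.where(history.valid, history.detected, 0).sum(axis=1).astype(float)
    keep = K > 0
    return K[keep], d[keep]


def _loglik(psi: float, p: float, K: np.ndarray, d: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        det = d > 0
        ll = 0.0
        if det.any():
            ll += det.sum() * math.log(psi) if psi > 0 else -np.inf
            ll += float(np.sum(d[det] * np.log(p) + (K[det] - d[det]) * np.log1p(-p))) \
                if 0 < p < 1 else (-np.inf if (d[det] > 0).any() and p == 0 else
                                   (0.0 if p == 1 and np.all(d[det] == K[det]) else -np.inf))
        nod = ~det
        if nod.any():
            zero_terms = psi * np.power(1.0 - p, K[nod]) + (1.0 - psi)
            ll += float(np.sum(np.log(np.maximum(zero_terms, 1e-300))))
    return ll


def _profile_se_p(p_hat: float, K: np.ndarray, d: np.ndarray, psi: float) -> float:
    """SE from the profile-likelihood half-width at a drop of 1.92 (chi2_1/2)."""
    target = _loglik(psi, p_hat, K, d) - 1.92

    def f(p):
        return _loglik(psi, p, K, d) - target

    lo = 1e-9
    if f(lo) > 0:  # likelihood too flat to bracket
        return float("nan")
    p_lo = optimize.brentq(f, lo, max(p_hat - 1e-12, lo * 2))
    return float((p_hat - p_lo) / 1.96)


def _profile_se_psi(psi_hat: float, p: float, K: np.ndarray, d: np.ndarray) -> float:
    target = _loglik(psi_hat, p, K, d) - 1.92

    def f(psi):
        return _loglik(psi, p, K, d) - target

    lo = 1e-9
    if f(lo) > 0:
        return float("nan")
    psi_lo = optimize.brentq(f, lo, max(psi_hat - 1e-12, lo * 2))
    return float((psi_hat - psi_lo) / 1.96)


def fit_occupancy(history: DetectionHistory) -> OccupancyFit:
    """Maximum-likelihood fit of the constant (psi, p) occupancy model.

    All-detected histories are solved in closed form (psi-hat = 1,
    p-hat = sum d_i / sum K_i, exactly the binomial MLE); all-zero histories
    are unidentifiable and returned flagged degenerate.  Interior fits use
    quasi-Newton optimisation on (logit psi, logit p) started at (0.5, 0.5)
    with Wald SEs via the delta method; estimates pushed past |logit| = 10
    are reported as exact 0/1 with profile-likelihood SEs.
    """
    K, d = _suff_stats(history)
    if K.size == 0:
        raise ValueError("history has no site with a valid night")
    n_sites, n_nights = int(K.size), int(K.sum())

    if np.all(d == 0):
        return OccupancyFit(
            psi_hat=float("nan"), p_hat=float("nan"), se_psi=float("nan"),
            se_p=float("nan"), loglik=0.0, n_sites=n_sites,
            n_nights_total=n_nights, degenerate=True,
            message="no detections: psi and p are not identifiable",
        )

    if np.all(d > 0):  # every site detected at least once: psi on the boundary
        p_hat = float(d.sum() / K.sum())
        psi_hat = 1.0
        ll = _loglik(psi_hat, p_hat, K, d)
        if 0 < p_hat < 1:
            se_p = math.sqrt(p_hat * (1 - p_hat) / K.sum())
        else:
            se_p = _profile_se_p(p_hat, K, d, psi_hat) if p_hat < 1 else float("nan")
        return OccupancyFit(
            psi_hat=psi_hat, p_hat=p_hat,
            se_psi=_profile_se_psi(psi_hat, p_hat, K, d), se_p=se_p,
            loglik=ll, n_sites=n_sites, n_nights_total=n_nights,
            boundary=True, message="all sites detected: psi-hat on the boundary at 1",
        )

    def nll(theta: np.ndarray) -> float:
        psi = 1.0 / (1.0 + math.exp(-theta[0]))
        p = 1.0 / (1.0 + math.exp(-theta[1]))
        return -_loglik(psi, p, K, d)

    res = optimize.minimize(nll, x0=np.zeros(2), method="BFGS")
    # polish with Nelder-Mead if BFGS stalled on the flat logit tails
    res2 = optimize.minimize(nll, x0=res.x, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12})
    theta = res2.x if res2.fun <= res.fun else res.x
    psi_hat = 1.0 / (1.0 + math.exp(-theta[0]))
    p_hat = 1.0 / (1.0 + math.exp(-theta[1]))
    ll = -nll(theta)

    boundary = bool(np.any(np.abs(theta) > _LOGIT_BOUNDARY))
    if boundary:
        psi_r = 1.0 if theta[0] > _LOGIT_BOUNDARY else (0.0 if theta[0] < -_LOGIT_BOUNDARY else psi_hat)
        p_r = 1.0 if theta[1] > _LOGIT_BOUNDARY else (0.0 if theta[1] < -_LOGIT_BOUNDARY else p_hat)
        ll = _loglik(psi_r, p_r, K, d)
        return OccupancyFit(
            psi_hat=psi_r, p_hat=p_r,
            se_psi=_profile_se_psi(psi_r, p_r, K, d),
            se_p=_profile_se_p(p_r, K, d, psi_r) if p_r > 0 else float("nan"),
            loglik=ll, n_sites=n_sites, n_nights_total=n_nights,
            boundary=True, message="estimate on the parameter boundary",
        )

    H = _hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
        se_logit = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se_logit = np.array([float("nan"), float("nan")])
    se_psi = float(se_logit[0] * psi_hat * (1 - psi_hat))
    se_p = float(se_logit[1] * p_hat * (1 - p_hat))
    return OccupancyFit(
        psi_hat=float(psi_hat), p_hat=float(p_hat), se_psi=se_psi, se_p=se_p,
        loglik=float(ll), n_sites=n_sites, n_nights_total=n_nights,
    )


def _hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function of a small vector."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h
            ej = np.eye(n)[j] * h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def cumulative_detection(p_list: Sequence[float]) -> float:
    """P = 1 - prod(1 - p_n): chance of at least one detection over the nights."""
    ps = np.asarray(p_list, dtype=float)
    if ps.size and (np.any(ps < 0) or np.any(ps > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - ps)) if ps.size else 0.0


def nights_required(p: float, confidence: float) -> int:
    """Smallest n with 1 - (1-p)^n >= confidence (inclusive threshold).

    This is the survey effort needed to be ``confidence`` sure of a
    site-specific absence when the species goes undetected every night.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]: confidence is unreachable at p = 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if p == 1:
        return 1
    n = max(1, math.ceil(math.log1p(-confidence) / math.log1p(-p)))
    # guard the ceiling against floating-point slop on either side
    while n > 1 and 1.0 - (1.0 - p) ** (n - 1) >= confidence:
        n -= 1
    while 1.0 - (1.0 - p) ** n < confidence:
        n += 1
    return n


def design_table(
    histories: Mapping[tuple[Stratum, str], DetectionHistory],
    confidences: tuple[float, float] = (0.80, 0.95),
) -> list[DesignRow]:
    """One design row per (stratum, schedule): p-hat, SE and nights to confidence.

    Fit failures (degenerate histories) produce a flagged row with NaN
    estimates rather than aborting the remaining rows.
    """
    lo_c, hi_c = sorted(confidences)
    rows: list[DesignRow] = []
    for (stratum, schedule), hist in histories.items():
        try:
            fit = fit_occupancy(hist)
            if fit.degenerate or not (0 < fit.p_hat <= 1):
                raise ValueError(fit.message or "degenerate fit")
            rows.append(
                DesignRow(
                    stratum.season_stage, stratum.density_class, schedule,
                    p_hat=fit.p_hat, se_p=fit.se_p,
                    nights_80=nights_required(fit.p_hat, lo_c),
                    nights_95=nights_required(fit.p_hat, hi_c),
                    note="boundary" if fit.boundary else "",
                )
            )
        except (ValueError, FloatingPointError) as exc:
            rows.append(
                DesignRow(
                    stratum.season_stage, stratum.density_class, schedule,
                    p_hat=float("nan"), se_p=float("nan"),
                    nights_80=float("nan"), nights_95=float("nan"),
                    note=f"fit failed: {exc}",
                )
            )
    return rows


def one_way_anova(
    values: Sequence[float], groups: Sequence
) -> tuple[float, int, int, float]:
    """Classical one-way fixed-effects ANOVA: (F, df_between, df_within, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must align")
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    k, n = len(labels), values.size
    df_b, df_w = k - 1, n - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    if np.ptp(values) == 0:
        return 0.0, df_b, df_w, 1.0
    F = float(stats.f_oneway(*samples).statistic)
    if not np.isfinite(F):  # within-group variance zero
        F = 0.0 if np.ptp([s.mean() for s in samples]) == 0 else float("inf")
    p = float(stats.f.sf(F, df_b, df_w))
    return F, df_b, df_w, p


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def simulate_detection_history(
    psi: float, p: float, n_sites: int, n_nights: int, seed: int
) -> DetectionHistory:
    """Draw a balanced site x night history from the occupancy model itself.

    Used for parameter-recovery and coverage studies: sites are occupied
    Bernoulli(psi); occupied sites yield Bernoulli(p) detections per night.
    """
    import datetime as dt

    rng = np.random.default_rng(seed)
    occupied = rng.random(n_sites) < psi
    detected = (rng.random((n_sites, n_nights)) < p) & occupied[:, None]
    nights = tuple(dt.date(2016, 8, 1) + dt.timedelta(days=i) for i in range(n_nights))
    return DetectionHistory(
        site_ids=tuple(f"s{i:03d}" for i in range(n_sites)),
        nights=nights,
        detected=detected.astype(int),
        valid=np.ones((n_sites, n_nights), dtype=bool),
    )
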