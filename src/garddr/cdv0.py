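"""cDV0 estimation: the lowest concentration with a non-negative decision value.

Two estimators are provided, mirroring how the dose-response adaptation of
the assay is analysed:

* **model-based** — solve the fitted constrained log-logistic curve for the
  concentration where it crosses the decision threshold (default DV = 0),
  with an approximate 95% confidence interval obtained by inverse
  regression (delta-method propagation of the fit covariance on the
  log-concentration scale);
* **linear interpolation** — interpolate between the two assayed points on
  adjacent sides of the decision border,

      cDV0 = c_minus - DV_minus * (c_plus - c_minus) / (DV_plus - DV_minus),

  optionally after a centred running-median smoothing of the DV sequence to
  reduce the impact of noise on which point counts as "positive".

Both return a :class:`Cdv0Estimate`, which may be censored: ``NS`` when no
concentration (assayed or modelled) reaches the threshold, or ``<cmin``
when already the lowest assayed concentration is positive, so the true
crossing lies below the assayed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DoseResponseDataset
from .model import LogLogisticResults, fit_log_logistic

__all__ = [
    "Cdv0Estimate",
    "InterpolationBracket",
    "cdv0_from_model",
    "cdv0_confidence_interval",
    "running_median",
    "needs_smoothing",
    "cdv0_linear_interpolation",
    "compare_estimators",
    "CENSOR_NS",
    "CENSOR_BELOW_MIN",
]

CENSOR_NS = "NS"
CENSOR_BELOW_MIN = "<cmin"


@dataclass(frozen=True)
class Cdv0Estimate:
    """A possibly-censored threshold-crossing concentration (µM).

    ``value`` is None when censored; ``censored`` then holds ``"NS"`` (no
    crossing) or ``"<cmin"`` (crossing below the assayed range).  A censored
    estimate may still carry a finite lower confidence bound with an
    undefined upper bound.
    """

    value: float | None
    method: str  # "log_logistic" | "linear_interpolation"
    ci_low: float | None = None
    ci_high: float | None = None
    threshold: float = 0.0
    censored: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.value is not None:
            if not (self.value > 0 and math.isfinite(self.value)):
                raise ValueError(f"cDV0 must be positive and finite, got {self.value}")
            if self.censored is not None:
                raise ValueError("a defined estimate cannot also be censored")
        for bound in (self.ci_low, self.ci_high):
            if bound is not None and not bound > 0:
                raise ValueError("confidence bounds must be positive when defined")
        if (
            self.value is not None
            and self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low <= self.value <= self.ci_high)
        ):
            raise ValueError("confidence interval must bracket the estimate")

    @property
    def is_censored(self) -> bool:
        return self.value is None

    def display(self) -> str:
        """Table-style rendering, e.g. ``'257 (107, NA)'`` or ``'NS'``."""
        val = self.censored if self.is_censored else f"{self.value:.3g}"
        if self.ci_low is None and self.ci_high is None:
            return val
        lo = "NA" if self.ci_low is None else f"{self.ci_low:.3g}"
        hi = "NA" if self.ci_high is None else f"{self.ci_high:.3g}"
        return f"{val} ({lo}, {hi})"


@dataclass(frozen=True)
class InterpolationBracket:
    """Adjacent assayed points straddling the decision border."""

    c_minus: float
    dv_minus: float
    c_plus: float
    dv_plus: float

    def __post_init__(self) -> None:
        if not self.c_minus < self.c_plus:
            raise ValueError("bracket concentrations must be increasing")
        if not (self.dv_minus < 0 <= self.dv_plus):
            raise ValueError("bracket must straddle the threshold (dv_minus < 0 <= dv_plus)")

    def interpolate(self) -> float:
        """Exact linear crossing of DV = 0 within the bracket."""
        return self.c_minus - self.dv_minus * (self.c_plus - self.c_minus) / (
            self.dv_plus - self.dv_minus
        )


# ---------------------------------------------------------------------------
# model-based estimator


def cdv0_from_model(
    fit: LogLogisticResults,
    threshold: float = 0.0,
    ci_level: float | None = 0.95,
) -> Cdv0Estimate:
    """Threshold crossing of the fitted curve, in closed form.

    Solving f(x) = t for the 4PL with b < 0 gives

        x = e * ((d - c) / (t - c) - 1) ** (1 / b).

    Returns a censored ``NS`` estimate when the curve never reaches the
    threshold (d <= t) or when the fixed lower asymptote already exceeds it
    (c >= t, degenerate), and when the fit did not converge.
    """
    b, c, d, e = fit.b, fit.c, fit.d, fit.e
    if not fit.converged:
        return Cdv0Estimate(
            value=None,
            method="log_logistic",
            threshold=threshold,
            censored=CENSOR_NS,
            notes="fit not converged",
        )
    if c >= threshold:
        return Cdv0Estimate(
            value=None,
            method="log_logistic",
            threshold=threshold,
            censored=CENSOR_NS,
            notes="lower asymptote at or above threshold (degenerate)",
        )
    if d <= threshold:
        return Cdv0Estimate(
            value=None,
            method="log_logistic",
            threshold=threshold,
            censored=CENSOR_NS,
            notes="upper asymptote below threshold; curve never crosses",
        )
    ratio = (d - c) / (threshold - c) - 1.0
    value = float(e * ratio ** (1.0 / b))
    ci_low = ci_high = None
    if ci_level is not None:
        ci_low, ci_high = cdv0_confidence_interval(fit, threshold=threshold, level=ci_level)
        if ci_low is not None and ci_low > value:
            ci_low = value
        if ci_high is not None and ci_high < value:
            ci_high = value
    return Cdv0Estimate(
        value=value,
        method="log_logistic",
        ci_low=ci_low,
        ci_high=ci_high,
        threshold=threshold,
    )


def _log_cdv0_gradient(fit: LogLogisticResults, threshold: float):
    """Gradient of log cDV0 with respect to (b, d, log e)."""
    b, c, d = fit.b, fit.c, fit.d
    r = (d - c) / (threshold - c) - 1.0
    g = np.empty(3)
    g[0] = -math.log(r) / b**2  # d/d b of (1/b) log r
    g[1] = 1.0 / (b * r * (threshold - c))  # d/d d
    g[2] = 1.0  # d/d log e
    return g


def cdv0_confidence_interval(
    fit: LogLogisticResults,
    threshold: float = 0.0,
    level: float = 0.95,
) -> tuple[float | None, float | None]:
    """Inverse-regression (delta-method) confidence interval for cDV0.

    The variance of log cDV0 is propagated from the Gauss-Newton
    covariance of (b, d, log e) at the optimum and the interval
    exponentiated, so the bounds are positive and asymmetric on the
    concentration scale.  A bound is None (NA) when the propagated
    variance is non-finite, the covariance is unavailable, or the endpoint
    overflows (diverges).
    """
    if not fit.converged or fit.cov_bdu is None:
        return None, None
    b, c, d, e = fit.b, fit.c, fit.d, fit.e
    if not (c < threshold < d):
        return None, None
    r = (d - c) / (threshold - c) - 1.0
    log_x = math.log(e) + math.log(r) / b
    g = _log_cdv0_gradient(fit, threshold)
    var = float(g @ fit.cov_bdu @ g)
    if not math.isfinite(var) or var < 0:
        return None, None
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    lo = math.exp(log_x - half) if math.isfinite(log_x - half) else None
    hi_exp = log_x + half
    hi = math.exp(hi_exp) if hi_exp < 700 else None  # overflow -> NA (diverged)
    if lo is not None and (not math.isfinite(lo) or lo <= 0):
        lo = None
    return lo, hi


# ---------------------------------------------------------------------------
# interpolation estimator


def running_median(dvs: Sequence[float], window: int = 3) -> np.ndarray:
    """Centred running median with symmetric window shrinking at the edges.

    At position i the window radius is min((window-1)//2, i, n-1-i), so the
    output has the same length as the input and endpoints are left nearly
    untouched.  The window must be odd and >= 3.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    y = np.asarray(dvs, dtype=float)
    n = y.size
    if n < window:
        raise ValueError(f"sequence length {n} is shorter than window {window}")
    k = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        r = min(k, i, n - 1 - i)
        out[i] = np.median(y[i - r : i + r + 1])
    return out


def needs_smoothing(dvs: Sequence[float], threshold: float = 0.0) -> bool:
    """Heuristic noise indicator: the sign of (dv - threshold) flips more than once."""
    signs = np.asarray(dvs, dtype=float) >= threshold
    return int(np.sum(signs[1:] != signs[:-1])) > 1


def cdv0_linear_interpolation(
    data: DoseResponseDataset,
    threshold: float = 0.0,
    smooth: bool = False,
    window: int = 3,
) -> Cdv0Estimate:
    """cDV0 by linear interpolation across the decision border.

    Uses the lowest-concentration pair of adjacent assayed points with
    DV_minus < threshold <= DV_plus; its locality makes the estimate
    robust to departures from the sigmoid shape at higher concentrations.
    Returns ``NS`` when no (smoothed) DV reaches the threshold and the
    censored marker ``"<cmin"`` when the lowest assayed concentration is
    already positive (the true crossing is unobserved).
    """
    ds = data.viable_subset()
    x = ds.concentrations  # sorted ascending by construction
    y = ds.dvs
    if x.size < 2:
        return Cdv0Estimate(
            value=None,
            method="linear_interpolation",
            threshold=threshold,
            censored=CENSOR_NS,
            notes="fewer than 2 viable points",
        )
    notes = []
    if smooth and y.size >= window:
        y = running_median(y, window=window)
        notes.append("running median applied")
    pos = y >= threshold
    if not pos.any():
        return Cdv0Estimate(
            value=None,
            method="linear_interpolation",
            threshold=threshold,
            censored=CENSOR_NS,
            notes="; ".join(notes + ["no DV reaches the threshold"]),
        )
    if pos[0]:
        return Cdv0Estimate(
            value=None,
            method="linear_interpolation",
            threshold=threshold,
            censored=CENSOR_BELOW_MIN,
            notes="; ".join(
                notes + [f"lowest assayed concentration ({x[0]:g} µM) already positive"]
            ),
        )
    # lowest-concentration adjacent bracket straddling the threshold
    idx = None
    for i in range(x.size - 1):
        if y[i] < threshold <= y[i + 1]:
            idx = i
            break
    if idx is None:  # cannot happen given pos[0] is False and pos.any()
        raise AssertionError("bracket search failed on straddling data")
    bracket = InterpolationBracket(
        c_minus=float(x[idx]),
        dv_minus=float(y[idx] - threshold),
        c_plus=float(x[idx + 1]),
        dv_plus=float(y[idx + 1] - threshold),
    )
    return Cdv0Estimate(
        value=bracket.interpolate(),
        method="linear_interpolation",
        threshold=threshold,
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# estimator comparison


def compare_estimators(
    datasets: Iterable[DoseResponseDataset],
    threshold: float = 0.0,
    smooth: str | bool = "auto",
    window: int = 3,
    ratio_flag: float = 2.0,
) -> pd.DataFrame:
    """Run both cDV0 estimators on every dataset and flag discordances.

    ``smooth`` may be True, False or ``"auto"`` (apply the running median
    only when the raw sign pattern around the threshold flips more than
    once).  A chemical is flagged when one method is censored and the other
    is not, or when the estimates differ by more than ``ratio_flag``-fold —
    the situations where the shape assumptions of the two estimators
    disagree and the analyst should inspect the raw curve.
    """
    rows = []
    for ds in datasets:
        try:
            fit = fit_log_logistic(ds)
            est_ll = cdv0_from_model(fit, threshold=threshold)
            p_no_effect = fit.no_effect_test().p_value
        except Exception as exc:
            est_ll = Cdv0Estimate(
                value=None,
                method="log_logistic",
                threshold=threshold,
                censored=CENSOR_NS,
                notes=f"fit failed: {exc}",
            )
            p_no_effect = float("nan")
        do_smooth = (
            needs_smoothing(ds.viable_subset().dvs, threshold)
            if smooth == "auto"
            else bool(smooth)
        )
        est_li = cdv0_linear_interpolation(
            ds, threshold=threshold, smooth=do_smooth, window=window
        )
        flagged = False
        reason = ""
        if est_ll.is_censored != est_li.is_censored:
            flagged = True
            reason = "one method censored, the other defined"
        elif not est_ll.is_censored and not est_li.is_censored:
            ratio = max(est_ll.value, est_li.value) / min(est_ll.value, est_li.value)
            if ratio > ratio_flag:
                flagged = True
                reason = f"estimates differ {ratio:.2g}-fold"
        rows.append(
            {
                "chemical_id": ds.chemical_id,
                "cdv0_ll_uM": est_ll.value,
                "cdv0_ll_censored": est_ll.censored or "",
                "ci_low_uM": est_ll.ci_low,
                "ci_high_uM": est_ll.ci_high,
                "cdv0_interp_uM": est_li.value,
                "cdv0_interp_censored": est_li.censored or "",
                "smoothed": do_smooth,
                "p_no_effect": p_no_effect,
                "flagged": flagged,
                "flag_reason": reason,
            }
        )
    return pd.DataFrame(rows)
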