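"""Constrained log-logistic dose-response model and the no-effect test.

The response model is the four-parameter log-logistic (4PL) curve

    f(x; b, c, d, e) = c + (d - c) / (1 + exp(b * (log x - log e)))

with two constraints reflecting how the assay is analysed: the lower
asymptote ``c`` is *fixed* at the decision value of unstimulated controls
(the response the classifier gives when nothing happens), and the slope
``b`` is restricted to negative values so the fitted curve is
monotonically non-decreasing in concentration.  ``d`` is the upper
asymptote and ``e`` the midpoint concentration (ED50, µM).

Fitting minimises the residual sum of squares over (b, d, e), which under
i.i.d. Gaussian errors on the DV scale equals maximum likelihood.  The
no-effect test compares this fit against the best horizontal line by a
likelihood-ratio test: a significant result indicates a genuine
concentration dependence of the response.

The public surface follows the model/results idiom: build a
:class:`LogLogisticDoseResponse` from a dataset, call :meth:`fit`, and
read estimates, covariance and diagnostics off the returned
:class:`LogLogisticResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import DoseResponseDataset, InsufficientDataError

__all__ = [
    "log_logistic",
    "LogLogisticDoseResponse",
    "LogLogisticResults",
    "NoEffectTestResult",
    "fit_log_logistic",
    "fit_flat",
    "no_effect_test",
]

#: slope upper bound enforcing b < 0 (box constraint)
B_MAX = -1e-6
#: number of free mean parameters of the constrained 4PL (b, d, e)
N_FREE_PARAMS = 3


def log_logistic(x, b: float, c: float, d: float, e: float):
    """Evaluate the 4PL response at concentration ``x`` (µM, scalar or array).

    Tends to ``c`` as x -> 0+ and to ``d`` as x -> inf when ``b < 0``.
    Raises for non-positive concentrations (log-concentration undefined).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be strictly positive")
    if e <= 0:
        raise ValueError("midpoint e must be strictly positive")
    z = np.clip(b * (np.log(x) - math.log(e)), -500.0, 500.0)
    out = c + (d - c) / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def _residuals(theta: np.ndarray, logx: np.ndarray, y: np.ndarray, c: float):
    b, d, u = theta  # u = log(e)
    z = np.clip(b * (logx - u), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(z))
    return c + (d - c) * s - y


def _jacobian(theta: np.ndarray, logx: np.ndarray, y: np.ndarray, c: float):
    b, d, u = theta
    z = np.clip(b * (logx - u), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(z))
    w = s * (1.0 - s)
    J = np.empty((logx.size, 3))
    J[:, 0] = -(d - c) * w * (logx - u)  # d f / d b
    J[:, 1] = s  # d f / d d
    J[:, 2] = (d - c) * w * b  # d f / d log(e)
    return J


# internal smooth reparameterisation used during optimisation:
# b = -(|B_MAX| + exp(beta)) keeps the slope strictly below the b < 0 box
# bound, and u = log(e) keeps the midpoint positive, so the problem is
# unconstrained and the fast Levenberg-Marquardt path applies.  beta and u
# are clipped to generous fixed windows so degenerate (flat) data cannot
# push exp() to overflow.
_BETA_CLIP = 40.0
_U_CLIP = 60.0


def _b_of_beta(beta: float | np.ndarray):
    return -(abs(B_MAX) + np.exp(np.clip(beta, -_BETA_CLIP, _BETA_CLIP)))


def _residuals_free(phi: np.ndarray, logx: np.ndarray, y: np.ndarray, c: float):
    beta, d, u = phi
    u = float(np.clip(u, -_U_CLIP, _U_CLIP))
    return _residuals(np.array([_b_of_beta(beta), d, u]), logx, y, c)


def _jacobian_free(phi: np.ndarray, logx: np.ndarray, y: np.ndarray, c: float):
    beta, d, u = phi
    u = float(np.clip(u, -_U_CLIP, _U_CLIP))
    b = _b_of_beta(beta)
    J = _jacobian(np.array([b, d, u]), logx, y, c)
    J[:, 0] *= -np.exp(np.clip(beta, -_BETA_CLIP, _BETA_CLIP))  # chain rule db/dbeta
    return J


def _gaussian_llf(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood with sigma^2 = rss/n."""
    if rss <= 0:
        return math.inf
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


@dataclass(frozen=True)
class NoEffectTestResult:
    """Likelihood-ratio test of the 4PL fit against the best horizontal line.

    A small ``p_value`` indicates the dose-response model explains the data
    better than a flat line, i.e. a concentration-dependent response.
    """

    lr_statistic: float
    df: int
    p_value: float
    flat_fit_value: float
    flat_rss: float
    converged: bool = True


class LogLogisticDoseResponse:
    """Constrained log-logistic dose-response model for one chemical.

    Non-viable points (failed cytotoxicity screen) are excluded before
    fitting; the exclusion is recorded on the results.
    """

    def __init__(self, dataset: DoseResponseDataset):
        self.dataset = dataset
        self.fit_data = dataset.viable_subset()
        self.control_dv = dataset.control_dv

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        chemical_id: str = "chemical",
        control_dv: float = -1.0,
        concentration_col: str = "concentration_uM",
        dv_col: str = "dv",
    ) -> "LogLogisticDoseResponse":
        """Build the model from a two-column dataframe."""
        ds = DoseResponseDataset.from_arrays(
            chemical_id=chemical_id,
            concentrations=df[concentration_col].to_numpy(dtype=float),
            dvs=df[dv_col].to_numpy(dtype=float),
            control_dv=control_dv,
            viable=df["viable"].to_numpy(dtype=bool) if "viable" in df else None,
        )
        return cls(ds)

    # ------------------------------------------------------------------
    def _start_grid(self, logx: np.ndarray, y: np.ndarray, c: float):
        """Deterministic multi-start grid for (b, d, log e).

        e starts at the geometric mean/extremes of the assayed range and at
        the concentration whose DV is closest to the curve midpoint; b
        starts from a logit linearisation of centred responses plus fixed
        fallbacks.  Multi-start guards against the multimodality of the
        least-squares surface under noise.
        """
        d0 = float(np.max(y))
        if d0 <= c:
            d0 = c + 1e-3
        mid = 0.5 * (c + d0)
        u_candidates = [
            float(np.mean(logx)),
            float(logx[np.argmin(np.abs(y - mid))]),
            float(np.min(logx)),
            float(np.max(logx)),
        ]
        # logit linearisation: s = (y-c)/(d-c) in (0,1); logit(s) = -b(logx-u)
        b_lin = -1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.clip((y - c) / (d0 - c), 1e-3, 1 - 1e-3)
            logit = np.log(s / (1 - s))
            denom = np.sum((logx - logx.mean()) ** 2)
            if denom > 0:
                slope = float(np.sum((logx - logx.mean()) * logit) / denom)
                if slope > 0:
                    b_lin = -slope
        starts = []
        for b0 in (b_lin, -0.7, -2.5):
            for u0 in u_candidates[:2]:
                starts.append((min(b0, B_MAX), d0, u0))
        starts.append((-1.2, d0, u_candidates[2]))
        starts.append((-1.2, d0, u_candidates[3]))
        return starts

    def fit(self, xtol: float = 1e-8, ftol: float = 1e-10) -> "LogLogisticResults":
        """Fit by multi-start box-constrained least squares.

        Returns a :class:`LogLogisticResults`; never raises on optimizer
        failure (the ``converged`` flag is cleared and the best-found
        parameters retained).  Raises :class:`InsufficientDataError` when
        fewer than three distinct concentrations are available.
        """
        data = self.fit_data
        if data.n_distinct < 3:
            raise InsufficientDataError(
                f"{data.chemical_id}: {data.n_distinct} distinct concentrations; "
                f"at least 3 are required to fit (b, d, e)"
            )
        x = data.concentrations
        y = data.dvs
        c = self.control_dv
        logx = np.log(x)
        n = y.size

        flat_value, flat_rss = fit_flat(data)

        if np.allclose(y, y[0], atol=0.0):
            # no variation at all: degenerate, flagged not converged
            theta = np.array([B_MAX, c, float(np.exp(np.mean(logx)))])
            return LogLogisticResults(
                model=self,
                b=float(theta[0]),
                d=float(theta[1]),
                e=float(theta[2]),
                rss=float(flat_rss),
                converged=False,
                cov_bdu=None,
                _flat=(flat_value, flat_rss),
            )

        best = None
        any_success = False
        for b0, d0, u0 in self._start_grid(logx, y, c):
            beta0 = math.log(max(-b0 - abs(B_MAX), 1e-8))
            try:
                sol = optimize.least_squares(
                    _residuals_free,
                    np.array([beta0, d0, u0]),
                    jac=_jacobian_free,
                    method="lm",
                    args=(logx, y, c),
                    xtol=xtol,
                    ftol=ftol,
                    max_nfev=600,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
            any_success = any_success or bool(sol.success)

        rss, sol = best
        beta, d, u = (float(v) for v in sol.x)
        u = float(np.clip(u, -_U_CLIP, _U_CLIP))
        b = float(_b_of_beta(beta))
        e = float(np.exp(u))
        degenerate = d <= c + 1e-12
        converged = bool(any_success and math.isfinite(rss) and not degenerate)

        cov = None
        if converged and n > N_FREE_PARAMS:
            J = _jacobian(np.array([b, d, u]), logx, y, c)
            JtJ = J.T @ J
            try:
                cov = np.linalg.inv(JtJ) * (rss / (n - N_FREE_PARAMS))
            except np.linalg.LinAlgError:
                cov = None

        return LogLogisticResults(
            model=self,
            b=b,
            d=d,
            e=e,
            rss=rss,
            converged=converged,
            cov_bdu=cov,
            _flat=(flat_value, flat_rss),
        )


class LogLogisticResults:
    """Fit results: parameter estimates, diagnostics and derived tests.

    Attributes
    ----------
    b, c, d, e : float
        Fitted slope, fixed lower asymptote, upper asymptote and midpoint.
    rss : float
        Residual sum of squares of the fit.
    log_likelihood : float
        Gaussian profile log-likelihood (sigma^2 = rss/n).
    cov_bdu : ndarray or None
        3x3 Gauss-Newton covariance of (b, d, log e); None when the fit is
        degenerate or the normal matrix is singular.
    """

    def __init__(self, model, b, d, e, rss, converged, cov_bdu, _flat):
        self.model = model
        self.dataset = model.fit_data
        self.b = b
        self.c = model.control_dv
        self.d = d
        self.e = e
        self.rss = max(rss, 0.0)
        self.converged = converged
        self.cov_bdu = cov_bdu
        self.n_points = self.dataset.n_points
        self.n_free_params = N_FREE_PARAMS
        self._flat_value, self._flat_rss = _flat

    @property
    def params(self) -> dict[str, float]:
        return {"b": self.b, "c": self.c, "d": self.d, "e": self.e}

    @property
    def log_likelihood(self) -> float:
        return _gaussian_llf(self.rss, self.n_points)

    def predict(self, concentration) -> float | np.ndarray:
        """Predicted decision value at the given concentration(s), µM."""
        return log_logistic(concentration, self.b, self.c, self.d, self.e)

    def no_effect_test(self) -> NoEffectTestResult:
        """Likelihood-ratio test against the best horizontal line.

        LR = n * ln(RSS_flat / RSS_4PL), referred to a chi-square with
        df = 2 (the 4PL has three free mean parameters, the flat line one).
        The chi-square reference is approximate because of the boundary
        constraints on b and d.  A non-converged (degenerate) fit reports
        p = 1: the curve brings no improvement over the flat line.
        """
        n = self.n_points
        flat_value, flat_rss = self._flat_value, self._flat_rss
        df = N_FREE_PARAMS - 1
        if not self.converged:
            return NoEffectTestResult(
                lr_statistic=0.0,
                df=df,
                p_value=1.0,
                flat_fit_value=flat_value,
                flat_rss=flat_rss,
                converged=False,
            )
        if self.rss <= 0:
            lr = math.inf
        else:
            lr = n * math.log(flat_rss / self.rss) if flat_rss > 0 else 0.0
        lr = max(lr, 0.0)  # clip tiny negatives from numerical noise
        p = float(min(stats.chi2.sf(lr, df), 1.0)) if math.isfinite(lr) else 0.0
        return NoEffectTestResult(
            lr_statistic=float(lr),
            df=df,
            p_value=p,
            flat_fit_value=flat_value,
            flat_rss=flat_rss,
        )

    # cDV0 estimation lives in garddr.cdv0; these are convenience wrappers
    def cdv0(self, threshold: float = 0.0, ci_level: float | None = 0.95):
        """Threshold-crossing concentration from the fitted curve (see garddr.cdv0)."""
        from .cdv0 import cdv0_from_model

        return cdv0_from_model(self, threshold=threshold, ci_level=ci_level)

    def summary(self) -> str:
        net = self.no_effect_test()
        lines = [
            "Constrained log-logistic dose-response fit",
            "==========================================",
            f"chemical:        {self.dataset.chemical_id}",
            f"n points:        {self.n_points} (viable)",
            f"converged:       {self.converged}",
            f"slope b:         {self.b:.6g}   (constrained < 0)",
            f"lower asymp. c:  {self.c:.6g}   (fixed at control DV)",
            f"upper asymp. d:  {self.d:.6g}",
            f"midpoint e:      {self.e:.6g} µM",
            f"RSS:             {self.rss:.6g}",
            f"log-likelihood:  {self.log_likelihood:.6g}",
            f"no-effect test:  LR = {net.lr_statistic:.4g}, df = {net.df}, "
            f"p = {net.p_value:.3g}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<LogLogisticResults {self.dataset.chemical_id}: b={self.b:.4g}, "
            f"d={self.d:.4g}, e={self.e:.4g}, converged={self.converged}>"
        )


# ---------------------------------------------------------------------------
# functional layer


def fit_log_logistic(data: DoseResponseDataset) -> LogLogisticResults:
    """Fit the constrained log-logistic model to one dataset."""
    return LogLogisticDoseResponse(data).fit()


def fit_flat(data: DoseResponseDataset) -> tuple[float, float]:
    """Best-fitting horizontal line: (mean DV, residual sum of squares)."""
    y = data.viable_subset().dvs
    if y.size == 0:
        raise InsufficientDataError(f"{data.chemical_id}: no viable points")
    m = float(np.mean(y))
    return m, float(np.sum((y - m) ** 2))


def no_effect_test(data: DoseResponseDataset) -> NoEffectTestResult:
    """Fit both models and run the likelihood-ratio no-effect test."""
    return fit_log_logistic(data).no_effect_test()
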