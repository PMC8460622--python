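"""Synthetic dose-response generator with the statistical structure the
analysis assumes.

Raw decision-value titration data are not deposited anywhere, so every
stage of the pipeline is exercised against simulated experiments:
sigmoidal DV curves with the lower asymptote at the unstimulated-control
DV, homoscedastic Gaussian noise on the DV scale, flat curves for
non-sensitizers, and optional deterministic contamination modes that mimic
the two pathological shapes seen in practice — an apparent U-shape
(positive DVs at the lowest concentrations) and a two-phase curve (an
early rise to a positive plateau followed by a second increase).

DV magnitudes default to the ±1.5 range typical of the classifier's
output; the noise standard deviation defaults to 0.1, a convention (the
true DV noise magnitude is not quantified anywhere) exposed in every entry
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DoseResponseDataset
from .design import DEFAULT_CAP_UM, design_series
from .model import log_logistic

__all__ = ["SimulationSpec", "simulate_dataset", "simulate_panel", "default_grid", "true_cdv0"]

DEFAULT_NOISE_SD = 0.1


def default_grid(
    c_input: float = 500.0, cap: float = DEFAULT_CAP_UM, n: int = 9
) -> np.ndarray:
    """Assay-style concentration grid: the 3/5 geometric ladder, top ``n`` steps.

    Defaults to the ladder re-anchored at the 500 µM cap with nine
    concentrations retained, the usual post-screening regime.
    """
    series = design_series(c_input, cap=cap)
    return np.sort(series.concentrations)[-n:]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one simulated dose-response experiment.

    ``(b, c, d, e)`` are the log-logistic parameters (b < 0, e > 0, c < 0
    since the control must classify negative); ``noise_sd`` is the
    standard deviation of additive Gaussian noise on the DV scale;
    ``contamination`` is one of ``"none"``, ``"u_shape"``, ``"two_phase"``.
    """

    b: float = -1.5
    c: float = -1.0
    d: float = 1.0
    e: float = 20.0
    noise_sd: float = DEFAULT_NOISE_SD
    grid: np.ndarray = field(default_factory=default_grid)
    contamination: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.b < 0:
            raise ValueError(f"slope b must be negative, got {self.b}")
        if not self.e > 0:
            raise ValueError(f"midpoint e must be positive, got {self.e}")
        if not self.c < 0:
            raise ValueError(f"lower asymptote c must be negative (control DV), got {self.c}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        grid = np.sort(np.asarray(self.grid, dtype=float))
        if grid.size == 0:
            raise ValueError("grid must be non-empty")
        if np.any(grid <= 0):
            raise ValueError("grid concentrations must be positive")
        object.__setattr__(self, "grid", grid)
        if self.contamination not in ("none", "u_shape", "two_phase"):
            raise ValueError(f"unknown contamination mode {self.contamination!r}")


def true_cdv0(spec: SimulationSpec, threshold: float = 0.0) -> float | None:
    """Analytic threshold crossing of the uncontaminated true curve, or None."""
    if spec.d <= threshold or spec.c >= threshold:
        return None
    ratio = (spec.d - spec.c) / (threshold - spec.c) - 1.0
    return float(spec.e * ratio ** (1.0 / spec.b))


def _contaminate(spec: SimulationSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if spec.contamination == "none":
        return y
    logx = np.log(x)
    if spec.contamination == "u_shape":
        # positive bump at the lowest concentrations (Gaussian in log x),
        # large enough to push the lowest points above the threshold
        amp = abs(spec.c) + 0.3
        width = 0.7
        return y + amp * np.exp(-((logx - logx.min()) ** 2) / (2 * width**2))
    # two_phase: an early steep rise to a positive plateau well below the
    # main transition, so the first crossing sits far left of the 4PL one
    e_early = spec.e / 25.0
    amp = abs(spec.c) + 0.25
    early = amp / (1.0 + np.exp(np.clip(-4.0 * (logx - math.log(e_early)), -500, 500)))
    return y + early


def simulate_dataset(spec: SimulationSpec, chemical_id: str = "sim") -> DoseResponseDataset:
    """Draw one dataset: DV_i = f(c_i; b, c, d, e) [+ contamination] + noise.

    The control DV equals the true lower asymptote ``c``.  The same seed
    always reproduces the identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    x = spec.grid
    y = log_logistic(x, spec.b, spec.c, spec.d, spec.e)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    y = _contaminate(spec, x, y)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
    return DoseResponseDataset.from_arrays(
        chemical_id=chemical_id,
        concentrations=x,
        dvs=y,
        control_dv=spec.c,
    )


def simulate_panel(
    n_sensitizers: int,
    n_nonsensitizers: int,
    potency_range: tuple[float, float] = (1.0, 500.0),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[list[DoseResponseDataset], pd.DataFrame]:
    """Simulate a chemical panel with known potencies.

    Sensitizers get true threshold-crossing concentrations drawn
    log-uniformly over ``potency_range`` (µM); the midpoint ``e`` is then
    back-solved from the drawn crossing, slope and asymptotes so the truth
    is exact by construction.  Non-sensitizers are flat at the control DV
    plus noise.  Returns the datasets and a ground-truth table with one row
    per chemical (``true_cdv0_um`` is NaN for non-sensitizers).
    """
    if n_sensitizers < 0 or n_nonsensitizers < 0:
        raise ValueError("panel counts must be non-negative")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = default_grid()
    datasets: list[DoseResponseDataset] = []
    truth_rows = []
    lo, hi = potency_range
    for i in range(n_sensitizers):
        x0 = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        b = float(rng.uniform(-3.0, -0.8))
        c = -1.0
        d = float(rng.uniform(0.8, 1.5))
        # back-solve e so the curve crosses the threshold exactly at x0
        ratio = (d - c) / (0.0 - c) - 1.0
        e = x0 * ratio ** (-1.0 / b)
        spec = SimulationSpec(
            b=b,
            c=c,
            d=d,
            e=e,
            noise_sd=noise_sd,
            grid=grid,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cid = f"sens_{i + 1:03d}"
        datasets.append(simulate_dataset(spec, chemical_id=cid))
        truth_rows.append(
            {
                "chemical_id": cid,
                "sensitizer": True,
                "true_cdv0_um": x0,
                "b": b,
                "c": c,
                "d": d,
                "e": e,
            }
        )
    for i in range(n_nonsensitizers):
        c = -1.0
        cid = f"nons_{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        dvs = c + (sub_rng.normal(0.0, noise_sd, size=len(grid)) if noise_sd > 0 else 0.0)
        datasets.append(
            DoseResponseDataset.from_arrays(
                chemical_id=cid,
                concentrations=grid,
                dvs=np.atleast_1d(dvs) * np.ones(len(grid)),
                control_dv=c,
            )
        )
        truth_rows.append(
            {
                "chemical_id": cid,
                "sensitizer": False,
                "true_cdv0_um": math.nan,
                "b": math.nan,
                "c": c,
                "d": math.nan,
                "e": math.nan,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chemical_id", "sensitizer", "true_cdv0_um", "b", "c", "d", "e"],
    )
    return datasets, truth
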