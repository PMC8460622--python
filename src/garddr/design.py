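"""Concentration-series design for dose-response runs of the assay.

Concentrations form a descending geometric ladder with scaling factor 3/5,

    c_i = c_input * (3/5) ** (i - 3),   i = 1 .. 12,

anchored so that the highest concentration sits two steps above the assay
input concentration, but never above the standard upper concentration
limit (500 µM by default).  When the two-steps-above anchor would exceed
the cap, the whole ladder is re-anchored to descend from the cap (a
truncation alternative is selectable).  After cytotoxicity screening,
non-viable concentrations and typically the lowest step are excluded,
leaving eight to nine assayed concentrations per chemical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ConcentrationStep", "ConcentrationSeries", "design_series", "select_for_assay"]

logger = logging.getLogger(__name__)

RATIO = 3.0 / 5.0
DEFAULT_CAP_UM = 500.0
DEFAULT_N_STEPS = 12


@dataclass(frozen=True)
class ConcentrationStep:
    index: int
    concentration: float
    selected: bool = True


@dataclass(frozen=True)
class ConcentrationSeries:
    """A chemical's geometric concentration ladder (descending, ratio 3/5)."""

    chemical_id: str
    input_concentration: float
    steps: tuple[ConcentrationStep, ...]
    cap: float = DEFAULT_CAP_UM

    @property
    def concentrations(self) -> np.ndarray:
        """All generated concentrations, descending (µM)."""
        return np.array([s.concentration for s in self.steps])

    @property
    def selected_concentrations(self) -> np.ndarray:
        """Concentrations retained for assaying, descending (µM)."""
        return np.array([s.concentration for s in self.steps if s.selected])

    @property
    def n_selected(self) -> int:
        return sum(1 for s in self.steps if s.selected)


def design_series(
    c_input: float,
    cap: float = DEFAULT_CAP_UM,
    n_steps: int = DEFAULT_N_STEPS,
    chemical_id: str = "",
    cap_mode: str = "reanchor",
) -> ConcentrationSeries:
    """Generate the geometric concentration ladder for one chemical.

    The anchor (highest concentration) is ``c_input * (5/3)**2`` — two
    steps above the input concentration — capped at ``cap``.  With
    ``cap_mode="reanchor"`` (default) a binding cap re-anchors the whole
    ladder to descend from the cap; with ``"truncate"`` the uncapped
    ladder is generated and steps above the cap removed.
    """
    if not c_input > 0:
        raise ValueError(f"c_input must be positive, got {c_input}")
    if cap_mode not in ("reanchor", "truncate"):
        raise ValueError(f"unknown cap_mode {cap_mode!r}")
    anchor = c_input * RATIO ** (-2)
    if cap_mode == "reanchor":
        anchor = min(anchor, cap)
        concs = anchor * RATIO ** np.arange(n_steps)
    else:
        concs = anchor * RATIO ** np.arange(n_steps)
        concs = np.minimum(concs[concs <= cap * (1 + 1e-12)], cap)
    steps = tuple(
        ConcentrationStep(index=i + 1, concentration=float(c), selected=True)
        for i, c in enumerate(concs)
    )
    return ConcentrationSeries(
        chemical_id=chemical_id, input_concentration=c_input, steps=steps, cap=cap
    )


def select_for_assay(
    series: ConcentrationSeries,
    viability: dict[float, bool] | None = None,
    drop_lowest: bool = True,
) -> ConcentrationSeries:
    """Deselect cytotoxic concentrations and, by default, the lowest step.

    ``viability`` maps concentration (µM) to whether the cytotoxicity
    screen was passed; concentrations absent from the map are assumed
    viable.  Every exclusion is logged with its reason.  A warning (not an
    error) is raised when the selected count falls outside the usual
    eight-to-nine range.
    """
    viability = viability or {}
    concs = series.concentrations
    for key in viability:
        if not np.any(np.isclose(concs, key, rtol=1e-9)):
            raise ValueError(f"viability key {key} is not a concentration of the series")

    def is_viable(c: float) -> bool:
        for key, ok in viability.items():
            if np.isclose(c, key, rtol=1e-9):
                return bool(ok)
        return True

    lowest = min(s.concentration for s in series.steps)
    new_steps = []
    for s in series.steps:
        selected = s.selected
        if selected and not is_viable(s.concentration):
            selected = False
            logger.info(
                "%s: excluding %.6g µM (excessive cytotoxicity)",
                series.chemical_id,
                s.concentration,
            )
        if selected and drop_lowest and s.concentration == lowest:
            selected = False
            logger.info(
                "%s: excluding %.6g µM (lowest evaluated concentration)",
                series.chemical_id,
                s.concentration,
            )
        new_steps.append(replace(s, selected=selected))
    out = replace(series, steps=tuple(new_steps))
    if not 8 <= out.n_selected <= 9:
        warnings.warn(
            f"{series.chemical_id or 'series'}: {out.n_selected} concentrations selected; "
            "eight to nine is the usual regime",
            stacklevel=2,
        )
    return out
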