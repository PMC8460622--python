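"""Dose-response data containers and delimited-text readers/writers.

The unit of analysis is one chemical's titration series: a set of
(concentration, decision value) points produced by running the frozen
GARDskin classifier on samples exposed at each concentration, together
with the decision value of unstimulated controls.  Decision values (DVs)
are the signed outputs of the classifier; DV >= 0 classifies a sample as
a skin sensitizer.  Concentrations are in µM throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponsePoint",
    "DoseResponseDataset",
    "InsufficientDataError",
    "SchemaError",
    "read_dose_response",
    "write_dose_response",
]


class SchemaError(ValueError):
    """Raised when an input table violates the expected column schema."""


class InsufficientDataError(ValueError):
    """Raised when a dataset has too few distinct concentrations to fit."""


@dataclass(frozen=True)
class DoseResponsePoint:
    """A single assayed concentration and its classifier decision value.

    Parameters
    ----------
    concentration : float
        Exposure concentration in µM; must be strictly positive so that
        log-concentration is defined.
    dv : float
        Decision value of the classifier at this concentration (unitless).
    viable : bool
        Whether the concentration passed the cytotoxicity screen.  Points
        failing the screen are excluded before any fitting.
    is_input_concentration : bool
        Marks the standard single-dose input concentration of the assay.
    """

    concentration: float
    dv: float
    viable: bool = True
    is_input_concentration: bool = False

    def __post_init__(self) -> None:
        if not (self.concentration > 0) or not math.isfinite(self.concentration):
            raise ValueError(
                f"concentration must be positive and finite, got {self.concentration!r}"
            )
        if not math.isfinite(self.dv):
            raise ValueError(f"dv must be finite, got {self.dv!r}")


@dataclass(frozen=True)
class DoseResponseDataset:
    """One chemical's dose-response experiment.

    Points are stored sorted ascending by concentration; replicates
    (duplicate concentrations) are retained.  ``control_dv`` is the decision
    value of unstimulated controls and anchors the fixed lower asymptote of
    the log-logistic model; an unstimulated control must classify negative,
    so ``control_dv < 0`` is enforced.
    """

    chemical_id: str
    points: tuple[DoseResponsePoint, ...]
    control_dv: float
    input_concentration: float | None = None

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.concentration))
        object.__setattr__(self, "points", pts)
        if not (self.control_dv < 0):
            raise ValueError(
                f"{self.chemical_id}: control_dv must be negative "
                f"(an unstimulated control must classify negative), got {self.control_dv}"
            )
        if self.input_concentration is not None and not self.input_concentration > 0:
            raise ValueError("input_concentration must be positive when given")
        if 0 < self.n_distinct < 4:
            warnings.warn(
                f"{self.chemical_id}: only {self.n_distinct} distinct concentrations; "
                "at least 4 are recommended for a stable fit",
                stacklevel=2,
            )

    # -- array views -------------------------------------------------------
    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration for p in self.points], dtype=float)

    @property
    def dvs(self) -> np.ndarray:
        return np.array([p.dv for p in self.points], dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_distinct(self) -> int:
        return len({p.concentration for p in self.points})

    def viable_subset(self) -> "DoseResponseDataset":
        """Return a copy containing only points that passed the cytotoxicity screen."""
        kept = tuple(p for p in self.points if p.viable)
        if len(kept) == len(self.points):
            return self
        return replace(self, points=kept)

    def excluded_points(self) -> tuple[DoseResponsePoint, ...]:
        return tuple(p for p in self.points if not p.viable)

    @classmethod
    def from_arrays(
        cls,
        chemical_id: str,
        concentrations: Sequence[float],
        dvs: Sequence[float],
        control_dv: float,
        viable: Sequence[bool] | None = None,
        input_concentration: float | None = None,
    ) -> "DoseResponseDataset":
        conc = np.asarray(concentrations, dtype=float)
        dv = np.asarray(dvs, dtype=float)
        if conc.shape != dv.shape:
            raise ValueError("concentrations and dvs must have equal length")
        if viable is None:
            viable = np.ones(conc.shape, dtype=bool)
        pts = tuple(
            DoseResponsePoint(
                concentration=float(c),
                dv=float(y),
                viable=bool(v),
                is_input_concentration=(
                    input_concentration is not None
                    and math.isclose(float(c), input_concentration, rel_tol=1e-9)
                ),
            )
            for c, y, v in zip(conc, dv, viable)
        )
        return cls(
            chemical_id=chemical_id,
            points=pts,
            control_dv=control_dv,
            input_concentration=input_concentration,
        )


_REQUIRED_COLUMNS = ("chemical_id", "concentration_uM", "dv")


def read_dose_response(
    path: str | Path,
    default_control_dv: float = -1.0,
) -> list[DoseResponseDataset]:
    """Read dose-response datasets from a delimited text file.

    The file must be UTF-8 CSV/TSV with a header row and columns
    ``chemical_id, concentration_uM, dv`` plus optional ``viable`` (0/1,
    default 1), ``is_input`` (0/1) and ``control_dv`` (constant per
    chemical).  When ``control_dv`` is absent, ``default_control_dv`` is
    used for every chemical.

    Malformed rows are reported with their 1-based file line numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []

    bad: list[str] = []
    # +2: header occupies line 1, data starts at line 2
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            conc = float(row["concentration_uM"])
            dv = float(row["dv"])
        except (TypeError, ValueError):
            bad.append(f"line {line}: non-numeric concentration_uM/dv")
            continue
        if not conc > 0 or not math.isfinite(conc):
            bad.append(f"line {line}: concentration_uM must be > 0, got {conc}")
        if not math.isfinite(dv):
            bad.append(f"line {line}: dv must be finite")
    if bad:
        raise SchemaError(f"{path}: malformed rows:\n  " + "\n  ".join(bad))

    datasets: list[DoseResponseDataset] = []
    for chem, grp in df.groupby("chemical_id", sort=True):
        viable = (
            grp["viable"].astype(float).astype(bool).to_numpy()
            if "viable" in grp.columns
            else None
        )
        if "control_dv" in grp.columns:
            ctrl_vals = grp["control_dv"].astype(float).unique()
            if len(ctrl_vals) != 1:
                raise SchemaError(
                    f"{path}: chemical {chem!r} has non-constant control_dv"
                )
            control_dv = float(ctrl_vals[0])
        else:
            control_dv = default_control_dv
        input_conc = None
        if "is_input" in grp.columns:
            marked = grp.loc[grp["is_input"].astype(float) > 0, "concentration_uM"]
            if len(marked):
                input_conc = float(marked.iloc[0])
        datasets.append(
            DoseResponseDataset.from_arrays(
                chemical_id=str(chem),
                concentrations=grp["concentration_uM"].to_numpy(dtype=float),
                dvs=grp["dv"].to_numpy(dtype=float),
                control_dv=control_dv,
                viable=viable,
                input_concentration=input_conc,
            )
        )
    return datasets


def write_dose_response(
    datasets: Iterable[DoseResponseDataset], path: str | Path
) -> None:
    """Write datasets in the standard input CSV dialect (lossless round-trip)."""
    rows = []
    for ds in datasets:
        for p in ds.points:
            rows.append(
                {
                    "chemical_id": ds.chemical_id,
                    "concentration_uM": repr(p.concentration),
                    "dv": repr(p.dv),
                    "viable": int(p.viable),
                    "is_input": int(p.is_input_concentration),
                    "control_dv": repr(ds.control_dv),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
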