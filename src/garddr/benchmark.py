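"""Benchmarking cDV0 against reference potency metrics.

cDV0 values (µM) are converted to weight-based concentrations (mg/L) so
they can be compared across chemicals of different molecular weight, then
correlated on the log scale against two established potency references:

* **LLNA EC3** — the concentration (%) giving a threefold lymphocyte
  stimulation index in the murine local lymph node assay; lower EC3 means
  a more potent sensitizer;
* **human NOEL** — the no-observed-effect level (µg/cm²) from human
  repeated insult patch testing.

GHS sub-categories are assigned from EC3 with the standard 2% cutoff
(1A: EC3 <= 2%, 1B: EC3 > 2%, non-sensitizers: No Cat), and a
class-separation report checks how cleanly ranking chemicals by cDV0
resolves 1A from 1B.

The packaged reference table ``table1_reference.csv`` carries the study's
29 chemicals with their censoring markers (``NS`` non-sensitizer, ``ND``
insufficient data for a NOEL, ``NA`` undefined) as literal tokens, plus a
molecular-weight column.  For the mixture benzalkonium chloride the
molecular weight is back-computed from the table's paired µM / mg/L
values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChemicalRecord",
    "CorrelationResult",
    "ClassSeparationReport",
    "um_to_mg_per_l",
    "mg_per_l_to_um",
    "ghs_subcategory",
    "load_reference_table",
    "records_from_frame",
    "correlate_potency",
    "class_separation_report",
    "GHS_EC3_CUTOFF_PCT",
]

GHS_EC3_CUTOFF_PCT = 2.0


def um_to_mg_per_l(concentration_um: float, molecular_weight: float) -> float:
    """Convert a molar concentration (µM) to mg/L via the molecular weight (g/mol)."""
    if not concentration_um > 0:
        raise ValueError(f"concentration must be positive, got {concentration_um}")
    if not molecular_weight > 0:
        raise ValueError(f"molecular weight must be positive, got {molecular_weight}")
    return concentration_um * molecular_weight / 1000.0


def mg_per_l_to_um(concentration_mg_l: float, molecular_weight: float) -> float:
    """Inverse of :func:`um_to_mg_per_l`."""
    if not concentration_mg_l > 0 or not molecular_weight > 0:
        raise ValueError("inputs must be positive")
    return concentration_mg_l * 1000.0 / molecular_weight


def ghs_subcategory(ec3, cutoff: float = GHS_EC3_CUTOFF_PCT) -> str:
    """GHS sub-category from an LLNA EC3 value (%): 1A, 1B or NoCat.

    ``ec3`` may be a number or the censoring token ``"NS"`` (LLNA
    non-sensitizer).  The cutoff is inclusive: EC3 <= 2% is 1A.
    """
    if ec3 is None or (isinstance(ec3, str) and ec3.upper() == "NS"):
        return "NoCat"
    if isinstance(ec3, float) and math.isnan(ec3):
        return "NoCat"
    ec3 = float(ec3)
    if not 0 < ec3 <= 100:
        raise ValueError(f"EC3 must be in (0, 100] %, got {ec3}")
    return "1A" if ec3 <= cutoff else "1B"


@dataclass(frozen=True)
class ChemicalRecord:
    """Reference potency data for one chemical.

    Numeric fields are None when censored; the original censoring token is
    kept in the matching ``*_status`` field ("" when numeric).
    """

    name: str
    cas: str
    molecular_weight: float
    llna_ec3: float | None
    noel: float | None
    cdv0_um: float | None
    cdv0_mgl: float | None
    ec3_status: str = ""
    noel_status: str = ""
    cdv0_status: str = ""
    sensitizer: bool = True
    ghs: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValueError(f"{self.name}: molecular weight must be positive")
        if self.llna_ec3 is not None and not 0 < self.llna_ec3 <= 100:
            raise ValueError(f"{self.name}: EC3 must be in (0, 100] %")
        if self.cdv0_um is not None and self.cdv0_mgl is not None:
            implied = um_to_mg_per_l(self.cdv0_um, self.molecular_weight)
            if abs(implied - self.cdv0_mgl) / self.cdv0_mgl > 0.02:
                warnings.warn(
                    f"{self.name}: cdv0_um x MW / 1000 = {implied:.3g} mg/L differs from "
                    f"the recorded {self.cdv0_mgl:.3g} mg/L by more than 2%",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class CorrelationResult:
    """Log-scale Pearson correlation between cDV0 and a reference metric."""

    r: float
    p_value: float
    n: int
    metric: str

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("Pearson r must lie in [-1, 1]")


def _parse_cell(value) -> tuple[float | None, str]:
    """Split a table cell into (numeric value or None, censoring token)."""
    if value is None:
        return None, "NA"
    s = str(value).strip()
    if s.upper() in {"NS", "ND", "NA", "NM", ""} or s.lower() == "nan":
        token = s.upper() if s and s.lower() != "nan" else "NA"
        return None, token
    return float(s), ""


def load_reference_table(path: str | Path | None = None) -> list[ChemicalRecord]:
    """Load the chemical reference table (the packaged study table by default).

    Censoring markers (NS/ND/NA) are parsed into None values plus status
    tokens; GHS sub-categories are assigned from the EC3 column.  Internal
    µM vs mg/L consistency is checked through :class:`ChemicalRecord`
    (violations warn, they do not fail: printed tables round).
    """
    if path is None:
        source = resources.files("garddr.resources").joinpath("table1_reference.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[ChemicalRecord]:
    records = []
    for _, row in df.iterrows():
        ec3, ec3_tok = _parse_cell(row.get("llna_ec3_pct"))
        noel, noel_tok = _parse_cell(row.get("noel_ug_cm2"))
        cdv0_um, cdv0_tok = _parse_cell(row.get("cdv0_interp_um"))
        cdv0_mgl, _ = _parse_cell(row.get("cdv0_interp_mg_l"))
        records.append(
            ChemicalRecord(
                name=str(row["name"]),
                cas=str(row.get("cas", "")),
                molecular_weight=float(row["molecular_weight_g_mol"]),
                llna_ec3=ec3,
                noel=noel,
                cdv0_um=cdv0_um,
                cdv0_mgl=cdv0_mgl,
                ec3_status=ec3_tok,
                noel_status=noel_tok,
                cdv0_status=cdv0_tok,
                sensitizer=bool(int(row.get("sensitizer", 1))),
                ghs=ghs_subcategory(ec3 if ec3 is not None else "NS"),
            )
        )
    return records


_METRICS = {
    "llna_ec3": lambda r: r.llna_ec3,
    "human_noel": lambda r: r.noel,
}


def correlate_potency(
    records: list[ChemicalRecord],
    metric: str = "llna_ec3",
    cdv0_scale: str = "mg_l",
) -> CorrelationResult:
    """Pearson correlation of log cDV0 against a log reference metric.

    Pairs are formed from records where both cDV0 and the chosen metric
    are numeric; censored entries (NS/ND/NA) drop out.  cDV0 enters in
    weight-based units (mg/L) by default so chemicals of different
    molecular weight are comparable.  The p-value is the standard
    two-sided t test with n - 2 degrees of freedom.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    getter = _METRICS[metric]
    xs, ys = [], []
    for rec in records:
        ref = getter(rec)
        cdv0 = rec.cdv0_mgl if cdv0_scale == "mg_l" else rec.cdv0_um
        if ref is None or cdv0 is None:
            continue
        xs.append(math.log(ref))
        ys.append(math.log(cdv0))
    n = len(xs)
    if n < 3:
        raise ValueError(f"only {n} complete pairs for metric {metric!r}; need >= 3")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(r=float(r), p_value=float(p), n=n, metric=metric)


@dataclass(frozen=True)
class ClassSeparationReport:
    """Ordering of chemicals by cDV0 with 1A/1B resolution diagnostics.

    ``violations`` lists the 1B chemicals whose cDV0 ranks below (is more
    potent than) at least one 1A chemical; an empty list means ranking by
    cDV0 separates the classes completely.
    """

    table: pd.DataFrame
    violations: tuple[str, ...]

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def class_separation_report(
    records: list[ChemicalRecord], cdv0_scale: str = "um"
) -> ClassSeparationReport:
    """Sort by cDV0 and count 1B chemicals ranking below any 1A chemical."""
    rows = []
    for rec in records:
        cdv0 = rec.cdv0_um if cdv0_scale == "um" else rec.cdv0_mgl
        if cdv0 is None or rec.ghs not in ("1A", "1B"):
            continue
        rows.append({"name": rec.name, "cdv0": cdv0, "ghs": rec.ghs})
    table = pd.DataFrame(rows, columns=["name", "cdv0", "ghs"]).sort_values(
        "cdv0", ignore_index=True
    )
    violations: tuple[str, ...] = ()
    a_vals = table.loc[table["ghs"] == "1A", "cdv0"]
    if len(a_vals):
        max_1a = a_vals.max()
        mask = (table["ghs"] == "1B") & (table["cdv0"] < max_1a)
        violations = tuple(table.loc[mask, "name"])
    return ClassSeparationReport(table=table, violations=violations)
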