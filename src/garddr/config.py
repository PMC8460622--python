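"""Run configuration: the analysis constants in one serializable place."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable constants of the end-to-end analysis.

    threshold
        Decision-value threshold defining cDV0 (the classifier's positive
        border; 0 by default).
    smoothing_window
        Odd window of the running median applied before interpolation when
        the DV sign pattern looks noisy.
    ci_level
        Confidence level of the inverse-regression interval on cDV0.
    ghs_cutoff
        LLNA EC3 cutoff (%) splitting GHS 1A from 1B.
    cap
        Upper concentration limit of the assay ladder (µM).
    estimator
        Which cDV0 estimate feeds the benchmark correlations.
    seed
        Seed for any simulation the run performs.
    """

    threshold: float = 0.0
    smoothing_window: int = 3
    ci_level: float = 0.95
    ghs_cutoff: float = 2.0
    cap: float = 500.0
    estimator: str = "linear_interpolation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothing_window % 2 == 0 or self.smoothing_window < 3:
            raise ValueError("smoothing_window must be an odd integer >= 3")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.estimator not in ("linear_interpolation", "log_logistic"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    def to_file(self, path: str | Path) -> None:
        """Write as a flat key=value file (lossless round-trip)."""
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name}={value!r}" if isinstance(value, str) else f"{f.name}={value!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if key == "estimator":
                kwargs[key] = raw.strip("'\"")
            elif key in ("smoothing_window", "seed"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)
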