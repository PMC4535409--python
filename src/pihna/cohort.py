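"""Virtual cohort: logarithmic grids of tumour growth kinetics.

The study population is not sampled -- it is a deterministic Cartesian
sweep of net proliferation rates rho and net invasion rates D spanning
the ranges reported for patient-derived glioma kinetics (roughly two
orders of magnitude each), evaluated at three treatment-start sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = ["CohortGrid", "VirtualPatient", "build_cohort", "aggressive_preset"]


class VirtualPatient(NamedTuple):
    patient_id: str
    D: float        # mm^2/yr
    rho: float      # 1/yr


@dataclass(frozen=True)
class CohortGrid:
    """Cartesian product of kinetic rates and treatment-start sizes."""

    rho_values: np.ndarray          # 1/yr, sorted ascending
    D_values: np.ndarray            # mm^2/yr, sorted ascending
    start_sizes_cm: tuple[float, ...] = (1.5, 2.5, 3.5)

    def __post_init__(self) -> None:
        for name in ("rho_values", "D_values"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if np.any(np.diff(vals) < 0):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, vals)
        if any(s <= 0 for s in self.start_sizes_cm):
            raise ValueError("start sizes must be positive")

    @property
    def n_patients(self) -> int:
        return self.rho_values.size * self.D_values.size

    def patients(self) -> Iterator[VirtualPatient]:
        """Iterate (D, rho) pairs in row-major (D outer, rho inner) order."""
        for i, D in enumerate(self.D_values):
            for j, rho in enumerate(self.rho_values):
                yield VirtualPatient(f"D{i:02d}_r{j:02d}", float(D), float(rho))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p.patient_id, "D": p.D, "rho": p.rho,
             "start_size_cm": s}
            for s in self.start_sizes_cm for p in self.patients()
        ]
        return pd.DataFrame(rows)


def build_cohort(rho_bounds: tuple[float, float] = (8.3, 83.0),
                 n_rho: int = 11,
                 D_bounds: tuple[float, float] = (1.43, 143.0),
                 n_D: int = 13,
                 start_sizes_cm: tuple[float, ...] = (1.5, 2.5, 3.5)) -> CohortGrid:
    """Deterministic log-spaced kinetics grid (default 11 rho x 13 D).

    Both axes are geometric sequences including their endpoints, so the
    same bounds always reproduce bit-identical grids.  Equal bounds give a
    degenerate single-value axis and emit a warning.
    """
    for name, (lo, hi) in (("rho", rho_bounds), ("D", D_bounds)):
        if lo <= 0 or hi <= 0:
            raise ValueError(f"{name} bounds must be positive")
        if lo > hi:
            raise ValueError(f"{name} lower bound exceeds upper bound")
        if lo == hi:
            warnings.warn(f"degenerate {name} axis: both bounds equal {lo}",
                          stacklevel=2)
    rho_values = (np.geomspace(*rho_bounds, n_rho) if rho_bounds[0] < rho_bounds[1]
                  else np.full(n_rho, rho_bounds[0]))
    D_values = (np.geomspace(*D_bounds, n_D) if D_bounds[0] < D_bounds[1]
                else np.full(n_D, D_bounds[0]))
    return CohortGrid(rho_values=rho_values, D_values=D_values,
                      start_sizes_cm=tuple(start_sizes_cm))


def aggressive_preset() -> tuple[float, float]:
    """Kinetics of the named aggressive virtual patient: (D, rho).

    D = 305 mm^2/yr, rho = 83 /yr -- a fast-growing, highly invasive GBM.
    """
    return 305.0, 83.0
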