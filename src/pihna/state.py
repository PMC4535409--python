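"""Tumour state container: the five radial profiles at one time point."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import RadialGrid

__all__ = ["TumourState", "FIELD_NAMES"]

FIELD_NAMES = ("c", "h", "n", "v", "a")


@dataclass(frozen=True)
class TumourState:
    """Radial profiles of the PIHNA fields at time ``t`` (days).

    c, h, n : normoxic, hypoxic and necrotic tumour cell densities,
    cells/mm^3; v : vascular density, cells/mm^3; a : angiogenic factor
    concentration, a-units.
    """

    t: float
    c: np.ndarray
    h: np.ndarray
    n: np.ndarray
    v: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, f)) for f in FIELD_NAMES}
        if len(lengths) != 1:
            raise ValueError("all field profiles must share one length")
        for f in FIELD_NAMES:
            object.__setattr__(self, f, np.asarray(getattr(self, f), dtype=float))

    # -- construction ------------------------------------------------------
    @classmethod
    def seed(cls, grid: RadialGrid, params, amplitude_fraction: float = 0.02,
             width: float = 1.0) -> "TumourState":
        """Localised low-density normoxic seed in otherwise normal tissue.

        c(r,0) = amplitude_fraction*K * exp(-(r/width)^2); h = n = a = 0;
        v at the normal-tissue level.  Starting well below carrying
        capacity lets the whole early lesion rise towards K together, so
        the imaging profile stays radially monotone and the enhancing
        core forms shortly after the lesion first becomes T2-visible,
        for diffuse and nodular kinetics alike.
        """
        z = np.zeros_like(grid.r)
        c0 = amplitude_fraction * params.K * np.exp(-((grid.r / width) ** 2))
        v0 = np.full_like(grid.r, params.vascular_fraction_normal * params.K)
        return cls(t=0.0, c=c0, h=z.copy(), n=z.copy(), v=v0, a=z.copy())

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray) -> "TumourState":
        Y = y.reshape(-1, len(FIELD_NAMES))
        return cls(t=t, c=Y[:, 0].copy(), h=Y[:, 1].copy(), n=Y[:, 2].copy(),
                   v=Y[:, 3].copy(), a=Y[:, 4].copy())

    def to_vector(self) -> np.ndarray:
        return np.column_stack([getattr(self, f) for f in FIELD_NAMES]).ravel()

    # -- derived quantities ------------------------------------------------
    @property
    def total_density(self) -> np.ndarray:
        """Total malignant cell density c + h + n (vasculature excluded)."""
        return self.c + self.h + self.n

    @property
    def viable_density(self) -> np.ndarray:
        return self.c + self.h

    def with_time(self, t: float) -> "TumourState":
        return replace(self, t=t)

    # -- validation --------------------------------------------------------
    def validate(self, grid: RadialGrid, K: float | None = None,
                 negative_tol: float = 1.0, capacity_tol: float = 1e-3) -> None:
        """Check invariants: grid match, nonnegativity, capacity bound."""
        for f in FIELD_NAMES:
            prof = getattr(self, f)
            if prof.shape != grid.r.shape:
                raise ValueError(f"profile {f!r} does not match the grid")
            if prof.min() < -negative_tol:
                raise ValueError(
                    f"profile {f!r} is negative beyond tolerance "
                    f"(min {prof.min():.3g})")
        if K is not None and self.total_density.max() > K * (1 + capacity_tol):
            raise ValueError("total cell density exceeds carrying capacity")

    def clipped(self) -> "TumourState":
        """Copy with tiny numerical undershoots clipped to zero."""
        return TumourState(t=self.t, **{f: np.maximum(getattr(self, f), 0.0)
                                        for f in FIELD_NAMES})

    # -- I/O ----------------------------------------------------------------
    def to_frame(self, grid: RadialGrid) -> pd.DataFrame:
        return pd.DataFrame({"r": grid.r, **{f: getattr(self, f) for f in FIELD_NAMES}})

    def to_csv(self, path, grid: RadialGrid) -> None:
        self.to_frame(grid).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, t: float = 0.0) -> tuple["TumourState", RadialGrid]:
        df = pd.read_csv(path)
        r = df["r"].to_numpy()
        grid = RadialGrid(r=r, dr=float(r[1] - r[0]), r_max=float(r[-1]))
        return cls(t=t, **{f: df[f].to_numpy() for f in FIELD_NAMES}), grid

    def to_npz(self, path, grid: RadialGrid) -> None:
        np.savez(path, t=self.t, r=grid.r,
                 **{f: getattr(self, f) for f in FIELD_NAMES})

    @classmethod
    def from_npz(cls, path) -> tuple["TumourState", RadialGrid]:
        with np.load(path) as data:
            r = data["r"]
            grid = RadialGrid(r=r, dr=float(r[1] - r[0]), r_max=float(r[-1]))
            return cls(t=float(data["t"]),
                       **{f: data[f] for f in FIELD_NAMES}), grid
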