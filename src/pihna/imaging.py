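"""Imaging observables and population summaries.

MRI-visible tumour extent is modelled as an isocontour of total malignant
cell density: the T1Gd (contrast-enhancing) abnormality is where density
reaches 80% of the carrying capacity K, the T2/FLAIR abnormality where it
reaches 16%.  Cell counts are spherical integrals 4*pi Int u(r) r^2 dr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RadialGrid
from .state import TumourState

__all__ = [
    "ImagingThresholds", "PopulationCounts",
    "radius_at_threshold", "spherical_count", "composition",
]


@dataclass(frozen=True)
class ImagingThresholds:
    """Density thresholds (fractions of K) defining the MRI abnormalities."""

    t1gd_fraction: float = 0.80
    t2_fraction: float = 0.16

    def __post_init__(self) -> None:
        if not 0.0 < self.t2_fraction < self.t1gd_fraction < 1.0:
            raise ValueError(
                "need 0 < t2_fraction < t1gd_fraction < 1, got "
                f"{self.t2_fraction} and {self.t1gd_fraction}")


@dataclass(frozen=True)
class PopulationCounts:
    """Spherical cell counts per phenotype and their composition fractions.

    Fractions are ``None`` when the tumour is empty (N_total == 0) rather
    than NaN, so downstream arithmetic fails loudly instead of silently.
    """

    N_c: float
    N_h: float
    N_n: float

    @property
    def N_total(self) -> float:
        return self.N_c + self.N_h + self.N_n

    def _frac(self, x: float) -> float | None:
        return x / self.N_total if self.N_total > 0 else None

    @property
    def f_c(self) -> float | None:
        return self._frac(self.N_c)

    @property
    def f_h(self) -> float | None:
        return self._frac(self.N_h)

    @property
    def f_n(self) -> float | None:
        return self._frac(self.N_n)


def _total_for_imaging(state: TumourState, include_necrotic: bool,
                       include_vasculature: bool) -> np.ndarray:
    total = state.total_density if include_necrotic else state.viable_density
    return total + state.v if include_vasculature else total


def radius_at_threshold(state: TumourState, grid: RadialGrid,
                        fraction_of_K: float, K: float,
                        include_necrotic: bool = True,
                        include_vasculature: bool = False) -> float:
    """Outermost radius (mm) where total density >= fraction_of_K * K.

    The total is the malignant cell density c+h+n by default; necrotic
    and vascular inclusion are both configurable.  The crossing is located
    by linear interpolation between grid nodes; for non-monotone profiles
    (possible with a collapsing necrotic core) the *outermost* crossing is
    reported, matching how an imaging abnormality boundary is read.
    Returns 0.0 when the density is everywhere below threshold.
    """
    if not 0.0 < fraction_of_K < 1.0:
        raise ValueError("fraction_of_K must lie strictly between 0 and 1")
    total = _total_for_imaging(state, include_necrotic, include_vasculature)
    threshold = fraction_of_K * K
    above = np.flatnonzero(total >= threshold)
    if above.size == 0:
        return 0.0
    j = int(above[-1])
    if j == grid.n - 1:
        return float(grid.r[-1])
    frac = (total[j] - threshold) / (total[j] - total[j + 1])
    return float(grid.r[j] + frac * (grid.r[j + 1] - grid.r[j]))


def spherical_count(profile: np.ndarray, grid: RadialGrid,
                    r_lo: float = 0.0, r_hi: float | None = None,
                    negative_tol: float = 1.0) -> float:
    """Cell count 4*pi Int_{r_lo}^{r_hi} profile(r) r^2 dr.

    Quadrature rule: composite trapezoid on the grid applied to the
    integrand g(r) = profile(r)*r^2, i.e. g is taken linear between
    nodes.  Because g is interpolated linearly, splitting the range at an
    arbitrary radius and summing the pieces reproduces the whole exactly,
    so counts are additive over disjoint radial shells.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.min() < -negative_tol:
        raise ValueError(
            f"profile is negative beyond tolerance (min {profile.min():.3g})")
    r_hi = grid.r_max if r_hi is None else r_hi
    if r_lo > r_hi:
        raise ValueError("r_lo must not exceed r_hi")
    r_lo = max(r_lo, 0.0)
    r_hi = min(r_hi, grid.r_max)
    g = np.maximum(profile, 0.0) * grid.r**2
    # integral of the piecewise-linear interpolant of g over [r_lo, r_hi]
    def G(x: float) -> float:  # antiderivative at x
        full = np.concatenate(([0.0], np.cumsum(
            0.5 * (g[1:] + g[:-1]) * np.diff(grid.r))))
        j = int(np.clip(np.searchsorted(grid.r, x, side="right") - 1,
                        0, grid.n - 2))
        gj = np.interp(x, grid.r, g)
        return full[j] + 0.5 * (g[j] + gj) * (x - grid.r[j])

    return 4.0 * np.pi * (G(r_hi) - G(r_lo))


def composition(state: TumourState, grid: RadialGrid) -> PopulationCounts:
    """Per-phenotype spherical counts for one state."""
    return PopulationCounts(
        N_c=spherical_count(state.c, grid),
        N_h=spherical_count(state.h, grid),
        N_n=spherical_count(state.n, grid))
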