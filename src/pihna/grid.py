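"""Uniform radial grid for the spherically symmetric solver.

All lengths are millimetres.  The grid carries the finite-volume geometry
(cell volumes and interior face areas, both with the common factor 4*pi
dropped) used by the discrete spherical Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RadialGrid"]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform grid of radial nodes r_i = i*dr on [0, r_max].

    Nodes are cell centres of a finite-volume tessellation whose interior
    faces sit halfway between nodes; the innermost cell is the ball of
    radius dr/2 and the outermost cell is clipped at r_max (zero-flux
    boundaries at r=0 and r=r_max).
    """

    r: np.ndarray
    dr: float
    r_max: float
    # geometry caches (4*pi dropped everywhere)
    face_area: np.ndarray = field(init=False, repr=False)
    cell_volume: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or r.size < 3:
            raise ValueError("radial grid needs at least 3 nodes")
        if r[0] != 0.0:
            raise ValueError("radial grid must start at r = 0")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial coordinates must be strictly increasing")
        object.__setattr__(self, "r", r)
        r_face = 0.5 * (r[:-1] + r[1:])            # interior faces
        edges = np.concatenate(([0.0], r_face, [self.r_max]))
        object.__setattr__(self, "face_area", r_face**2)
        object.__setattr__(self, "cell_volume", np.diff(edges**3) / 3.0)

    @classmethod
    def uniform(cls, r_max: float = 100.0, dr: float = 0.25) -> "RadialGrid":
        """Build a uniform grid covering [0, r_max] with spacing dr (mm)."""
        if r_max <= 0 or dr <= 0:
            raise ValueError("r_max and dr must be positive")
        n = int(round(r_max / dr)) + 1
        r = np.linspace(0.0, r_max, n)
        return cls(r=r, dr=float(r[1] - r[0]), r_max=float(r_max))

    @property
    def n(self) -> int:
        return self.r.size

    def refine(self, factor: int = 2) -> "RadialGrid":
        """Grid with the spatial step divided by ``factor`` (same extent)."""
        return RadialGrid.uniform(self.r_max, self.dr / factor)
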