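"""Model and solver parameter containers.

Canonical internal units are millimetres and days.  The two kinetic rates
that define a virtual patient -- the net invasion rate ``D`` and the net
proliferation rate ``rho`` -- are stored in the units the glioma-kinetics
literature reports them in (mm^2/yr and 1/yr) and converted with
1 yr = 365 days; every other rate constant is stored directly in 1/day.

The PIHNA right-hand side reads *only* named fields of
:class:`PihnaParameters`, so alternative transcriptions of the model
constants are a matter of configuration, not code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["PihnaParameters", "SolverSettings", "DAYS_PER_YEAR", "per_year_to_per_day"]

DAYS_PER_YEAR = 365.0


def per_year_to_per_day(x: float) -> float:
    return x / DAYS_PER_YEAR


@dataclass(frozen=True)
class PihnaParameters:
    """Constants of the proliferation-invasion-hypoxia-necrosis-angiogenesis model.

    Parameters
    ----------
    D : float
        Net invasion rate of normoxic tumour cells, mm^2/yr.
    rho : float
        Net proliferation rate of normoxic tumour cells, 1/yr.
    K : float
        Malignant cell carrying capacity (maximum packing density),
        cells/mm^3.
    D_h, D_v : float or None
        Motility of hypoxic cells and of vasculature, mm^2/yr.  ``None``
        resolves to ``D`` (hypoxic cells migrate at the normoxic rate) and
        ``0.1 * D`` (endothelial sprouts advance an order slower than the
        tumour front) respectively.
    D_a : float
        Diffusivity of the angiogenic factor, mm^2/yr.
    hypoxia_rate : float
        Maximum normoxic->hypoxic conversion rate, 1/day.  The realised
        rate is gated by a logistic switch in the relative vascular
        density ``V = v/(c+h+v)``, fully on well below
        ``vascular_sufficiency_threshold`` and off well above it.
    reoxygenation_rate : float
        Maximum hypoxic->normoxic recovery rate, 1/day, gated by the
        complementary logistic switch (on above the sufficiency
        threshold).
    necrosis_rate : float
        Maximum hypoxic->necrotic death rate, 1/day; ramps linearly from
        0 at ``necrosis_threshold`` to the full rate at V = 0.
    vascular_sufficiency_threshold : float
        Relative vascular density at which the normoxic/hypoxic switch is
        centred: below it cells convert to the hypoxic phenotype, above
        it hypoxic cells recover.  Setting it to 0 disables the hypoxia
        pathway entirely: no cell ever becomes hypoxic.
    vascular_sufficiency_width : float
        Width of the logistic switch in V.  A finite width makes the
        hypoxic balance point respond to the conversion-rate multipliers
        of anti-angiogenic therapy (raising recovery and lowering
        conversion shifts the effective threshold downwards).
    necrosis_threshold : float
        Relative vascular density below which hypoxic cells begin dying;
        must not exceed the sufficiency threshold.  0 disables necrosis.
    vessel_growth_rate : float
        Maximum vessel proliferation rate, 1/day, saturating in the
        angiogenic factor with half-saturation ``a_halfsat``.
    a_halfsat : float
        Angiogenic-factor level at which vessel proliferation runs at half
        its maximum (the "action" threshold anti-angiogenic therapy
        raises), a-units.
    a_production_h, a_production_c : float
        Angiogenic-factor production rates, a-units/day, by a full-K
        density of hypoxic and normoxic cells respectively; hypoxic cells
        are the dominant source.
    a_decay : float
        First-order clearance of the angiogenic factor, 1/day.
    a_uptake_vessel : float
        Uptake of angiogenic factor by vasculature at full-K vessel
        density, 1/day.
    a_consumption_growth : float
        Angiogenic factor consumed per unit (relative) vessel growth,
        a-units.
    vessel_destabilization_rate : float
        Maximum vessel regression rate, 1/day.  Sustained high levels of
        angiogenic factor destabilise vasculature (immature, leaky
        vessels) with a cooperative (Hill-2) dependence of
        half-saturation ``a_destabilization_halfsat``; inside a dense
        tumour the hypoxia -> angiogenic factor -> vessel loss feedback
        collapses perfusion and drives necrosis, while the low factor
        levels at the invasive rim leave vasculature intact.
    a_destabilization_halfsat : float
        Angiogenic-factor level at which vessel destabilisation runs at
        half its maximum (the "action" threshold for vessel permeability
        that anti-angiogenic therapy raises), a-units.  Larger than
        ``a_halfsat``: destabilisation needs more factor than sprouting.
    vascular_fraction_normal : float
        Normal-tissue vascular density as a fraction of K (initial and
        far-field condition); about 5%, the cerebral blood-volume
        fraction of grey matter.
    """

    D: float
    rho: float
    K: float = 2.39e5
    D_h: float | None = None
    D_v: float | None = None
    D_a: float = 3139.0
    hypoxia_rate: float = 0.02
    reoxygenation_rate: float = 0.1
    necrosis_rate: float = 0.05
    vascular_sufficiency_threshold: float = 0.05
    vascular_sufficiency_width: float = 0.005
    necrosis_threshold: float = 0.03
    vessel_growth_rate: float = 0.1
    a_halfsat: float = 1.0
    a_production_h: float = 40.0
    a_production_c: float = 0.4
    a_decay: float = 2.0
    a_uptake_vessel: float = 1.0
    a_consumption_growth: float = 10.0
    vessel_destabilization_rate: float = 0.12
    a_destabilization_halfsat: float = 3.0
    vascular_fraction_normal: float = 0.05

    def __post_init__(self) -> None:
        for name in ("D", "rho", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if val is not None and val < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {val}")
        if not 0 <= self.vascular_fraction_normal < 1:
            raise ValueError("vascular_fraction_normal must lie in [0, 1)")
        if not 0 <= self.vascular_sufficiency_threshold < 1:
            raise ValueError("vascular_sufficiency_threshold must lie in [0, 1)")
        if self.necrosis_threshold > self.vascular_sufficiency_threshold:
            raise ValueError(
                "necrosis_threshold must not exceed the sufficiency threshold")

    # -- resolved motilities, converted to mm^2/day ------------------------
    @property
    def D_c_day(self) -> float:
        return self.D / DAYS_PER_YEAR

    @property
    def D_h_day(self) -> float:
        return (self.D if self.D_h is None else self.D_h) / DAYS_PER_YEAR

    @property
    def D_v_day(self) -> float:
        return (0.1 * self.D if self.D_v is None else self.D_v) / DAYS_PER_YEAR

    @property
    def D_a_day(self) -> float:
        return self.D_a / DAYS_PER_YEAR

    @property
    def rho_day(self) -> float:
        return self.rho / DAYS_PER_YEAR

    def replace(self, **changes) -> "PihnaParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs for the method-of-lines integration."""

    dr: float = 0.25                 # spatial step, mm
    r_max: float = 100.0             # domain extent, mm
    rtol: float = 1e-5
    atol_density: float = 1.0        # cells/mm^3 (~4e-6 of K)
    atol_a: float = 1e-6             # a-units
    max_step: float = float("inf")   # days
    event_tol: float = 0.1           # mm, radius-crossing acceptance
    max_horizon: float = 15000.0     # days, growth-to-size cutoff
    negative_tol: float = 1.0        # cells/mm^3, worst undershoot tolerated

    def __post_init__(self) -> None:
        for name in ("dr", "r_max", "rtol", "atol_density", "atol_a",
                     "event_tol", "max_horizon", "negative_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def make_grid(self):
        from .grid import RadialGrid

        return RadialGrid.uniform(self.r_max, self.dr)

    def replace(self, **changes) -> "SolverSettings":
        return dataclasses.replace(self, **changes)
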