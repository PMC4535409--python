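"""Therapy operators: anti-angiogenic normalization, resection, radiation.

Anti-angiogenic (AA) therapy is a *parameter* transformation -- the drug
neither kills cells nor changes state directly.  Gross total resection
(GTR) removes the T1Gd-visible core of the tumour.  Radiotherapy applies
linear-quadratic (LQ) cell kill in one instant for the whole fractionated
course, with the radiosensitivity alpha tied linearly to the tumour's net
proliferation rate and attenuated per grid node by an effective oxygen
enhancement ratio (OER).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .grid import RadialGrid
from .imaging import ImagingThresholds, radius_at_threshold, spherical_count
from .parameters import PihnaParameters
from .state import TumourState

__all__ = [
    "AAEffect", "RadiotherapyPlan", "TherapyPlan",
    "aa_transform_parameters", "gtr_resect", "alpha_from_rho",
    "effective_oer", "radiation_cell_kill", "RadiationOutcome",
]


@dataclass(frozen=True)
class AAEffect:
    """Bevacizumab-style vascular normalization, as parameter multipliers.

    ``angiogenic_action_factor`` (>= 1) scales every angiogenic-factor
    half-saturation constant: more factor is needed for the same vessel
    "action" (inhibited angiogenesis).  Normalized vessels are more
    efficient, so less vasculature is needed for normoxia: the h->c
    conversion rate is raised by ``h_to_c_multiplier`` and the c->h rate
    lowered by ``c_to_h_multiplier``.  All multipliers equal to 1 is the
    identity therapy.
    """

    angiogenic_action_factor: float = 100.0
    h_to_c_multiplier: float = 2.0
    c_to_h_multiplier: float = 0.5
    duration_days: float = 42.0

    def __post_init__(self) -> None:
        if self.angiogenic_action_factor < 1:
            raise ValueError("angiogenic_action_factor must be >= 1")
        if self.h_to_c_multiplier < 0 or self.c_to_h_multiplier < 0:
            raise ValueError("conversion multipliers must be nonnegative")
        if self.duration_days < 0:
            raise ValueError("duration_days must be nonnegative")

    @classmethod
    def identity(cls, duration_days: float = 42.0) -> "AAEffect":
        return cls(1.0, 1.0, 1.0, duration_days)


@dataclass(frozen=True)
class RadiotherapyPlan:
    """LQ radiotherapy course settings.

    ``alpha_slope`` (Gy^-1 per yr^-1) and ``alpha_intercept`` (Gy^-1) map
    the net proliferation rate rho to the radiosensitivity alpha; they
    have no defaults and must come from configuration.
    """

    alpha_slope: float
    alpha_intercept: float
    dose_per_fraction: float = 2.0     # Gy
    n_fractions: int = 30
    alpha_beta_ratio: float = 10.0     # Gy
    oer_max: float = 3.0

    def __post_init__(self) -> None:
        if self.dose_per_fraction < 0 or self.n_fractions < 0:
            raise ValueError("dose and fraction count must be nonnegative")
        if self.alpha_beta_ratio <= 0:
            raise ValueError("alpha_beta_ratio must be positive")
        if not 1.0 <= self.oer_max <= 3.0:
            raise ValueError("oer_max must lie in [1, 3]")

    @property
    def total_dose(self) -> float:
        return self.dose_per_fraction * self.n_fractions


@dataclass(frozen=True)
class TherapyPlan:
    """Schedule tying the operators together: AA window plus optional RT."""

    aa_start: float = 0.0              # days, absolute simulation time
    aa_effect: AAEffect | None = None
    radiotherapy: RadiotherapyPlan | None = None

    def aa_window(self, t: float) -> bool:
        if self.aa_effect is None:
            return False
        return self.aa_start <= t < self.aa_start + self.aa_effect.duration_days


def aa_transform_parameters(params: PihnaParameters,
                            effect: AAEffect) -> PihnaParameters:
    """Parameters in force during anti-angiogenic therapy.

    Scales every angiogenic-factor half-saturation ("action") constant --
    the one governing vessel proliferation and the one governing vessel
    destabilisation/permeability -- by the action factor, and adjusts the
    two phenotype conversion rates; every other constant is untouched.
    """
    return _dc_replace(
        params,
        a_halfsat=params.a_halfsat * effect.angiogenic_action_factor,
        a_destabilization_halfsat=(params.a_destabilization_halfsat
                                   * effect.angiogenic_action_factor),
        reoxygenation_rate=params.reoxygenation_rate * effect.h_to_c_multiplier,
        hypoxia_rate=params.hypoxia_rate * effect.c_to_h_multiplier)


def gtr_resect(state: TumourState, grid: RadialGrid,
               thresholds: ImagingThresholds | None = None,
               K: float | None = None) -> tuple[TumourState, float]:
    """Remove the T1Gd-visible tumour core (gross total resection).

    Tumour cell densities (c, h, n) are zeroed at every node with
    r <= T1Gd radius; vasculature and angiogenic factor are untouched, as
    is everything outside the resection radius.  When no node reaches the
    T1Gd threshold the state is returned unchanged with radius 0 (no-op).
    """
    thresholds = thresholds or ImagingThresholds()
    if K is None:
        raise ValueError("carrying capacity K is required to locate the T1Gd radius")
    r_t1gd = radius_at_threshold(state, grid, thresholds.t1gd_fraction, K)
    if r_t1gd == 0.0:
        return state, 0.0
    inside = grid.r <= r_t1gd
    post = TumourState(
        t=state.t,
        c=np.where(inside, 0.0, state.c),
        h=np.where(inside, 0.0, state.h),
        n=np.where(inside, 0.0, state.n),
        v=state.v.copy(), a=state.a.copy())
    return post, r_t1gd


def alpha_from_rho(rho: float, plan: RadiotherapyPlan) -> float:
    """Radiosensitivity alpha (Gy^-1) from the net proliferation rate (yr^-1).

    alpha = alpha_slope * rho + alpha_intercept; beta follows as
    alpha / alpha_beta_ratio.  Faster-proliferating tumours are more
    radiosensitive (the linear map also absorbs concurrent chemotherapy
    implicitly).
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    alpha = plan.alpha_slope * rho + plan.alpha_intercept
    if alpha <= 0:
        raise ValueError(
            f"alpha = {alpha:.4g} Gy^-1 is nonphysical; check the alpha-rho "
            "coefficients")
    return alpha


def effective_oer(c_i: float | np.ndarray, h_i: float | np.ndarray,
                  plan: RadiotherapyPlan) -> float | np.ndarray:
    """Hypoxia-weighted effective oxygen enhancement ratio per location.

    OER_e = (1*c + oer_max*h)/(c + h): 1 in purely normoxic tissue,
    oer_max in purely hypoxic tissue.  Only viable compartments carry
    weight; locations with no viable cells return 1 (nothing to kill, so
    the value is inert).
    """
    c_i = np.asarray(c_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    if np.any(c_i < 0) or np.any(h_i < 0):
        raise ValueError("cell counts must be nonnegative")
    viable = c_i + h_i
    oer = np.where(viable > 0,
                   (c_i + plan.oer_max * h_i) / np.where(viable > 0, viable, 1.0),
                   1.0)
    return float(oer) if oer.ndim == 0 else oer


@dataclass(frozen=True)
class RadiationOutcome:
    cells_killed: float
    kill_fraction: float        # F_CK over the whole tumour
    post_state: TumourState
    survival: np.ndarray        # per-node LQ survival factor


def radiation_cell_kill(state: TumourState, grid: RadialGrid, rho: float,
                        plan: RadiotherapyPlan) -> RadiationOutcome:
    """Apply the full fractionated LQ course at a single instant.

    Per node i the surviving fraction is
    S_i = exp(-n (alpha d + beta d^2) / OER_e,i) with alpha from the
    alpha-rho map and beta = alpha/(alpha/beta ratio); whole-brain
    irradiation, so every node is dosed.  Viable compartments c and h are
    scaled by S_i; necrotic cells are already dead and are untouched.
    """
    alpha = alpha_from_rho(rho, plan)
    beta = alpha / plan.alpha_beta_ratio
    d, n_fr = plan.dose_per_fraction, plan.n_fractions
    oer = effective_oer(state.c, state.h, plan)
    lq_exponent = n_fr * (alpha * d + beta * d * d) / oer
    survival = np.exp(-lq_exponent)
    post = TumourState(t=state.t, c=state.c * survival, h=state.h * survival,
                       n=state.n.copy(), v=state.v.copy(), a=state.a.copy())
    killed_density = state.viable_density * (1.0 - survival)
    cells_killed = spherical_count(killed_density, grid)
    total_viable = spherical_count(state.viable_density, grid)
    frac = cells_killed / total_viable if total_viable > 0 else 0.0
    return RadiationOutcome(cells_killed=cells_killed, kill_fraction=frac,
                            post_state=post, survival=survival)
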