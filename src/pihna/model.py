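"""PIHNA right-hand side and time integration in spherical symmetry.

The model tracks normoxic (c), hypoxic (h) and necrotic (n) tumour cells,
vasculature (v) and a generic angiogenic factor (a) on a radial grid.
Writing T = (c+h+n+v)/K for the total tissue fraction and
V = v/(c+h+v) for the relative vascular density (the nutrient-sufficiency
signal), the equations integrated here are

    dc/dt = div(D_c (1-T) grad c) + rho c (1-T) - beta g_ch(V) c + gamma g_hc(V) h
    dh/dt = div(D_h (1-T) grad h) + beta g_ch(V) c - gamma g_hc(V) h
            - alpha_n g_hn(V) h
    dn/dt = alpha_n g_hn(V) h
    dv/dt = div(D_v (1-T) grad v) + mu a/(a+a_m) v (1-T)
            - eta a^2/(a^2+a_d^2) v
    da/dt = div(D_a grad a) + xi_h h/K + xi_c c/K - lambda a
            - omega (v/K) a - q mu a/(a+a_m) (v/K) (1-T)

where the conversion gates switch across the vascular-sufficiency
thresholds: g_ch(V) = 1/(1 + exp((V - V_ch)/w)) turns on hypoxic
conversion below the sufficiency threshold V_ch, its complement
g_hc(V) = 1/(1 + exp(-(V - V_ch)/w)) turns on recovery above it (w =
vascular_sufficiency_width), and g_hn(V) = clip((V_hn - V)/V_hn, 0, 1)
ramps necrosis in below the (lower) necrosis threshold V_hn.  The
logistic pair makes the oxygenation balance point a smooth function of
vascular density, so rescaling the two conversion rates (anti-angiogenic
therapy) shifts the effective sufficiency threshold rather than merely
rescaling fluxes.  beta = hypoxia_rate, gamma = reoxygenation_rate,
alpha_n = necrosis_rate, mu = vessel_growth_rate, a_m = a_halfsat and so
on (see :class:`~pihna.parameters.PihnaParameters`).  Normoxic cells invade and
divide; hypoxic cells only move; necrosis is the terminal fate of hypoxia.
Hypoxic cells drive angiogenesis, which restores V and re-oxygenates
tissue where there is room to grow.  The phenotype conversions appear
pairwise with opposite signs, so the logistic term in the c equation is
the only net source of tumour cells.

Diffusion is discretised in flux form with the symmetric spherical
Laplacian (finite volumes, zero flux at r=0 and r=r_max), and the
resulting ODE system is integrated with LSODA using its banded Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .grid import RadialGrid
from .parameters import PihnaParameters, SolverSettings
from .state import FIELD_NAMES, TumourState

__all__ = [
    "FieldDerivatives", "Trajectory", "GrowthTimeoutError",
    "pihna_rhs", "reaction_terms", "simulate", "simulate_with_plan",
    "run_until_t2_radius", "apply_parameter_schedule",
]

_NF = len(FIELD_NAMES)
# widest Jacobian band: a density at node i couples to v (or n) at node i+1
# through the shared crowding factor -> offset 5*1 + 3 = 8
_JAC_BAND = 8

# Tiny density regularising V = v/(c+h+v) where no cells or vessels exist.
_EPS_DENS = 1e-12


class FieldDerivatives(NamedTuple):
    dc: np.ndarray
    dh: np.ndarray
    dn: np.ndarray
    dv: np.ndarray
    da: np.ndarray


class GrowthTimeoutError(RuntimeError):
    """Raised when a tumour fails to reach a target size within the horizon."""


def _switch_hypoxia(V: np.ndarray, threshold: float, width: float) -> np.ndarray:
    """Logistic gate, on below the sufficiency threshold; 0 if disabled."""
    if threshold <= 0.0:
        return np.zeros_like(V)
    z = np.clip((V - threshold) / width, -50.0, 50.0)
    return 1.0 / (1.0 + np.exp(z))


def _switch_recovery(V: np.ndarray, threshold: float, width: float) -> np.ndarray:
    """Complementary logistic gate, on above the sufficiency threshold."""
    if threshold <= 0.0:
        return np.ones_like(V)
    z = np.clip((V - threshold) / width, -50.0, 50.0)
    return 1.0 / (1.0 + np.exp(-z))


def _ramp_necrosis(V: np.ndarray, threshold: float) -> np.ndarray:
    """Linear ramp from 1 at V=0 to 0 at the necrosis threshold."""
    if threshold <= 0.0:
        return np.zeros_like(V)
    return np.clip((threshold - V) / threshold, 0.0, 1.0)


def _make_rhs(params: PihnaParameters, grid: RadialGrid) -> Callable:
    """Vectorised RHS closure over flat state vectors (fields interleaved)."""
    K = params.K
    dr = grid.dr
    area = grid.face_area
    vol = grid.cell_volume
    Dc, Dh, Dv, Da = (params.D_c_day, params.D_h_day,
                      params.D_v_day, params.D_a_day)
    rho = params.rho_day
    beta = params.hypoxia_rate
    gamma = params.reoxygenation_rate
    alpha_n = params.necrosis_rate
    mu = params.vessel_growth_rate
    a_m = params.a_halfsat
    xi_h, xi_c = params.a_production_h, params.a_production_c
    lam = params.a_decay
    omega = params.a_uptake_vessel
    q = params.a_consumption_growth
    eta = params.vessel_destabilization_rate
    a_d = params.a_destabilization_halfsat
    V_ch = params.vascular_sufficiency_threshold
    w_ch = params.vascular_sufficiency_width
    V_hn = params.necrosis_threshold

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        Y = y.reshape(-1, _NF)
        c, h, n, v, a = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3], Y[:, 4]
        room = 1.0 - (c + h + n + v) / K
        V = v / (c + h + v + _EPS_DENS)
        # free room at faces: the *smaller* of the two neighbours, so no
        # flux ever pushes cells into an already-full cell
        room_face = np.maximum(np.minimum(room[:-1], room[1:]), 0.0)

        out = np.empty_like(Y)

        def _div(u: np.ndarray, D: float, face_factor: np.ndarray, into: np.ndarray) -> None:
            flux = (D / dr) * face_factor * np.diff(u) * area
            into[0] = flux[0] / vol[0]
            into[1:-1] = np.diff(flux) / vol[1:-1]
            into[-1] = -flux[-1] / vol[-1]

        hyp = beta * _switch_hypoxia(V, V_ch, w_ch)
        reox = gamma * _switch_recovery(V, V_ch, w_ch)
        nec = alpha_n * _ramp_necrosis(V, V_hn)
        sat = a / (a + a_m)
        vgrow = mu * sat * v * room

        _div(c, Dc, room_face, out[:, 0])
        out[:, 0] += rho * c * room - hyp * c + reox * h
        _div(h, Dh, room_face, out[:, 1])
        out[:, 1] += hyp * c - (reox + nec) * h
        out[:, 2] = nec * h
        _div(v, Dv, room_face, out[:, 3])
        out[:, 3] += vgrow - eta * (a * a / (a * a + a_d * a_d)) * v
        _div(a, Da, 1.0, out[:, 4])
        out[:, 4] += (xi_h * h + xi_c * c - omega * v * a - q * vgrow) / K - lam * a
        return out.ravel()

    return rhs


def pihna_rhs(state: TumourState, params: PihnaParameters,
              grid: RadialGrid) -> FieldDerivatives:
    """Evaluate the time derivative of all five fields at one state."""
    state.validate(grid)
    dy = _make_rhs(params, grid)(state.t, state.to_vector())
    Y = dy.reshape(-1, _NF)
    return FieldDerivatives(*(Y[:, i].copy() for i in range(_NF)))


def reaction_terms(state: TumourState, params: PihnaParameters) -> dict[str, np.ndarray]:
    """Named local reaction terms (no transport), for bookkeeping checks.

    Conversion fluxes are reported once each; they enter the two affected
    equations with opposite signs.
    """
    c, h, v, a = state.c, state.h, state.v, state.a
    T = (c + h + state.n + v) / params.K
    V = v / (c + h + v + _EPS_DENS)
    room = 1.0 - T
    vgrow = (params.vessel_growth_rate * a / (a + params.a_halfsat) * v * room)
    return {
        "proliferation_c": params.rho_day * c * room,
        "c_to_h": (params.hypoxia_rate
                   * _switch_hypoxia(V, params.vascular_sufficiency_threshold,
                                     params.vascular_sufficiency_width) * c),
        "h_to_c": (params.reoxygenation_rate
                   * _switch_recovery(V, params.vascular_sufficiency_threshold,
                                      params.vascular_sufficiency_width) * h),
        "h_to_n": (params.necrosis_rate
                   * _ramp_necrosis(V, params.necrosis_threshold) * h),
        "vessel_growth": vgrow,
        "vessel_destabilization": (
            params.vessel_destabilization_rate
            * (a**2 / (a**2 + params.a_destabilization_halfsat**2)) * v),
        "a_production": (params.a_production_h * h + params.a_production_c * c) / params.K,
        "a_decay": params.a_decay * a,
        "a_uptake": (params.a_uptake_vessel * v * a
                     + params.a_consumption_growth * vgrow) / params.K,
    }


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed sequence of tumour states on one grid."""

    times: np.ndarray
    states: tuple[TumourState, ...]
    grid: RadialGrid

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> TumourState:
        return self.states[i]

    @property
    def final(self) -> TumourState:
        return self.states[-1]


def _postprocess(t: float, y: np.ndarray, grid: RadialGrid,
                 settings: SolverSettings, K: float) -> TumourState:
    worst = y.min()
    if worst < -settings.negative_tol:
        raise RuntimeError(
            f"negative density {worst:.3g} beyond tolerance at t={t:.2f} d")
    state = TumourState.from_vector(t, np.maximum(y, 0.0))
    state.validate(grid, K=K)
    return state


def _atol_vector(grid: RadialGrid, settings: SolverSettings) -> np.ndarray:
    per_node = np.array([settings.atol_density] * 4 + [settings.atol_a])
    return np.tile(per_node, grid.n)


def simulate(state0: TumourState, params: PihnaParameters, grid: RadialGrid,
             t_span: float, settings: SolverSettings | None = None,
             t_eval: Sequence[float] | None = None) -> Trajectory:
    """Integrate the model forward by ``t_span`` days from ``state0``.

    ``t_eval`` requests output times (offsets from ``state0.t``); by
    default only the initial and final states are returned.
    """
    settings = settings or SolverSettings()
    if t_span < 0:
        raise ValueError("t_span must be nonnegative")
    state0.validate(grid)
    if t_span == 0:
        return Trajectory(np.array([state0.t]), (state0,), grid)
    t0 = state0.t
    offsets = (np.asarray(t_eval, dtype=float) if t_eval is not None
               else np.array([0.0, t_span]))
    sol = solve_ivp(
        _make_rhs(params, grid), (t0, t0 + t_span), state0.to_vector(),
        method="LSODA", t_eval=t0 + offsets, rtol=settings.rtol,
        atol=_atol_vector(grid, settings), max_step=settings.max_step,
        lband=_JAC_BAND, uband=_JAC_BAND)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.2f} d: {sol.message}")
    states = tuple(_postprocess(t, sol.y[:, i], grid, settings, params.K)
                   for i, t in enumerate(sol.t))
    return Trajectory(sol.t.copy(), states, grid)


def run_until_t2_radius(params: PihnaParameters, grid: RadialGrid,
                        settings: SolverSettings | None = None,
                        target_radius: float = 1.5,
                        state0: TumourState | None = None,
                        t2_fraction: float = 0.16) -> tuple[TumourState, float]:
    """Grow a tumour until its T2 imaging radius reaches ``target_radius`` (cm).

    Starts from a localised normoxic seed unless ``state0`` is given.
    Returns the event-detected state at the crossing and the crossing time
    in days (time elapsed since ``state0.t``).  Raises
    :class:`GrowthTimeoutError` if the target is not reached within
    ``settings.max_horizon`` days.
    """
    from .imaging import radius_at_threshold

    settings = settings or SolverSettings()
    target_mm = target_radius * 10.0
    if target_mm >= grid.r_max:
        raise ValueError("target radius must lie inside the grid")
    if state0 is None:
        state0 = TumourState.seed(grid, params)
    state0.validate(grid)
    threshold = t2_fraction * params.K

    if radius_at_threshold(state0, grid, t2_fraction, params.K) >= target_mm:
        return state0, 0.0

    def crossing(t: float, y: np.ndarray) -> float:
        total = y.reshape(-1, _NF)[:, :3].sum(axis=1)
        above = np.flatnonzero(total >= threshold)
        if above.size == 0:
            return -target_mm
        j = above[-1]
        if j == grid.n - 1:
            r = grid.r_max
        else:
            frac = (total[j] - threshold) / (total[j] - total[j + 1])
            r = grid.r[j] + frac * grid.dr
        return r - target_mm

    crossing.terminal = True
    crossing.direction = 1.0

    t0 = state0.t
    sol = solve_ivp(
        _make_rhs(params, grid), (t0, t0 + settings.max_horizon),
        state0.to_vector(), method="LSODA", events=crossing,
        rtol=settings.rtol, atol=_atol_vector(grid, settings),
        max_step=settings.max_step, lband=_JAC_BAND, uband=_JAC_BAND)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    if sol.t_events[0].size == 0:
        raise GrowthTimeoutError(
            f"T2 radius {target_radius} cm not reached within "
            f"{settings.max_horizon:.0f} simulated days")
    t_cross = float(sol.t_events[0][0])
    state = _postprocess(t_cross, sol.y_events[0][0], grid, settings, params.K)
    achieved = radius_at_threshold(state, grid, t2_fraction, params.K)
    if abs(achieved - target_mm) > settings.event_tol:
        raise RuntimeError(
            f"event detection missed the target radius by "
            f"{abs(achieved - target_mm):.3g} mm")
    return state, t_cross - t0


def apply_parameter_schedule(params: PihnaParameters, plan, t: float) -> PihnaParameters:
    """Parameters in force at absolute time ``t`` under a therapy plan.

    Inside the anti-angiogenic window the transformation of
    :func:`pihna.therapy.aa_transform_parameters` applies; outside it the
    parameters are returned untouched.
    """
    from .therapy import aa_transform_parameters

    if plan.aa_effect is not None and plan.aa_window(t):
        return aa_transform_parameters(params, plan.aa_effect)
    return params


def simulate_with_plan(state0: TumourState, params: PihnaParameters,
                       grid: RadialGrid, plan, t_span: float,
                       settings: SolverSettings | None = None,
                       t_eval: Sequence[float] | None = None) -> Trajectory:
    """Integrate across the AA window, switching parameter sets at its edges."""
    settings = settings or SolverSettings()
    t0, t_end = state0.t, state0.t + t_span
    cuts = [t0, t_end]
    if plan.aa_effect is not None:
        for edge in (plan.aa_start, plan.aa_start + plan.aa_effect.duration_days):
            if t0 < edge < t_end:
                cuts.append(edge)
    cuts = sorted(set(cuts))
    offsets = (np.asarray(t_eval, dtype=float) + t0 if t_eval is not None
               else np.asarray(cuts))

    times: list[float] = []
    states: list[TumourState] = []
    current = state0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        seg_params = apply_parameter_schedule(params, plan, 0.5 * (lo + hi))
        seg_eval = offsets[(offsets >= lo) & (offsets <= hi)] - lo
        seg_eval = np.unique(np.concatenate([seg_eval, [hi - lo]]))
        traj = simulate(current, seg_params, grid, hi - lo, settings,
                        t_eval=seg_eval)
        for t, s in zip(traj.times, traj.states):
            if not times or t > times[-1] + 1e-9:
                times.append(float(t))
                states.append(s)
        current = traj.final
    keep = [i for i, t in enumerate(times)
            if np.any(np.isclose(t, offsets, atol=1e-9)) or i == len(times) - 1]
    return Trajectory(np.array([times[i] for i in keep]),
                      tuple(states[i] for i in keep), grid)
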