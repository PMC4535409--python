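"""Drivers for the virtual combination-therapy experiments.

Each experiment grows virtual patients (defined by their net invasion and
proliferation rates) to an imaging-defined treatment-start size, applies
therapy operators, and reduces the outcome to per-patient response
metrics:

* experiment 0 -- tumour composition time-series for one patient, with a
  treated (anti-angiogenic, AA) and an untreated arm;
* experiment 1 -- R1, the drop in hypoxic cell count from just before AA
  therapy to 14 days into it;
* experiment 2 -- R2, the hypoxic cell count of the untreated virtual
  control minus that of the treated tumour at the same time point;
* experiment 3 -- radiation cell kill (LQ with OER weighting) after 14
  days of AA therapy vs after 14 untreated days, and their difference;
* experiment 4 -- the percentage of the hypoxic burden removed by gross
  total resection at the start size.

Per-patient failures (growth timeouts for near-degenerate kinetics) are
recorded in a ``status`` column instead of aborting a sweep.  Everything
is deterministic: rerunning an experiment reproduces every table cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortGrid
from .grid import RadialGrid
from .imaging import ImagingThresholds, composition, radius_at_threshold, spherical_count
from .model import (GrowthTimeoutError, run_until_t2_radius, simulate,
                    simulate_with_plan)
from .parameters import PihnaParameters, SolverSettings
from .state import TumourState
from .therapy import AAEffect, RadiotherapyPlan, TherapyPlan, radiation_cell_kill

__all__ = [
    "ResponseMetrics", "experiment0_composition", "experiment1_R1",
    "experiment2_R2", "experiment3_combination", "experiment4_gtr",
    "min_measurable_hypoxic_burden",
]

log = logging.getLogger(__name__)

#: days from the start of AA therapy to the response-evaluation point
EVALUATION_OFFSET = 14.0


@dataclass(frozen=True)
class ResponseMetrics:
    """Per-patient response summary across the experiments.

    R1 and R2 are hypoxic-cell-count differences (cells), delta_cell_kill
    the extra radiation kill from 14 days of AA therapy (cells), and
    gtr_removal_pct the percentage of the hypoxic burden inside the
    resected T1Gd ball.
    """

    R1: float
    R2: float
    delta_cell_kill: float
    gtr_removal_pct: float

    def __post_init__(self) -> None:
        if np.isfinite(self.gtr_removal_pct) and not (
                0.0 <= self.gtr_removal_pct <= 100.0):
            raise ValueError("gtr_removal_pct must lie in [0, 100]")


def min_measurable_hypoxic_burden(params: PihnaParameters) -> float:
    """Smallest hypoxic burden treated as real: 1 mm^3 at carrying capacity.

    Burdens below the cell count of a single cubic millimetre of packed
    tumour are far below imaging detectability; removal percentages
    computed from them would be quotients of numerical noise.
    """
    return params.K * 1.0


def _params_for(base: PihnaParameters, D: float, rho: float) -> PihnaParameters:
    return base.replace(D=D, rho=rho)


def _composition_row(state: TumourState, grid: RadialGrid, K: float,
                     thresholds: ImagingThresholds) -> dict:
    pc = composition(state, grid)
    return {
        "t": state.t,
        "N_c": pc.N_c, "N_h": pc.N_h, "N_n": pc.N_n, "N_total": pc.N_total,
        "f_c": pc.f_c, "f_h": pc.f_h, "f_n": pc.f_n,
        "r_t1gd": radius_at_threshold(state, grid, thresholds.t1gd_fraction, K),
        "r_t2": radius_at_threshold(state, grid, thresholds.t2_fraction, K),
    }


def experiment0_composition(D: float, rho: float,
                            start_sizes_cm=(1.5, 2.5, 3.5),
                            aa_effect: AAEffect | None = None,
                            base_params: PihnaParameters | None = None,
                            settings: SolverSettings | None = None,
                            thresholds: ImagingThresholds | None = None,
                            follow_up_days: float = 28.0,
                            sample_every: float = 2.0) -> pd.DataFrame:
    """Composition time-series for one patient, treated and untreated arms.

    For each start size the tumour is grown to the size, then both arms
    are integrated through the AA course plus ``follow_up_days``; counts
    and imaging radii are sampled every ``sample_every`` days.
    """
    aa_effect = aa_effect or AAEffect()
    settings = settings or SolverSettings()
    thresholds = thresholds or ImagingThresholds()
    params = _params_for(base_params or PihnaParameters(D=D, rho=rho), D, rho)
    grid = settings.make_grid()

    horizon = aa_effect.duration_days + follow_up_days
    offsets = np.unique(np.concatenate([
        np.arange(0.0, horizon + 1e-9, sample_every),
        [EVALUATION_OFFSET, aa_effect.duration_days, horizon]]))
    rows = []
    for size in start_sizes_cm:
        state_t1, t1 = run_until_t2_radius(
            params, grid, settings, size, t2_fraction=thresholds.t2_fraction)
        plan = TherapyPlan(aa_start=state_t1.t, aa_effect=aa_effect)
        arms = {
            "treated": simulate_with_plan(state_t1, params, grid, plan,
                                          horizon, settings, t_eval=offsets),
            "untreated": simulate(state_t1, params, grid, horizon, settings,
                                  t_eval=offsets),
        }
        for arm, traj in arms.items():
            for st in traj.states:
                row = _composition_row(st, grid, params.K, thresholds)
                row.update(start_size_cm=size, arm=arm, t1_days=t1,
                           days_from_t1=st.t - state_t1.t)
                rows.append(row)
    return pd.DataFrame(rows)


def _sweep(cohort: CohortGrid, start_sizes_cm, worker, columns) -> pd.DataFrame:
    """Run ``worker`` per (start size, patient), catching per-patient failures."""
    rows = []
    for size in start_sizes_cm:
        for patient in cohort.patients():
            base = {"patient_id": patient.patient_id, "start_size_cm": size,
                    "D": patient.D, "rho": patient.rho}
            try:
                base.update(worker(patient.D, patient.rho, size))
                base["status"] = base.get("status", "ok")
            except (GrowthTimeoutError, RuntimeError, ValueError) as exc:
                log.warning("patient %s at %.1f cm failed: %s",
                            patient.patient_id, size, exc)
                base.update({c: np.nan for c in columns})
                base["status"] = f"failed: {exc}"
            rows.append(base)
    ordered = ["patient_id", "start_size_cm", "D", "rho", *columns, "status"]
    return pd.DataFrame(rows)[ordered]


def _grow_and_fork(params: PihnaParameters, grid: RadialGrid,
                   settings: SolverSettings, size_cm: float,
                   aa_effect: AAEffect, thresholds: ImagingThresholds,
                   want_control: bool):
    """Grow to size, then run treated (and optionally control) arms 14 days."""
    state_t1, t1 = run_until_t2_radius(
        params, grid, settings, size_cm, t2_fraction=thresholds.t2_fraction)
    plan = TherapyPlan(aa_start=state_t1.t, aa_effect=aa_effect)
    treated = simulate_with_plan(state_t1, params, grid, plan,
                                 EVALUATION_OFFSET, settings).final
    control = (simulate(state_t1, params, grid, EVALUATION_OFFSET,
                        settings).final if want_control else None)
    return state_t1, t1, treated, control


def experiment1_R1(cohort: CohortGrid,
                   aa_effect: AAEffect | None = None,
                   base_params: PihnaParameters | None = None,
                   settings: SolverSettings | None = None,
                   thresholds: ImagingThresholds | None = None,
                   start_sizes_cm=None) -> pd.DataFrame:
    """R1 sweep: hypoxic count just before AA therapy minus 14 days into it.

    Negative R1 means the tumour carries *more* hypoxia two weeks into
    therapy than before it started (hypoxia still accumulating).
    """
    aa_effect = aa_effect or AAEffect()
    settings = settings or SolverSettings()
    thresholds = thresholds or ImagingThresholds()
    grid = settings.make_grid()
    sizes = start_sizes_cm or cohort.start_sizes_cm

    def worker(D, rho, size):
        params = _params_for(base_params or PihnaParameters(D=D, rho=rho), D, rho)
        state_t1, t1, treated, _ = _grow_and_fork(
            params, grid, settings, size, aa_effect, thresholds, False)
        H1 = spherical_count(state_t1.h, grid)
        H2 = spherical_count(treated.h, grid)
        return {"t1_days": t1, "H_t1": H1, "H_treated_t2": H2, "R1": H1 - H2}

    return _sweep(cohort, sizes, worker, ["t1_days", "H_t1", "H_treated_t2", "R1"])


def experiment2_R2(cohort: CohortGrid,
                   aa_effect: AAEffect | None = None,
                   base_params: PihnaParameters | None = None,
                   settings: SolverSettings | None = None,
                   thresholds: ImagingThresholds | None = None,
                   start_sizes_cm=None) -> pd.DataFrame:
    """R2 sweep: untreated virtual control vs treated hypoxic count at 14 days.

    Both arms fork from the identical state at t1, so R2 isolates the
    therapy effect from growth.
    """
    aa_effect = aa_effect or AAEffect()
    settings = settings or SolverSettings()
    thresholds = thresholds or ImagingThresholds()
    grid = settings.make_grid()
    sizes = start_sizes_cm or cohort.start_sizes_cm

    def worker(D, rho, size):
        params = _params_for(base_params or PihnaParameters(D=D, rho=rho), D, rho)
        state_t1, t1, treated, control = _grow_and_fork(
            params, grid, settings, size, aa_effect, thresholds, True)
        Ht = spherical_count(treated.h, grid)
        Hu = spherical_count(control.h, grid)
        return {"t1_days": t1, "H_treated_t2": Ht, "H_control_t2": Hu,
                "R2": Hu - Ht}

    return _sweep(cohort, sizes, worker,
                  ["t1_days", "H_treated_t2", "H_control_t2", "R2"])


def experiment3_combination(cohort: CohortGrid,
                            rt_plan: RadiotherapyPlan,
                            aa_effect: AAEffect | None = None,
                            base_params: PihnaParameters | None = None,
                            settings: SolverSettings | None = None,
                            thresholds: ImagingThresholds | None = None,
                            start_sizes_cm=None) -> pd.DataFrame:
    """Radiation kill with vs without a preceding 14-day AA course.

    The treated arm is irradiated at the 14-day state with AA still in
    force (only the instantaneous composition matters for the kill); the
    control arm is irradiated after 14 untreated days.
    """
    if rt_plan is None:
        raise ValueError("a RadiotherapyPlan with alpha coefficients is required")
    aa_effect = aa_effect or AAEffect()
    settings = settings or SolverSettings()
    thresholds = thresholds or ImagingThresholds()
    grid = settings.make_grid()
    sizes = start_sizes_cm or cohort.start_sizes_cm

    def worker(D, rho, size):
        params = _params_for(base_params or PihnaParameters(D=D, rho=rho), D, rho)
        state_t1, t1, treated, control = _grow_and_fork(
            params, grid, settings, size, aa_effect, thresholds, True)
        kill_aa = radiation_cell_kill(treated, grid, rho, rt_plan)
        kill_ctl = radiation_cell_kill(control, grid, rho, rt_plan)
        return {"t1_days": t1,
                "kill_with_AA": kill_aa.cells_killed,
                "kill_without_AA": kill_ctl.cells_killed,
                "F_CK_with_AA": kill_aa.kill_fraction,
                "F_CK_without_AA": kill_ctl.kill_fraction,
                "delta_cell_kill": kill_aa.cells_killed - kill_ctl.cells_killed}

    return _sweep(cohort, sizes, worker,
                  ["t1_days", "kill_with_AA", "kill_without_AA",
                   "F_CK_with_AA", "F_CK_without_AA", "delta_cell_kill"])


def experiment4_gtr(cohort: CohortGrid,
                    base_params: PihnaParameters | None = None,
                    settings: SolverSettings | None = None,
                    thresholds: ImagingThresholds | None = None,
                    start_sizes_cm=None,
                    min_hypoxic_burden: float | None = None) -> pd.DataFrame:
    """Hypoxic burden removed by gross total resection at each start size.

    Rows whose pre-resection hypoxic burden falls below
    ``min_hypoxic_burden`` (default: the count of 1 mm^3 of packed
    tumour, see :func:`min_measurable_hypoxic_burden`) carry NaN removal
    and status ``no measurable hypoxia``: there is no burden to remove.
    """
    from .therapy import gtr_resect

    settings = settings or SolverSettings()
    thresholds = thresholds or ImagingThresholds()
    grid = settings.make_grid()
    sizes = start_sizes_cm or cohort.start_sizes_cm

    def worker(D, rho, size):
        params = _params_for(base_params or PihnaParameters(D=D, rho=rho), D, rho)
        floor = (min_hypoxic_burden if min_hypoxic_burden is not None
                 else min_measurable_hypoxic_burden(params))
        state_t1, t1 = run_until_t2_radius(
            params, grid, settings, size, t2_fraction=thresholds.t2_fraction)
        post, r_resect = gtr_resect(state_t1, grid, thresholds, K=params.K)
        H_pre = spherical_count(state_t1.h, grid)
        H_post = spherical_count(post.h, grid)
        out = {"t1_days": t1, "resection_radius_mm": r_resect,
               "H_pre": H_pre, "H_post": H_post}
        if H_pre < floor:
            out.update(gtr_removal_pct=np.nan,
                       status="no measurable hypoxia")
        else:
            out["gtr_removal_pct"] = 100.0 * (H_pre - H_post) / H_pre
        return out

    return _sweep(cohort, sizes, worker,
                  ["t1_days", "resection_radius_mm", "H_pre", "H_post",
                   "gtr_removal_pct"])
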