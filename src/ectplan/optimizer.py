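"""Electrode-position and voltage optimization.

The planning objective is to cover the whole tumor and its safety margin
with fields at or above the reversible electroporation threshold, while not
ablating (irreversibly electroporating) normal tissue beyond the margin and
respecting the device limits.  The score of an admissible plan is

    w1 * tumor_coverage(e_rev)
  + w2 * margin_coverage(e_rev)
  - w3 * overreach,

where overreach is the fraction of normal tissue outside the margin exposed
above the irreversible threshold, and the default weights are (1, 0.5, 0.5).

The search is a transparent coarse-to-fine procedure rather than a bespoke
heuristic: (1) seeded random/grid search over the array center (and
optionally the insertion direction) around the tumor centroid, evaluated on
a coarsened grid; (2) coordinate descent on the insertion depth and the
distinct voltage levels in fixed steps; the best plan is finally re-scored
at full resolution.  With a fixed seed and configuration the search is
bit-reproducible, and the best-so-far score along the trace is
nondecreasing by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ectplan.phantom import (
    BACKGROUND,
    TUMOR,
    TissueProperties,
    VoxelPhantom,
    default_tissue_table,
    safety_margin,
)
from ectplan.electrodes import (
    ElectrodeArray,
    PulseSchedule,
    check_collisions,
    rasterize,
    star_array,
    star_schedule,
)
from ectplan.solver import SolverConfig, solve_schedule
from ectplan.coverage import coverage_fraction, cumulative_field
from ectplan.plan import TreatmentPlan


class InadmissiblePlanError(ValueError):
    """Plan violates anatomical or device constraints."""


class InfeasibleProblemError(RuntimeError):
    """No admissible candidate found within the search budget."""


@dataclass
class OptimizationProblem:
    """What to optimize over, and under which constraints.

    Either a ``template_array``/``base_schedule`` pair is given (free
    placement: the geometry is fixed or only shifted, voltages are
    optimized), or a star array is parameterized by ``center`` /
    ``insertion_direction`` and built on the fly.
    """

    phantom: VoxelPhantom
    tissue_table: dict[int, TissueProperties] = field(default_factory=default_tissue_table)
    template_array: ElectrodeArray | None = None
    base_schedule: PulseSchedule | None = None
    center: tuple[float, float, float] | None = None  # default: tumor centroid
    insertion_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center_to_outer: float = 10.0
    active_tip: float = 30.0
    electrode_radius: float = 0.6
    margin_width_mm: float = 5.0
    weights: tuple[float, float, float] = (1.0, 0.5, 0.5)
    current_cap_a: float = 50.0
    voltage_bounds: tuple[float, float] = (500.0, 1500.0)

    def tumor_centroid(self) -> np.ndarray:
        mask = self.phantom.tumor_mask
        if not mask.any():
            raise ValueError("phantom has no tumor")
        idx = np.argwhere(mask).mean(axis=0)
        return self.phantom.origin + (idx + 0.5) * self.phantom.spacing


@dataclass
class StrategyConfig:
    """Search budgets and step sizes."""

    n_center_candidates: int = 8
    center_radius_mm: float = 5.0
    depth_step_mm: float = 5.0
    depth_range_mm: float = 5.0
    voltage_step: float = 50.0
    voltage_grid: tuple[float, ...] | None = None  # exhaustive grid per level
    descent_rounds: int = 3
    coarsen: int = 2
    solver_config: SolverConfig = field(default_factory=lambda: SolverConfig())


@dataclass
class PlanScore:
    score: float
    tumor_coverage: float
    margin_coverage: float
    overreach: float
    max_current_a: float
    total_voltage: float

    def key(self) -> tuple:
        # lexicographic tie-break: score, then tumor coverage, then lower
        # overreach, then lower total voltage
        return (self.score, self.tumor_coverage, -self.overreach, -self.total_voltage)


def _coarsen_phantom(phantom: VoxelPhantom, factor: int) -> VoxelPhantom:
    if factor <= 1:
        return phantom
    labels = phantom.labels[::factor, ::factor, ::factor]
    return VoxelPhantom(labels=labels.copy(), spacing=phantom.spacing * factor,
                        origin=phantom.origin)


def objective(
    tumor_coverage: float, margin_coverage: float, overreach: float,
    weights: tuple[float, float, float] = (1.0, 0.5, 0.5),
) -> float:
    """Weighted coverage score; higher is better."""
    w1, w2, w3 = weights
    return w1 * tumor_coverage + w2 * margin_coverage - w3 * overreach


def evaluate_plan(
    problem: OptimizationProblem,
    array: ElectrodeArray,
    schedule: PulseSchedule,
    phantom: VoxelPhantom | None = None,
    solver_config: SolverConfig | None = None,
) -> PlanScore:
    """Score one candidate plan; raises for inadmissible plans.

    Collision with vessel or bone raises :class:`InadmissiblePlanError`
    (callers filter candidates first); exceeding the device current cap is
    reported through ``max_current_a`` and handled by the search.
    """
    phantom = phantom if phantom is not None else problem.phantom
    solver_config = solver_config or SolverConfig()
    violations = check_collisions(array, phantom)
    if violations:
        raise InadmissiblePlanError(
            "plan collides with " + ", ".join(f"{v.tissue} (electrode {v.electrode_id})"
                                              for v in violations)
        )
    masks = rasterize(array, phantom, min_radius=0.75 * float(np.max(phantom.spacing)))
    sols = solve_schedule(phantom, problem.tissue_table, array, schedule,
                          solver_config, electrode_masks=masks)
    cum = cumulative_field(sols)
    tumor = phantom.tumor_mask
    margin = safety_margin(phantom, problem.margin_width_mm)
    e_rev_tumor = problem.tissue_table[TUMOR].e_rev
    e_rev_normal = problem.tissue_table[BACKGROUND].e_rev
    e_irrev_normal = problem.tissue_table[BACKGROUND].e_irrev

    tc = coverage_fraction(cum, tumor, e_rev_tumor)
    mc = coverage_fraction(cum, margin, e_rev_normal) if margin.any() else 1.0
    outside = (phantom.labels == BACKGROUND) & ~margin
    ov = coverage_fraction(cum, outside, e_irrev_normal) if outside.any() else 0.0
    return PlanScore(
        score=objective(tc, mc, ov, problem.weights),
        tumor_coverage=tc,
        margin_coverage=mc,
        overreach=ov,
        max_current_a=max(s.current for s in sols),
        total_voltage=sum(e.voltage for e in schedule),
    )


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return radius * rng.uniform() ** (1.0 / 3.0) * v


def _voltage_levels(schedule: PulseSchedule) -> list[float]:
    seen: list[float] = []
    for e in schedule:
        if e.voltage not in seen:
            seen.append(e.voltage)
    return seen


def optimize(
    problem: OptimizationProblem,
    strategy: StrategyConfig | None = None,
    seed: int = 0,
) -> tuple[TreatmentPlan, PlanScore, list[tuple[int, float]]]:
    """Coarse-to-fine search for the best admissible plan.

    Returns ``(plan, final_score, trace)`` where ``trace`` is the
    best-so-far score after each evaluation (nondecreasing) and
    ``final_score`` is the full-resolution re-score of the winner.
    Candidates that collide with vessel/bone, leave the grid, or exceed the
    device current cap are discarded.  Deterministic for fixed seed/config.
    """
    strategy = strategy or StrategyConfig()
    rng = np.random.default_rng(seed)
    coarse = _coarsen_phantom(problem.phantom, strategy.coarsen)

    if problem.template_array is not None:
        if problem.base_schedule is None:
            raise ValueError("template_array requires base_schedule")
        base_schedule = problem.base_schedule

        def build_array(center_offset: np.ndarray, depth_offset: float) -> ElectrodeArray:
            d = np.asarray(problem.template_array.insertion_direction)
            return problem.template_array.translated(center_offset + depth_offset * d)

    else:
        center0 = np.asarray(problem.center, dtype=float) if problem.center is not None \
            else problem.tumor_centroid()
        base_schedule = problem.base_schedule or star_schedule(
            star_array(center0, problem.insertion_direction,
                       problem.center_to_outer, problem.active_tip,
                       problem.electrode_radius)
        )

        def build_array(center_offset: np.ndarray, depth_offset: float) -> ElectrodeArray:
            d = np.asarray(problem.insertion_direction, dtype=float)
            d = d / np.linalg.norm(d)
            return star_array(
                center0 + center_offset + depth_offset * d,
                problem.insertion_direction, problem.center_to_outer,
                problem.active_tip, problem.electrode_radius,
            )

    levels = _voltage_levels(base_schedule)
    lo, hi = problem.voltage_bounds

    def admissible_score(offset, depth, level_map) -> PlanScore | None:
        try:
            array = build_array(np.asarray(offset, dtype=float), depth)
            schedule = base_schedule.with_voltages(level_map)
            sc = evaluate_plan(problem, array, schedule, phantom=coarse,
                              solver_config=strategy.solver_config)
        except (InadmissiblePlanError, ValueError):
            return None
        if sc.max_current_a > problem.current_cap_a:
            return None
        return sc

    trace: list[tuple[int, float]] = []
    best: tuple[tuple, dict] | None = None  # (key, state)
    n_eval = 0

    def consider(offset, depth, level_map) -> None:
        nonlocal best, n_eval
        sc = admissible_score(offset, depth, level_map)
        n_eval += 1
        if sc is not None and (best is None or sc.key() > best[0]):
            best = (sc.key(), {"offset": tuple(offset), "depth": depth,
                               "levels": dict(level_map), "score": sc})
        trace.append((n_eval, best[1]["score"].score if best else float("-inf")))

    identity = {v: v for v in levels}

    # stage 1: array-center candidates at nominal voltages
    candidates = [np.zeros(3)]
    for _ in range(strategy.n_center_candidates):
        candidates.append(_uniform_in_sphere(rng, strategy.center_radius_mm))
    for offset in candidates:
        consider(offset, 0.0, identity)

    if best is None:
        raise InfeasibleProblemError(
            "no admissible candidate found: every candidate collided with "
            "vessel/bone, left the grid, or exceeded the current cap"
        )

    # stage 2: coordinate descent on depth and the voltage levels
    if strategy.voltage_grid is not None:
        # exhaustive enumeration over the voltage grid (per level), at the
        # best geometry found in stage 1
        offset = best[1]["offset"]
        for combo in itertools.product(strategy.voltage_grid, repeat=len(levels)):
            level_map = dict(zip(levels, combo))
            consider(offset, best[1]["depth"], level_map)
    else:
        for _ in range(strategy.descent_rounds):
            improved = False
            state = best[1]
            # depth moves
            for ddepth in (-strategy.depth_step_mm, strategy.depth_step_mm):
                depth = state["depth"] + ddepth
                if abs(depth) <= strategy.depth_range_mm:
                    before = best[0]
                    consider(state["offset"], depth, state["levels"])
                    improved |= best[0] > before
            # voltage moves, one level at a time
            state = best[1]
            for level in levels:
                for dv in (-strategy.voltage_step, strategy.voltage_step):
                    new_levels = dict(state["levels"])
                    v = new_levels[level] + dv
                    if lo <= v <= hi:
                        new_levels[level] = v
                        before = best[0]
                        consider(state["offset"], state["depth"], new_levels)
                        improved |= best[0] > before
            if not improved:
                break

    # final: rebuild the winner and re-score at full resolution
    state = best[1]
    array = build_array(np.asarray(state["offset"]), state["depth"])
    schedule = base_schedule.with_voltages(state["levels"])
    final_score = evaluate_plan(problem, array, schedule,
                                solver_config=strategy.solver_config)
    plan = TreatmentPlan(
        array=array, schedule=schedule, tissue_table=problem.tissue_table,
        solver_config=strategy.solver_config, margin_width_mm=problem.margin_width_mm,
    )
    return plan, final_score, trace
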