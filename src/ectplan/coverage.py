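"""Cumulative field coverage, coverage-volume histograms and robustness.

Electrochemotherapy succeeds only where the tumor (plus a safety margin of
normal tissue) experiences a field at or above the reversible
electroporation threshold during at least one pulse.  Coverage is therefore
evaluated on the voxelwise *maximum* field over the delivered electrode
pairs, and summarized as a coverage-volume histogram (CVH): the fraction of
a target volume exposed to at least a given field strength, as a function of
that strength.  Thresholds are inclusive (``field >= threshold``).

Robustness asks how coverage degrades under small electrode-placement errors
and tissue-conductivity uncertainty; it is assessed by re-solving the plan
over a seeded perturbation ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ectplan.phantom import TissueProperties, TUMOR, VoxelPhantom, safety_margin
from ectplan.electrodes import ElectrodeArray, PulseSchedule, rasterize
from ectplan.solver import FieldSolution, SolverConfig, solve_schedule


def _check_same_grid(solutions: list[FieldSolution]) -> None:
    if not solutions:
        raise ValueError("no solutions given")
    ref = solutions[0]
    for s in solutions[1:]:
        if s.field_magnitude.shape != ref.field_magnitude.shape or not np.allclose(
            s.spacing, ref.spacing
        ):
            raise ValueError("solutions do not share a common grid")


def cumulative_field(solutions: list[FieldSolution]) -> np.ndarray:
    """Voxelwise maximum field magnitude (V/cm) over the pair sequence."""
    _check_same_grid(solutions)
    return np.maximum.reduce([s.field_magnitude for s in solutions])


def coverage_fraction(field: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Fraction of mask voxels with field >= threshold (inclusive)."""
    if not np.any(mask):
        raise ValueError("coverage of an empty mask is undefined")
    return float(np.mean(field[mask] >= threshold))


def cvh(field: np.ndarray, mask: np.ndarray, thresholds) -> list[tuple[float, float]]:
    """Coverage-volume histogram: (threshold, covered fraction) pairs.

    ``thresholds`` must be sorted ascending; the fractions are nonincreasing.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    if not np.any(mask):
        raise ValueError("coverage of an empty mask is undefined")
    vals = field[mask]
    return [(float(t), float(np.mean(vals >= t))) for t in thresholds]


def coverage_progression(
    solutions: list[FieldSolution], mask: np.ndarray, threshold: float
) -> list[float]:
    """Covered fraction of ``mask`` after each successive pair (prefix maxima)."""
    _check_same_grid(solutions)
    running = None
    out = []
    for s in solutions:
        running = s.field_magnitude if running is None else np.maximum(running, s.field_magnitude)
        out.append(coverage_fraction(running, mask, threshold))
    return out


@dataclass
class RobustnessSummary:
    """Tumor coverage at the reversible threshold across a perturbation ensemble."""

    nominal: float
    min: float
    mean: float
    max: float
    members: list[float]
    n_infeasible: int = 0


@dataclass
class CoverageReport:
    """Plan-level coverage summary.

    ``per_pair`` holds, per schedule entry, the pair, voltage, predicted
    current and the tumor coverage of that pair alone at the tumor
    reversible threshold.
    """

    cumulative: np.ndarray
    tumor_mask: np.ndarray
    margin_mask: np.ndarray | None
    tumor_e_rev: float
    per_pair: list[dict] = field(default_factory=list)
    cvh_table: list[tuple[float, float]] = field(default_factory=list)
    robustness: RobustnessSummary | None = None

    def tumor_coverage_at(self, threshold: float) -> float:
        return coverage_fraction(self.cumulative, self.tumor_mask, threshold)

    def margin_coverage_at(self, threshold: float) -> float:
        if self.margin_mask is None or not self.margin_mask.any():
            raise ValueError("no margin mask in this report")
        return coverage_fraction(self.cumulative, self.margin_mask, threshold)

    def to_dict(self) -> dict:
        d = {
            "tumor_e_rev_vcm": self.tumor_e_rev,
            "tumor_coverage_at_e_rev": self.tumor_coverage_at(self.tumor_e_rev),
            "per_pair": self.per_pair,
            "cvh": [{"threshold_vcm": t, "fraction": f} for t, f in self.cvh_table],
        }
        if self.margin_mask is not None and self.margin_mask.any():
            d["margin_coverage_at_e_rev"] = self.margin_coverage_at(self.tumor_e_rev)
        if self.robustness is not None:
            r = self.robustness
            d["robustness"] = {
                "nominal": r.nominal, "min": r.min, "mean": r.mean, "max": r.max,
                "n_members": len(r.members), "n_infeasible": r.n_infeasible,
            }
        return d


def compute_coverage(
    solutions: list[FieldSolution],
    phantom: VoxelPhantom,
    tissue_table: dict[int, TissueProperties],
    margin_width: float = 5.0,
    thresholds=None,
) -> CoverageReport:
    """Aggregate per-pair solutions into a coverage report."""
    cum = cumulative_field(solutions)
    tumor = phantom.tumor_mask
    margin = safety_margin(phantom, margin_width) if margin_width > 0 else None
    e_rev = tissue_table[TUMOR].e_rev
    if thresholds is None:
        thresholds = np.arange(0.0, 1600.0 + 1, 100.0)
    per_pair = [
        {
            "pair": list(s.pair),
            "voltage_v": s.voltage,
            "current_a": s.current,
            "tumor_coverage_at_e_rev": coverage_fraction(s.field_magnitude, tumor, e_rev)
            if tumor.any()
            else None,
        }
        for s in solutions
    ]
    return CoverageReport(
        cumulative=cum,
        tumor_mask=tumor,
        margin_mask=margin,
        tumor_e_rev=e_rev,
        per_pair=per_pair,
        cvh_table=cvh(cum, tumor, thresholds) if tumor.any() else [],
    )


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return r * v


def robustness_sweep(
    phantom: VoxelPhantom,
    tissue_table: dict[int, TissueProperties],
    array: ElectrodeArray,
    schedule: PulseSchedule,
    config: SolverConfig | None = None,
    shift_radius_mm: float = 1.0,
    sigma_scale: float = 0.2,
    n_members: int = 20,
    seed: int = 0,
    rasterize_min_radius: float | None = None,
) -> RobustnessSummary:
    """Coverage statistics over a seeded perturbation ensemble.

    Each member rigidly shifts the whole array by a vector drawn uniformly
    in a sphere of ``shift_radius_mm`` and scales every baseline conductivity
    by a factor uniform in ``1 +/- sigma_scale``, then re-solves the plan and
    records tumor coverage at the tumor reversible threshold.  Members whose
    shifted electrodes leave the grid are flagged infeasible and excluded.
    """
    if shift_radius_mm < 0 or sigma_scale < 0:
        raise ValueError("perturbation magnitudes must be >= 0")
    config = config or SolverConfig()
    rng = np.random.default_rng(seed)
    e_rev = tissue_table[TUMOR].e_rev
    tumor = phantom.tumor_mask

    def coverage_of(arr: ElectrodeArray, table) -> float:
        masks = rasterize(arr, phantom) if rasterize_min_radius is None else rasterize(
            arr, phantom, min_radius=rasterize_min_radius
        )
        sols = solve_schedule(phantom, table, arr, schedule, config, electrode_masks=masks)
        return coverage_fraction(cumulative_field(sols), tumor, e_rev)

    nominal = coverage_of(array, tissue_table)
    members: list[float] = []
    n_infeasible = 0
    for _ in range(n_members):
        shift = _uniform_in_sphere(rng, shift_radius_mm) if shift_radius_mm > 0 else np.zeros(3)
        scale = rng.uniform(1.0 - sigma_scale, 1.0 + sigma_scale) if sigma_scale > 0 else 1.0
        table = {
            code: TissueProperties(
                sigma0=p.sigma0 * scale, sigma_factor=p.sigma_factor,
                e_rev=p.e_rev, e_irrev=p.e_irrev,
            )
            for code, p in tissue_table.items()
        }
        try:
            members.append(coverage_of(array.translated(shift), table))
        except ValueError:
            n_infeasible += 1
    if n_infeasible:
        warnings.warn(f"{n_infeasible} ensemble member(s) infeasible (electrode left the grid)")
    pool = members + [nominal] if not members else members
    return RobustnessSummary(
        nominal=nominal,
        min=float(np.min(pool)),
        mean=float(np.mean(pool)),
        max=float(np.max(pool)),
        members=members,
        n_infeasible=n_infeasible,
    )
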