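"""Nonlinear electrostatic field solver with electroporation-dependent conductivity.

For each electrode pair the quasi-static potential solves the current
continuity equation

    div( sigma(|E|) grad(phi) ) = 0

on the voxel grid, with Dirichlet values on the active-tip voxels (the
applied voltage on one electrode, 0 V on the other) and an insulating
(homogeneous Neumann) outer boundary.  Electroporation makes the problem
mildly nonlinear: tissue conductivity rises from its baseline ``sigma0`` to
``sigma0 * sigma_factor`` as the local field magnitude crosses from the
reversible to the irreversible electroporation threshold.  The nonlinearity
is resolved by damped fixed-point iteration on the conductivity grid.

Discretization is a 7-point finite-difference / finite-volume scheme with
harmonic-mean face conductivities, which is robust for the discontinuous
conductivity at tissue interfaces.  The linear systems are symmetric
positive definite and solved by conjugate gradients with a Jacobi
preconditioner; successive nonlinear iterations warm-start from the previous
potential.  Everything is deterministic.

Internally the solve is in SI units (meters, S/m, volts); field magnitudes
are reported in V/cm, the unit in which electroporation thresholds are
conventionally quoted.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

from ectplan.phantom import TissueProperties, VoxelPhantom
from ectplan.electrodes import ElectrodeArray, PulseSchedule, rasterize


class ConvergenceError(RuntimeError):
    """Fixed-point iteration on sigma(|E|) failed to converge."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class SolverConfig:
    """Numerical controls for the field solve.

    Attributes
    ----------
    electroporation : bool
        Enable the sigma(|E|) conductivity increase.  Disabled, the problem
        is linear and solved in one step.
    persistent_sigma : bool
        Carry conductivity increases forward from pair to pair (pulse-history
        memory).  Off by default: pairs are solved independently.
    damping : float
        Damping of the fixed-point sigma update, in (0, 1].
    current_rtol : float
        Convergence: relative change of the predicted current between
        successive fixed-point iterations.
    max_iterations : int
        Fixed-point iteration cap.
    lin_rtol : float
        Relative residual for the inner conjugate-gradient solves.
    ramp : str
        Shape of the sigma(E) transition between the thresholds:
        "raised_cosine" (smooth, default) or "linear".
    strict : bool
        Raise ConvergenceError when the fixed point is not reached; if
        False, return the last iterate flagged unconverged.
    pad_factor : float
        Grid-padding policy used by fixture builders: the outer boundary
        should be at least ``pad_factor`` array diameters away from any
        electrode so the insulated-boundary approximation holds.
    """

    electroporation: bool = True
    persistent_sigma: bool = False
    damping: float = 0.5
    current_rtol: float = 1e-3
    max_iterations: int = 50
    lin_rtol: float = 1e-8
    ramp: str = "raised_cosine"
    strict: bool = True
    pad_factor: float = 1.5


@dataclass
class FieldSolution:
    """Per-pair solve result.

    ``current`` is the predicted delivered current (A), computed as the total
    conduction flux through the faces enclosing the energized electrode;
    ``current_return`` is the corresponding flux into the grounded electrode.
    ``field_magnitude`` is |E| in V/cm on the full grid.
    """

    potential: np.ndarray
    field_magnitude: np.ndarray
    conductivity: np.ndarray
    current: float
    current_return: float
    pair: tuple[int, int]
    voltage: float
    spacing: np.ndarray
    n_iterations: int = 1
    converged: bool = True
    residuals: list[float] = field(default_factory=list)


def sigma_of_e(e, tissue: TissueProperties, ramp: str = "raised_cosine"):
    """Conductivity (S/m) at field magnitude ``e`` (V/cm) for one tissue.

    Returns ``sigma0`` below the reversible threshold, ``sigma0 *
    sigma_factor`` above the irreversible threshold, and a smooth monotone
    interpolation in between (raised-cosine by default).
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("field magnitude must be >= 0")
    lo, hi = tissue.e_rev, tissue.e_irrev
    t = np.clip((e - lo) / (hi - lo), 0.0, 1.0)
    if ramp == "raised_cosine":
        f = 0.5 * (1.0 - np.cos(np.pi * t))
    elif ramp == "linear":
        f = t
    else:
        raise ValueError(f"unknown ramp {ramp!r}")
    out = tissue.sigma0 * (1.0 + (tissue.sigma_factor - 1.0) * f)
    return float(out) if out.ndim == 0 else out


def _sigma_grid(labels: np.ndarray, tissue_table: dict[int, TissueProperties]) -> np.ndarray:
    sigma = np.empty(labels.shape, dtype=float)
    for code, props in tissue_table.items():
        sigma[labels == code] = props.sigma0
    return sigma


def _sigma_update(e_vcm, labels, tissue_table, ramp: str) -> np.ndarray:
    sigma = np.empty(labels.shape, dtype=float)
    for code, props in tissue_table.items():
        sel = labels == code
        if np.any(sel):
            sigma[sel] = sigma_of_e(e_vcm[sel], props, ramp=ramp)
    return sigma


def _face_conductances(sigma: np.ndarray, spacing_m: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean conductance (S) of the faces along one axis."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(0, -1)
    hi[axis] = slice(1, None)
    s1 = sigma[tuple(lo)]
    s2 = sigma[tuple(hi)]
    h = spacing_m[axis]
    area = np.prod(np.delete(spacing_m, axis))
    return (2.0 * s1 * s2 / (s1 + s2)) * (area / h)


@functools.lru_cache(maxsize=64)
def _numerical_radius(offsets: tuple, h: float) -> float:
    """Equivalent (numerical) radius of a 2-D Dirichlet stencil.

    A needle cross-section rasterized to grid cells does not behave like a
    cylinder of the physical radius: the 5-point scheme around a Dirichlet
    cell set has its own equivalent radius (~0.2 h for a single cell, the
    classic well-model result).  It is measured here directly: solve the
    2-D Laplace problem with potential 1 on the stencil and 0 on a distant
    ring, read the total flux Q, and invert the radial-flow relation
    ``Q = 2 pi / ln(R / r_num)``.
    """
    m = 60  # outer ring radius in cells; log accuracy ~ h/R
    n = 2 * m + 1
    ii, jj = np.meshgrid(np.arange(n) - m, np.arange(n) - m, indexing="ij")
    rr = np.hypot(ii, jj)
    inner = np.zeros((n, n), dtype=bool)
    for di, dj in offsets:
        inner[m + di, m + dj] = True
    outer = rr >= m - 1
    phi_d = inner.astype(float)
    dirichlet = inner | outer
    unknown = ~dirichlet
    uidx = -np.ones((n, n), dtype=np.int64)
    nu = int(unknown.sum())
    uidx[unknown] = np.arange(nu)
    diag = np.zeros(nu)
    b = np.zeros(nu)
    rows, cols, vals = [], [], []
    for axis in range(2):
        lo = [slice(None)] * 2
        hi = [slice(None)] * 2
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        u1, u2 = uidx[tuple(lo)].ravel(), uidx[tuple(hi)].ravel()
        p1, p2 = phi_d[tuple(lo)].ravel(), phi_d[tuple(hi)].ravel()
        both = (u1 >= 0) & (u2 >= 0)
        np.add.at(diag, u1[both], 1.0)
        np.add.at(diag, u2[both], 1.0)
        rows += [u1[both], u2[both]]
        cols += [u2[both], u1[both]]
        vals += [-np.ones(both.sum()), -np.ones(both.sum())]
        only1 = (u1 >= 0) & (u2 < 0)
        np.add.at(diag, u1[only1], 1.0)
        np.add.at(b, u1[only1], p2[only1])
        only2 = (u2 >= 0) & (u1 < 0)
        np.add.at(diag, u2[only2], 1.0)
        np.add.at(b, u2[only2], p1[only2])
    rows.append(np.arange(nu))
    cols.append(np.arange(nu))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nu, nu),
    ).tocsr()
    x = spsolve(A, b)
    phi = phi_d.copy()
    phi[unknown] = x
    # total flux out of the stencil (unit conductance faces)
    q = 0.0
    for di, dj in offsets:
        i, j = m + di, m + dj
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if not inner[ni, nj]:
                q += 1.0 - phi[ni, nj]
    r_out = (m - 1) * h  # jagged-ring radius; adequate at this log accuracy
    return float(r_out * np.exp(-2.0 * np.pi / q))


def _dominant_axis(direction, tol_deg: float = 1.0) -> int | None:
    d = np.asarray(direction, dtype=float)
    d = np.abs(d / np.linalg.norm(d))
    axis = int(np.argmax(d))
    return axis if d[axis] >= np.cos(np.deg2rad(tol_deg)) else None


def _electrode_face_scales(
    phantom: VoxelPhantom, masks: dict[int, np.ndarray], array: ElectrodeArray,
    pair: tuple[int, int],
) -> tuple[list[np.ndarray], np.ndarray] | None:
    """Sub-grid needle model: face-conductance scales plus blocked voxels.

    Three corrections make the discrete electrode behave like the physical
    needle independently of grid spacing:

    * radius — for an axis-aligned needle the in-plane flow near the shaft
      is radial; matching the series resistance between the rasterized
      stencil's numerical radius and the physical radius gives a uniform
      factor ``beta = 2 pi / (2 pi + n_perim * ln(r_num / r_w))`` on the
      lateral boundary faces (``n_perim`` = lateral boundary faces per
      slice);
    * insulated proximal shaft — the needle between the skin entry and the
      start of the active tip is an insulated rod: its voxels are blocked
      (all adjacent faces removed), since they carry no current and exclude
      tissue;
    * distal cap — voxel-center rasterization extends the discrete rod half
      a voxel beyond the physical tip, so the flat end-cap face is removed
      to avoid counting the end length twice (a real trocar tip tapers to a
      point and contributes little extra flux).

    Returns ``(face_scales, blocked_mask)``, or None when the correction
    does not apply (oblique needle or anisotropic in-plane spacing), in
    which case the plain rasterized Dirichlet electrode is used.
    """
    axis = _dominant_axis(array.insertion_direction)
    if axis is None:
        return None
    perp = [a for a in range(3) if a != axis]
    if not np.isclose(phantom.spacing[perp[0]], phantom.spacing[perp[1]]):
        return None
    h = float(phantom.spacing[perp[0]])

    from ectplan.electrodes import _segment_mask

    scales = [np.ones(np.array(phantom.shape) - np.eye(3, dtype=int)[a]) for a in range(3)]
    blocked = np.zeros(phantom.shape, dtype=bool)
    in_pair = np.zeros(phantom.shape, dtype=bool)
    for eid in pair:
        in_pair |= masks[eid]
    for eid in pair:
        e = array.get(eid)
        mask = masks[eid]
        idx = np.argwhere(mask)
        if len(idx) == 0:
            continue

        # insulated proximal shaft: entry -> active-tip start
        a0, _ = e.active_segment
        shaft = _segment_mask(phantom, e.entry, a0, e.radius) & ~in_pair
        blocked |= shaft

        # radius correction from the modal 2-D cross-section
        mid = idx[:, axis] == int(np.median(idx[:, axis]))
        sec = idx[mid][:, perp]
        c = np.round(sec.mean(axis=0)).astype(int)
        offsets = tuple(sorted((int(p[0] - c[0]), int(p[1] - c[1])) for p in sec))
        r_num = _numerical_radius(offsets, h)
        sec_set = {tuple(p) for p in sec}
        n_perim = sum(
            (p[0] + di, p[1] + dj) not in sec_set
            for p in sec_set
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
        )
        denom = 2.0 * np.pi + n_perim * np.log(r_num / e.radius)
        if denom > 0.1 * 2.0 * np.pi:  # else pathological stencil; uncorrected
            beta = 2.0 * np.pi / denom
            for a in perp:
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[a] = slice(0, -1)
                hi[a] = slice(1, None)
                m1 = mask[tuple(lo)]
                m2 = mask[tuple(hi)]
                scales[a][m1 ^ m2] *= beta

        # distal cap: remove the axial boundary face on the tip side
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        m1 = mask[tuple(lo)]
        m2 = mask[tuple(hi)]
        if e.direction[axis] > 0:  # tip at the high-index end
            scales[axis][m1 & ~m2] = 0.0
        else:
            scales[axis][m2 & ~m1] = 0.0

    # blocked voxels carry no current: remove every adjacent face
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        scales[a][blocked[tuple(lo)] | blocked[tuple(hi)]] = 0.0
    return scales, blocked


def _assemble(sigma, spacing_m, dirichlet, phi_d, face_scales=None):
    """SPD system for the unknown (non-Dirichlet) voxels.

    Homogeneous Neumann outer boundary arises naturally from omitting faces
    beyond the grid.
    """
    shape = sigma.shape
    unknown = ~dirichlet
    n_unknown = int(unknown.sum())
    uidx = -np.ones(shape, dtype=np.int64)
    uidx[unknown] = np.arange(n_unknown)

    diag = np.zeros(n_unknown)
    b = np.zeros(n_unknown)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        g = _face_conductances(sigma, spacing_m, axis)
        if face_scales is not None:
            g = g * face_scales[axis]
        g = g.ravel()
        u1 = uidx[tuple(lo)].ravel()
        u2 = uidx[tuple(hi)].ravel()
        p1 = phi_d[tuple(lo)].ravel()
        p2 = phi_d[tuple(hi)].ravel()

        both = (u1 >= 0) & (u2 >= 0)
        np.add.at(diag, u1[both], g[both])
        np.add.at(diag, u2[both], g[both])
        rows.append(u1[both])
        cols.append(u2[both])
        vals.append(-g[both])
        rows.append(u2[both])
        cols.append(u1[both])
        vals.append(-g[both])

        only1 = (u1 >= 0) & (u2 < 0)
        np.add.at(diag, u1[only1], g[only1])
        np.add.at(b, u1[only1], g[only1] * p2[only1])

        only2 = (u2 >= 0) & (u1 < 0)
        np.add.at(diag, u2[only2], g[only2])
        np.add.at(b, u2[only2], g[only2] * p1[only2])

    rows.append(np.arange(n_unknown))
    cols.append(np.arange(n_unknown))
    # isolated unknowns (all faces removed) get an identity row, pinning 0 V
    diag = np.where(diag > 0, diag, 1.0)
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    ).tocsr()
    return A, b, diag, uidx


def _electrode_flux(phi, sigma, spacing_m, mask, face_scales=None) -> float:
    """Net conduction current (A) leaving the voxels in ``mask``."""
    total = 0.0
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        g = _face_conductances(sigma, spacing_m, axis)
        if face_scales is not None:
            g = g * face_scales[axis]
        m1 = mask[tuple(lo)]
        m2 = mask[tuple(hi)]
        p1 = phi[tuple(lo)]
        p2 = phi[tuple(hi)]
        out1 = m1 & ~m2  # flux from inside (lo side) to outside (hi side)
        out2 = m2 & ~m1
        total += float(np.sum(g[out1] * (p1[out1] - p2[out1])))
        total += float(np.sum(g[out2] * (p2[out2] - p1[out2])))
    return total


def _field_magnitude_vcm(phi: np.ndarray, spacing_mm: np.ndarray) -> np.ndarray:
    grads = np.gradient(phi, *spacing_mm)  # V/mm per axis
    mag = np.sqrt(sum(g * g for g in grads))
    return mag * 10.0  # V/mm -> V/cm


def solve_pair(
    phantom: VoxelPhantom,
    tissue_table: dict[int, TissueProperties],
    electrode_masks: dict[int, np.ndarray],
    pair: tuple[int, int],
    voltage: float,
    config: SolverConfig | None = None,
    sigma_floor: np.ndarray | None = None,
    array: ElectrodeArray | None = None,
) -> FieldSolution:
    """Solve one electrode pair at the given voltage.

    ``electrode_masks`` come from :func:`ectplan.electrodes.rasterize`.
    ``sigma_floor`` (optional) is a lower bound on the conductivity grid,
    used by the persistent-sigma mode to carry electroporation from earlier
    pairs.  When ``array`` is given, the sub-grid needle-radius correction
    is applied so the predicted current is grid-converged even when the
    needle radius is below the voxel size.
    """
    config = config or SolverConfig()
    id_a, id_b = pair
    mask_a = electrode_masks[id_a]
    mask_b = electrode_masks[id_b]
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"electrode mask for pair {pair} is empty")
    if np.any(mask_a & mask_b):
        raise ValueError(f"electrode masks for pair {pair} overlap")

    spacing_mm = phantom.spacing
    spacing_m = spacing_mm * 1e-3
    dirichlet = mask_a | mask_b
    phi_d = np.zeros(phantom.shape)
    phi_d[mask_a] = voltage

    sigma = _sigma_grid(phantom.labels, tissue_table)
    if sigma_floor is not None:
        sigma = np.maximum(sigma, sigma_floor)
    sigma0_grid = sigma.copy()
    corrections = (
        _electrode_face_scales(phantom, electrode_masks, array, pair)
        if array is not None
        else None
    )
    if corrections is not None:
        face_scales, blocked = corrections
    else:
        face_scales, blocked = None, None

    fill_idx = None
    if blocked is not None and blocked.any():
        # blocked (insulated-shaft) voxels carry no potential of their own;
        # for field evaluation they inherit the nearest tissue value
        from scipy import ndimage

        dirichlet = dirichlet | blocked
        _, nearest = ndimage.distance_transform_edt(blocked, return_indices=True)
        fill_idx = tuple(ix[blocked] for ix in nearest)

    unknown = ~dirichlet
    x0 = None
    phi = phi_d.copy()
    current = 0.0
    residuals: list[float] = []
    converged = not config.electroporation
    n_iter = 0
    max_iter = 1 if not config.electroporation else config.max_iterations
    # intermediate fixed-point iterates tolerate a looser inner solve; the
    # final potential is recomputed at the tight tolerance below
    rtol_inner = max(config.lin_rtol, 1e-5) if config.electroporation else config.lin_rtol

    def _linear_solve(sigma_now, x_start, rtol):
        A, b, diag, _ = _assemble(sigma_now, spacing_m, dirichlet, phi_d, face_scales)
        M = sparse.diags(1.0 / diag)
        x, info = cg(A, b, x0=x_start, M=M, rtol=rtol, atol=0.0, maxiter=20000)
        if info != 0:
            raise ConvergenceError(
                f"inner CG solve did not converge (info={info})", residuals
            )
        out = phi_d.copy()
        out[unknown] = x
        if fill_idx is not None:
            out[blocked] = out[fill_idx]
        return out, x

    for n_iter in range(1, max_iter + 1):
        phi, x0 = _linear_solve(sigma, x0, rtol_inner)
        new_current = _electrode_flux(phi, sigma, spacing_m, mask_a, face_scales)
        scale = max(abs(new_current), abs(current), 1e-300)
        rel = abs(new_current - current) / scale
        residuals.append(rel)
        current = new_current

        if not config.electroporation or (n_iter > 1 and rel < config.current_rtol):
            converged = True
            break
        e_vcm = _field_magnitude_vcm(phi, spacing_mm)
        sigma_target = _sigma_update(e_vcm, phantom.labels, tissue_table, config.ramp)
        sigma_target = np.maximum(sigma_target, sigma0_grid)
        if sigma_floor is not None:
            sigma_target = np.maximum(sigma_target, sigma_floor)
        sigma = sigma + config.damping * (sigma_target - sigma)

    if rtol_inner > config.lin_rtol:
        # converged conductivity: one tight solve so the reported potential,
        # current and charge balance are at the requested accuracy
        phi, x0 = _linear_solve(sigma, x0, config.lin_rtol)
        current = _electrode_flux(phi, sigma, spacing_m, mask_a, face_scales)

    if not converged and config.strict and config.electroporation:
        raise ConvergenceError(
            f"sigma fixed point not reached after {n_iter} iterations "
            f"(last relative current change {residuals[-1]:.3g})",
            residuals,
        )

    e_vcm = _field_magnitude_vcm(phi, spacing_mm)
    current_return = -_electrode_flux(phi, sigma, spacing_m, mask_b, face_scales)
    return FieldSolution(
        potential=phi,
        field_magnitude=e_vcm,
        conductivity=sigma,
        current=current,
        current_return=current_return,
        pair=pair,
        voltage=voltage,
        spacing=spacing_mm.copy(),
        n_iterations=n_iter,
        converged=converged,
        residuals=residuals,
    )


def solve_schedule(
    phantom: VoxelPhantom,
    tissue_table: dict[int, TissueProperties],
    array: ElectrodeArray,
    schedule: PulseSchedule,
    config: SolverConfig | None = None,
    electrode_masks: dict[int, np.ndarray] | None = None,
) -> list[FieldSolution]:
    """Solve every entry of a pulse schedule in delivery order.

    With ``config.persistent_sigma`` the conductivity increases from earlier
    pairs act as a floor for later ones; by default pairs are independent.
    """
    config = config or SolverConfig()
    schedule.validate_against(array)
    masks = electrode_masks if electrode_masks is not None else rasterize(array, phantom)
    solutions = []
    sigma_floor = None
    for entry in schedule:
        sol = solve_pair(
            phantom, tissue_table, masks, entry.pair, entry.voltage,
            config=config, sigma_floor=sigma_floor, array=array,
        )
        if config.persistent_sigma:
            floor = sol.conductivity
            sigma_floor = floor if sigma_floor is None else np.maximum(sigma_floor, floor)
        solutions.append(sol)
    return solutions


def current_balance(solution: FieldSolution) -> float:
    """Relative mismatch between anode and cathode currents.

    A discrete-conservation QA check: on a converged solve the flux leaving
    the energized electrode must equal the flux entering the grounded one up
    to the linear-solver tolerance.
    """
    if solution.current == 0:
        raise ValueError("anode current is zero; balance undefined")
    return abs(solution.current - solution.current_return) / abs(solution.current)


def two_cylinder_current(sigma: float, separation_mm: float, radius_mm: float,
                         length_mm: float, voltage: float) -> float:
    """Closed-form current between two parallel cylinders in a uniform medium.

    Per-unit-length conductance of two infinite parallel cylinders of radius
    ``a`` with axis separation ``d`` in a homogeneous medium of conductivity
    ``sigma`` is ``pi * sigma / arccosh(d / (2 a))``; multiplied by the
    active length it provides an analytic oracle for the discrete solver
    (end effects excluded).
    """
    g_per_len = np.pi * sigma / np.arccosh(separation_mm / (2.0 * radius_mm))
    return float(voltage * g_per_len * length_mm * 1e-3)
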