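"""Statics of a single protofilament curl.

A curl is modelled as a chain of rigid rods (one per tubulin dimer, length
``r``) joined by Hookean torsion springs with spring constant ``kappa`` and
a non-zero relaxed angle ``theta_i`` per joint.  A point load ``F`` applied
at the curl tip, perpendicular to the microtubule axis, compresses the curl
toward the wall.  Equilibrium shapes satisfy the per-node torque balance

    kappa * (theta_n - theta_i) + F * r * sum_{k>=n} cos(Phi_k) = 0,

where ``Phi_k = theta_1 + ... + theta_k`` is the cumulative angle of segment
``k`` measured from the microtubule axis.  The positive-``F`` convention is
a load that opposes the outward curl (the trap-loaded bead of the wave
assay); equivalently it is the gradient condition of the total potential

    U = sum_n 1/2 * kappa * (theta_n - theta_i)^2 + F * tip_height.

The equilibrium depends on force only through the dimensionless load
``lambda = F * r / kappa``, which :func:`unit_load_curve` exploits to make
repeated force-deflection evaluations (as needed by model fitting) cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import root

__all__ = [
    "ElasticaParams",
    "CurlState",
    "FDCurve",
    "solve_equilibrium",
    "tip_metrics",
    "force_deflection_curve",
    "elastic_energy",
    "unloaded_tip_height",
    "unit_load_curve",
    "fd_curve_from_unit_curve",
]

#: Residual max-norm tolerance for torque balance, pN·nm.
RESIDUAL_TOL_PN_NM = 1e-10

#: Default force grid: 0 to 20 pN (curl frame) in 0.1 pN steps.
DEFAULT_FORCE_GRID_PN = np.arange(0.0, 20.0 + 1e-9, 0.1)


class ConvergenceError(RuntimeError):
    """Raised when no equilibrium meeting the residual tolerance is found."""


@dataclass(frozen=True)
class ElasticaParams:
    """Physical parameters of one protofilament curl.

    Parameters
    ----------
    segment_length_nm:
        Rod length per tubulin dimer (nm).
    relaxed_angle_rad:
        Intrinsic bend per joint (radians); must lie in [0, pi/2).
    kappa_pn_nm_per_rad:
        Torsion-spring constant per joint (pN·nm·rad^-1).
    n_segments:
        Number of dimers in the curl (>= 1).
    """

    segment_length_nm: float
    relaxed_angle_rad: float
    kappa_pn_nm_per_rad: float
    n_segments: int

    def __post_init__(self) -> None:
        if not self.segment_length_nm > 0:
            raise ValueError("segment_length_nm must be positive")
        if not self.kappa_pn_nm_per_rad > 0:
            raise ValueError("kappa_pn_nm_per_rad must be positive")
        if not 0.0 <= self.relaxed_angle_rad < math.pi / 2:
            raise ValueError("relaxed_angle_rad must lie in [0, pi/2)")
        if int(self.n_segments) != self.n_segments or self.n_segments < 1:
            raise ValueError("n_segments must be a positive integer")


@dataclass(frozen=True)
class CurlState:
    """An equilibrium shape of a curl under a given tip load.

    ``joint_angles_rad[n]`` is the angle of segment ``n+1`` relative to the
    previous segment; the cumulative angle from the microtubule axis is
    ``Phi_k = sum(joint_angles_rad[:k+1])``.
    """

    joint_angles_rad: np.ndarray
    applied_force_pn: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "joint_angles_rad", np.asarray(self.joint_angles_rad, dtype=float)
        )


@dataclass(frozen=True)
class FDCurve:
    """Tabulated force vs radial tip height for a single curl.

    ``force_pn`` is strictly increasing and ``tip_height_nm`` non-increasing;
    the curve is invertible by monotone interpolation.
    """

    force_pn: np.ndarray
    tip_height_nm: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "force_pn", np.asarray(self.force_pn, dtype=float))
        object.__setattr__(
            self, "tip_height_nm", np.asarray(self.tip_height_nm, dtype=float)
        )
        if self.force_pn.shape != self.tip_height_nm.shape:
            raise ValueError("force_pn and tip_height_nm must have equal length")

    def height_at(self, force_pn):
        """Tip height at the given force(s), by monotone interpolation."""
        return np.interp(force_pn, self.force_pn, self.tip_height_nm)

    def force_at(self, height_nm):
        """Force required to compress the tip to the given height(s)."""
        h = self.tip_height_nm[::-1]
        f = self.force_pn[::-1]
        return np.interp(height_nm, h, f)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"force_pn": self.force_pn, "tip_height_nm": self.tip_height_nm}
        )


def _torque_residual(theta: np.ndarray, params: ElasticaParams, force_pn: float):
    """Per-node torque residual (pN·nm) and its Jacobian."""
    kappa = params.kappa_pn_nm_per_rad
    r = params.segment_length_nm
    phi = np.cumsum(theta)
    cos_phi = np.cos(phi)
    sin_phi = np.sin(phi)
    # tail[n] = sum_{k>=n} cos(Phi_k)
    tail = np.cumsum(cos_phi[::-1])[::-1]
    res = kappa * (theta - params.relaxed_angle_rad) + force_pn * r * tail

    n = theta.size
    # d tail[n] / d theta_j = -sum_{k >= max(n, j)} sin(Phi_k)
    sin_tail = np.cumsum(sin_phi[::-1])[::-1]
    jac = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            jac[i, j] = -force_pn * r * sin_tail[max(i, j)]
    jac[np.diag_indices(n)] += kappa
    return res, jac


def solve_equilibrium(
    params: ElasticaParams, force_pn: float, *, n_continuation_steps: int | None = None
) -> CurlState:
    """Solve the torque-balance equilibrium of a curl under a tip load.

    Continuation in force from the relaxed (``F=0``) state selects the branch
    connected to the relaxed shape; each step is solved with MINPACK's Powell
    hybrid (dogleg trust-region) method and polished with damped Newton steps
    until the residual max-norm is at most 1e-10 pN·nm.

    Raises
    ------
    ConvergenceError
        If no state meeting the tolerance is found (force beyond the
        solvable range for this curl).
    """
    if force_pn < 0:
        raise ValueError("force_pn must be nonnegative (compressive load)")
    n = int(params.n_segments)
    theta = np.full(n, params.relaxed_angle_rad)
    if force_pn == 0.0:
        return CurlState(joint_angles_rad=theta, applied_force_pn=0.0)

    if n_continuation_steps is None:
        # one step per ~0.05 units of dimensionless load, at least 4;
        # capped so that absurd loads fail fast instead of looping
        lam = force_pn * params.segment_length_nm / params.kappa_pn_nm_per_rad
        n_continuation_steps = min(500, max(4, int(math.ceil(lam / 0.05))))
    for f in np.linspace(0.0, force_pn, n_continuation_steps + 1)[1:]:
        sol = root(
            lambda th: _torque_residual(th, params, f)[0],
            theta,
            jac=lambda th: _torque_residual(th, params, f)[1],
            method="hybr",
            tol=1e-12,
        )
        # MINPACK's success flag is pessimistic when warm-started near the
        # solution; accept by residual via the Newton polish instead.
        try:
            theta = _newton_polish(sol.x, params, f)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"no equilibrium at F={f:.4g} pN for N={n} "
                f"(kappa={params.kappa_pn_nm_per_rad:.4g})"
            ) from exc

    return CurlState(joint_angles_rad=theta, applied_force_pn=float(force_pn))


def _newton_polish(theta: np.ndarray, params: ElasticaParams, force_pn: float):
    for _ in range(30):
        res, jac = _torque_residual(theta, params, force_pn)
        if np.max(np.abs(res)) <= RESIDUAL_TOL_PN_NM:
            return theta
        try:
            step = np.linalg.solve(jac, res)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Jacobian during polish") from exc
        theta = theta - step
    res, _ = _torque_residual(theta, params, force_pn)
    if np.max(np.abs(res)) > RESIDUAL_TOL_PN_NM:
        raise ConvergenceError(
            f"residual {np.max(np.abs(res)):.3g} pN·nm exceeds tolerance"
        )
    return theta


def tip_metrics(state: CurlState, params: ElasticaParams):
    """Radial tip height and axial extension of a curl shape.

    Returns ``(tip_height_nm, axial_extension_nm)`` where
    ``tip_height = r * sum_k sin(Phi_k)`` (radial distance of the tip above
    the microtubule wall) and ``axial_extension = r * sum_k cos(Phi_k)``.
    """
    if state.joint_angles_rad.size != params.n_segments:
        raise ValueError("state does not match params (segment count differs)")
    phi = np.cumsum(state.joint_angles_rad)
    r = params.segment_length_nm
    return float(r * np.sum(np.sin(phi))), float(r * np.sum(np.cos(phi)))


def unloaded_tip_height(
    n_segments: int, relaxed_angle_rad: float, segment_length_nm: float
) -> float:
    """Closed-form unloaded tip height ``r * sum_k sin(k * theta_i)``."""
    k = np.arange(1, n_segments + 1)
    return float(segment_length_nm * np.sum(np.sin(k * relaxed_angle_rad)))


def force_deflection_curve(params: ElasticaParams, force_grid_pn=None) -> FDCurve:
    """Tabulate tip height against tip load over a force grid.

    The grid must start at zero and increase strictly.  The curve is
    truncated at the first force where the tip height would drop to or below
    zero, or where the solver fails to converge.
    """
    if force_grid_pn is None:
        force_grid_pn = DEFAULT_FORCE_GRID_PN
    grid = np.asarray(force_grid_pn, dtype=float)
    if grid.size == 0:
        raise ValueError("force grid is empty")
    if grid[0] != 0.0 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("force grid must start at 0 and increase strictly")

    forces, heights = [], []
    theta = np.full(params.n_segments, params.relaxed_angle_rad)
    for f in grid:
        if f > 0.0:
            sol = root(
                lambda th: _torque_residual(th, params, f)[0],
                theta,
                jac=lambda th: _torque_residual(th, params, f)[1],
                method="hybr",
                tol=1e-12,
            )
            try:
                theta = _newton_polish(sol.x, params, f)
            except ConvergenceError:
                break
        state = CurlState(joint_angles_rad=theta, applied_force_pn=f)
        h, _ = tip_metrics(state, params)
        if f > 0.0 and h <= 0.0:
            break
        forces.append(f)
        heights.append(h)
    return FDCurve(
        force_pn=np.array(forces),
        tip_height_nm=np.array(heights),
        n_segments=params.n_segments,
    )


def elastic_energy(state: CurlState, params: ElasticaParams) -> float:
    """Stored bending energy ``sum_n 1/2 kappa (theta_n - theta_i)^2`` (pN·nm)."""
    if state.joint_angles_rad.size != params.n_segments:
        raise ValueError("state does not match params (segment count differs)")
    d = state.joint_angles_rad - params.relaxed_angle_rad
    return float(0.5 * params.kappa_pn_nm_per_rad * np.sum(d * d))


# ---------------------------------------------------------------------------
# Dimensionless master curve
# ---------------------------------------------------------------------------

#: Dimensionless load grid resolution and extent for the cached master curve.
_UNIT_LOAD_MAX = 3.0
_UNIT_LOAD_STEP = 0.002


@lru_cache(maxsize=64)
def unit_load_curve(
    n_segments: int, relaxed_angle_rad: float, segment_length_nm: float
):
    """Master force-deflection curve in the dimensionless load ``lambda = F r / kappa``.

    Because the torque balance can be written
    ``(theta_n - theta_i) + lambda * sum_{k>=n} cos(Phi_k) = 0``, the shape
    depends on force and stiffness only through ``lambda``.  The returned
    ``(lambda_grid, tip_height_nm)`` table (truncated where the height
    reaches zero or the solver fails) rescales to the physical curve of any
    ``kappa`` via ``F = lambda * kappa / r``.
    """
    params = ElasticaParams(
        segment_length_nm=segment_length_nm,
        relaxed_angle_rad=relaxed_angle_rad,
        kappa_pn_nm_per_rad=1.0,  # lambda = F * r with unit stiffness
        n_segments=n_segments,
    )
    lam_grid = np.arange(0.0, _UNIT_LOAD_MAX + 1e-12, _UNIT_LOAD_STEP)
    force_grid = lam_grid / segment_length_nm
    curve = force_deflection_curve(params, force_grid)
    lam = curve.force_pn * segment_length_nm
    return lam, curve.tip_height_nm


def fd_curve_from_unit_curve(params: ElasticaParams) -> FDCurve:
    """Physical force-deflection curve obtained by rescaling the master curve."""
    lam, heights = unit_load_curve(
        params.n_segments, params.relaxed_angle_rad, params.segment_length_nm
    )
    forces = lam * params.kappa_pn_nm_per_rad / params.segment_length_nm
    return FDCurve(
        force_pn=forces, tip_height_nm=heights, n_segments=params.n_segments
    )
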