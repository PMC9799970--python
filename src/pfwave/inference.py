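"""Fitting the tip model and work-output analysis of amplitude-vs-force data.

Two estimators operate on per-condition pulse amplitude vs trap force
summaries (mean, SEM, N per force level):

* :func:`fit_model` — weighted nonlinear least squares of the
  multi-protofilament tip model, with the per-dimer bending stiffness
  ``kappa`` and the mean curl length ``n_mean`` free.  Fitting is performed
  in the curl frame (bead-to-wall height vs lateral force) after lever
  conversion.  Parameter covariance is the Jacobian-based
  ``(J^T W J)^-1`` scaled by the reduced chi-square, and 95% confidence
  intervals use Student's t with ``n_points - 2`` degrees of freedom.

* :func:`line_work_analysis` — a weighted straight-line fit
  ``A = a - b F``; the area under the line, ``W = a^2 / (2 b)``, estimates
  the total mechanical work the curls could deliver in the assay.  The
  y-intercept ``a`` is the unloaded amplitude and ``a / b`` the suppression
  force.  Uncertainties in ``a`` and ``b`` are propagated assuming they are
  uncorrelated.

:func:`straightening_energy` reports the per-interface harmonic strain
estimate ``1/2 kappa theta_i^2`` in pN·nm, k_BT and kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import constants
from .bead_lever import LeverGeometry, amplitude_to_height, trap_to_lateral_force
from .tip_assembly import TipConfig, predicted_amplitude_curve

__all__ = [
    "AmplitudeForceDataset",
    "ModelFitResult",
    "LineWorkResult",
    "aggregate_events",
    "fit_model",
    "line_work_analysis",
    "straightening_energy",
]

#: Default fit initialisation and bounds.
FIT_INIT = {"kappa": 150.0, "n_mean": 3.0}
FIT_BOUNDS = {"kappa": (10.0, 1000.0), "n_mean": (1.0, 5.0)}


@dataclass(frozen=True)
class AmplitudeForceDataset:
    """Per-condition pulse amplitudes grouped by trap-force level."""

    trap_force_pn: np.ndarray
    mean_amplitude_nm: np.ndarray
    sem_nm: np.ndarray
    n_events: np.ndarray
    species: str = ""
    mg_mM: float = float("nan")
    treatment: str = ""

    def __post_init__(self) -> None:
        for name in ("trap_force_pn", "mean_amplitude_nm", "sem_nm", "n_events"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        f = self.trap_force_pn
        if len(set(f.tolist())) != f.size:
            raise ValueError("trap-force levels must be distinct")
        if np.any(self.n_events < 1):
            raise ValueError("each force level needs at least one event")
        if np.any((self.n_events > 1) & ~(self.sem_nm > 0)):
            raise ValueError("sem_nm must be positive where n_events > 1")

    @property
    def n_levels(self) -> int:
        return int(self.trap_force_pn.size)


def aggregate_events(events: pd.DataFrame) -> list[AmplitudeForceDataset]:
    """Group a per-event table into per-condition amplitude/force summaries.

    ``events`` needs columns ``trap_force_pn`` and ``amplitude_nm``;
    optional ``species``, ``mg_mM`` and ``treatment`` columns define the
    conditions.
    """
    df = events.copy()
    for col, default in (("species", ""), ("mg_mM", np.nan), ("treatment", "")):
        if col not in df.columns:
            df[col] = default
    out = []
    for (species, mg, treatment), grp in df.groupby(
        ["species", "mg_mM", "treatment"], dropna=False, sort=True
    ):
        agg = (
            grp.groupby("trap_force_pn")["amplitude_nm"]
            .agg(["mean", "sem", "count"])
            .reset_index()
            .sort_values("trap_force_pn")
        )
        out.append(
            AmplitudeForceDataset(
                trap_force_pn=agg["trap_force_pn"].to_numpy(),
                mean_amplitude_nm=agg["mean"].to_numpy(),
                sem_nm=agg["sem"].fillna(0.0).to_numpy(),
                n_events=agg["count"].to_numpy(),
                species=str(species),
                mg_mM=float(mg) if np.isfinite(mg) else float("nan"),
                treatment=str(treatment),
            )
        )
    return out


@dataclass(frozen=True)
class ModelFitResult:
    """Fitted curl stiffness and mean contour length with 95% CIs."""

    kappa_pn_nm_per_rad: float
    kappa_ci95: tuple
    mean_length_dimers: float
    mean_length_ci95: tuple
    covariance: np.ndarray
    weighted_residual_sum: float
    dof: int

    def to_dict(self) -> dict:
        return {
            "kappa_pn_nm_per_rad": self.kappa_pn_nm_per_rad,
            "kappa_ci95": list(self.kappa_ci95),
            "mean_length_dimers": self.mean_length_dimers,
            "mean_length_ci95": list(self.mean_length_ci95),
            "covariance": np.asarray(self.covariance).tolist(),
            "weighted_residual_sum": self.weighted_residual_sum,
            "dof": self.dof,
        }


@dataclass(frozen=True)
class LineWorkResult:
    """Line-fit work-output summary of an amplitude-vs-force dataset."""

    intercept_nm: float
    intercept_ci95: tuple
    slope_nm_per_pn: float
    x_intercept_pn: float
    work_pn_nm: float
    work_ci95: tuple
    work_defined: bool

    def to_dict(self) -> dict:
        return {
            "intercept_nm": self.intercept_nm,
            "intercept_ci95": list(self.intercept_ci95),
            "slope_nm_per_pn": self.slope_nm_per_pn,
            "x_intercept_pn": self.x_intercept_pn,
            "work_pn_nm": self.work_pn_nm,
            "work_ci95": list(self.work_ci95),
            "work_defined": self.work_defined,
        }


def _model_heights(
    kappa: float, n_mean: float, config: TipConfig, lever: LeverGeometry, f_lat
):
    cfg = replace(config, mean_length_dimers=float(n_mean),
                  elastica=replace(config.elastica, kappa_pn_nm_per_rad=float(kappa)))
    curve = predicted_amplitude_curve(cfg, lever, np.asarray(f_lat) / lever.leverage)
    return curve.amplitude_nm / lever.leverage


def fit_model(
    data: AmplitudeForceDataset,
    config: TipConfig,
    lever: LeverGeometry,
    init: dict | None = None,
    bounds: dict | None = None,
    scale_covariance: bool = True,
) -> ModelFitResult:
    """Weighted nonlinear fit of (kappa, n_mean) to amplitude-vs-force data.

    Residuals are evaluated in the curl frame: amplitudes and SEMs are
    divided by the leverage and trap forces multiplied by it before the
    inverse-variance-weighted least squares.  ``scale_covariance=False``
    switches off the reduced-chi-square scaling of the covariance.
    """
    if data.n_levels < 3:
        raise ValueError("need at least 3 force levels to fit 2 parameters")
    sem_h = amplitude_to_height(data.sem_nm, lever)
    if np.any(~(sem_h > 0)):
        raise ValueError("degenerate weights: every SEM must be positive")
    h_obs = amplitude_to_height(data.mean_amplitude_nm, lever)
    f_lat = trap_to_lateral_force(data.trap_force_pn, lever)

    init = {**FIT_INIT, **(init or {})}
    bounds = {**FIT_BOUNDS, **(bounds or {})}

    def residuals(p):
        kappa, n_mean = p
        return (h_obs - _model_heights(kappa, n_mean, config, lever, f_lat)) / sem_h

    res = optimize.least_squares(
        residuals,
        x0=[init["kappa"], init["n_mean"]],
        bounds=(
            [bounds["kappa"][0], bounds["n_mean"][0]],
            [bounds["kappa"][1], bounds["n_mean"][1]],
        ),
        method="trf",
        x_scale=[100.0, 1.0],
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
    )
    if not res.success:
        raise RuntimeError(f"model fit did not converge: {res.message}")

    kappa_hat, n_hat = res.x
    dof = data.n_levels - 2
    ssr = float(2 * res.cost)  # sum of squared weighted residuals
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular Jacobian: parameters not identifiable") from exc
    if scale_covariance and dof > 0:
        cov = cov * (ssr / dof)
    tval = stats.t.ppf(0.975, dof) if dof > 0 else float("inf")
    se = np.sqrt(np.diag(cov))
    return ModelFitResult(
        kappa_pn_nm_per_rad=float(kappa_hat),
        kappa_ci95=(float(kappa_hat - tval * se[0]), float(kappa_hat + tval * se[0])),
        mean_length_dimers=float(n_hat),
        mean_length_ci95=(float(n_hat - tval * se[1]), float(n_hat + tval * se[1])),
        covariance=cov,
        weighted_residual_sum=ssr,
        dof=dof,
    )


def line_work_analysis(
    data: AmplitudeForceDataset, scale_covariance: bool = True
) -> LineWorkResult:
    """Weighted line fit ``A = a - b F`` and the area-under-the-line work.

    ``work = a^2 / (2 b)`` with variance
    ``(a/b)^2 var(a) + (a^2 / (2 b^2))^2 var(b)`` (parameters treated as
    uncorrelated).  A non-negative slope leaves the work undefined
    (``work_defined=False``).
    """
    if data.n_levels < 2:
        raise ValueError("need at least 2 force levels for a line fit")
    f = data.trap_force_pn
    a_obs = data.mean_amplitude_nm
    sem = data.sem_nm
    if np.any(~(sem > 0)):
        raise ValueError("degenerate weights: every SEM must be positive")

    # weighted least squares on design [1, -F]
    X = np.column_stack([np.ones_like(f), -f])
    w = 1.0 / sem**2
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * a_obs)
    beta = np.linalg.solve(xtwx, xtwy)
    a, b = beta
    cov = np.linalg.inv(xtwx)
    dof = data.n_levels - 2
    if scale_covariance and dof > 0:
        resid = a_obs - X @ beta
        chi2 = float(np.sum(w * resid**2))
        cov = cov * (chi2 / dof)
    var_a, var_b = np.diag(cov)
    tval = stats.t.ppf(0.975, dof) if dof > 0 else float("inf")

    if b <= 0:
        return LineWorkResult(
            intercept_nm=float(a),
            intercept_ci95=(
                float(a - tval * np.sqrt(var_a)),
                float(a + tval * np.sqrt(var_a)),
            ),
            slope_nm_per_pn=float(-b),
            x_intercept_pn=float("nan"),
            work_pn_nm=float("nan"),
            work_ci95=(float("nan"), float("nan")),
            work_defined=False,
        )
    work = a**2 / (2 * b)
    var_w = (a / b) ** 2 * var_a + (a**2 / (2 * b**2)) ** 2 * var_b
    hw = tval * np.sqrt(var_w)
    return LineWorkResult(
        intercept_nm=float(a),
        intercept_ci95=(
            float(a - tval * np.sqrt(var_a)),
            float(a + tval * np.sqrt(var_a)),
        ),
        slope_nm_per_pn=float(-b),
        x_intercept_pn=float(a / b),
        work_pn_nm=float(work),
        work_ci95=(float(work - hw), float(work + hw)),
        work_defined=True,
    )


def straightening_energy(
    kappa_pn_nm_per_rad: float, relaxed_angle_rad: float
) -> dict:
    """Per-interface harmonic strain for straightening one joint.

    Returns the energy ``1/2 kappa theta_i^2`` in pN·nm, k_BT (25 °C) and
    kcal/mol.  This is the harmonic estimate implied by one Hookean spring
    per dimer; it does not attempt to account for additional lattice
    coupling or non-harmonic terms.
    """
    if kappa_pn_nm_per_rad <= 0 or relaxed_angle_rad < 0:
        raise ValueError("kappa must be positive and angle nonnegative")
    e = 0.5 * kappa_pn_nm_per_rad * relaxed_angle_rad**2
    return {
        "pn_nm": e,
        "kbt": e / constants.KBT_PN_NM,
        "kcal_per_mol": e / constants.PN_NM_PER_KCAL_MOL,
    }
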