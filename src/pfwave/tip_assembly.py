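"""Multi-protofilament tip model: radial curls under a rigid flat bead.

Thirteen single-curl elastica models are arranged radially about the
microtubule axis.  The bead is treated as an infinitely flat, rigid surface
(its 440 nm diameter dwarfs the 25 nm microtubule) descending toward the
wall along the apex direction.  A curl at azimuth ``phi`` (measured from the
bead-facing apex) whose tip sits at radius ``R`` from the axis touches the
plane when ``R * cos(phi) >= plane_z``; contact compresses it radially until
``R = plane_z / cos(phi)``.  Only the radial force component normal to the
plane, ``F_single * cos(phi)``, loads the bead.

Because curls engage sequentially as the bead descends, the force-deflection
curve carries slight ripples whose pattern depends on the azimuthal rotation
of the tip; curves for rotation offsets {0, pi/13} are averaged (force at
matched bead height).  A non-integer mean curl length ``n_mean`` is realised
as the (1-frac, frac) mixture of the integer-length tip curves, mixed as
bead height at matched force so that the zero-force bead height is the
weighted mean of the component apical heights (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .bead_lever import LeverGeometry, trap_to_lateral_force
from .elastica import ElasticaParams, FDCurve, fd_curve_from_unit_curve

__all__ = [
    "CurlParams",
    "TipConfig",
    "TipFDCurve",
    "AmplitudeCurve",
    "engaged_protofilaments",
    "tip_force_curve",
    "predicted_amplitude_curve",
]


@dataclass(frozen=True)
class CurlParams:
    """Per-curl elastica parameters without a segment count."""

    segment_length_nm: float = constants.DEFAULT_SEGMENT_LENGTH_NM
    relaxed_angle_rad: float = constants.DEFAULT_RELAXED_ANGLE_RAD
    kappa_pn_nm_per_rad: float = 176.0

    def with_segments(self, n_segments: int) -> ElasticaParams:
        return ElasticaParams(
            segment_length_nm=self.segment_length_nm,
            relaxed_angle_rad=self.relaxed_angle_rad,
            kappa_pn_nm_per_rad=self.kappa_pn_nm_per_rad,
            n_segments=n_segments,
        )


def _default_offsets() -> tuple:
    return (0.0, math.pi / constants.DEFAULT_N_PROTOFILAMENTS)


@dataclass(frozen=True)
class TipConfig:
    """Geometry and mechanics of a multi-protofilament tip.

    ``mean_length_dimers`` may be non-integer; the model then mixes the two
    bracketing integer-length tip curves.
    """

    mean_length_dimers: float
    elastica: CurlParams = field(default_factory=CurlParams)
    n_protofilaments: int = constants.DEFAULT_N_PROTOFILAMENTS
    mt_radius_nm: float = constants.DEFAULT_MT_RADIUS_NM
    rotation_offsets_rad: tuple = field(default_factory=_default_offsets)

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1:
            raise ValueError("n_protofilaments must be >= 1")
        if self.mean_length_dimers < 1:
            raise ValueError("mean_length_dimers must be >= 1")
        if self.mean_length_dimers > 5:
            warnings.warn(
                "mean_length_dimers > 5 is outside the 1-5 dimer range the "
                "model was characterised for",
                stacklevel=2,
            )
        sector = 2 * math.pi / self.n_protofilaments
        for off in self.rotation_offsets_rad:
            if not 0 <= off < sector:
                raise ValueError(
                    "rotation offsets must lie within one protofilament sector"
                )

    def integer_lengths_and_weights(self):
        """Bracketing integer curl lengths and their mixture weights."""
        lo = int(math.floor(self.mean_length_dimers))
        frac = self.mean_length_dimers - lo
        if frac == 0.0:
            return [(lo, 1.0)]
        return [(lo, 1.0 - frac), (lo + 1, frac)]


@dataclass(frozen=True)
class TipFDCurve:
    """Whole-tip normal force vs bead height above the microtubule wall."""

    bead_height_nm: np.ndarray  # ascending
    normal_force_pn: np.ndarray  # non-increasing in height
    engaged_counts: np.ndarray

    def force_at(self, bead_height_nm):
        return np.interp(
            bead_height_nm, self.bead_height_nm, self.normal_force_pn
        )

    def height_at(self, force_pn):
        """Bead height at a given normal force, by monotone inversion.

        Forces beyond the tabulated range clip to the wall (height 0).
        """
        f = self.normal_force_pn[::-1]
        h = self.bead_height_nm[::-1]
        return np.interp(force_pn, f, h, right=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bead_height_nm": self.bead_height_nm,
                "normal_force_pn": self.normal_force_pn,
                "engaged_count": self.engaged_counts,
            }
        )


@dataclass(frozen=True)
class AmplitudeCurve:
    """Predicted axial pulse amplitude against trap force."""

    trap_force_pn: np.ndarray
    amplitude_nm: np.ndarray
    suppressed: np.ndarray  # True where the trap force fully suppresses the pulse

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trap_force_pn": self.trap_force_pn,
                "amplitude_nm": self.amplitude_nm,
                "suppressed": self.suppressed,
            }
        )


def _azimuths(n_protofilaments: int, offset_rad: float) -> np.ndarray:
    """Azimuths of all protofilaments, wrapped to (-pi, pi]."""
    phi = offset_rad + 2 * math.pi * np.arange(n_protofilaments) / n_protofilaments
    return (phi + math.pi) % (2 * math.pi) - math.pi


def engaged_protofilaments(
    config: TipConfig, curl_fd: FDCurve, plane_z_nm: float, offset_rad: float = 0.0
):
    """Protofilaments touched by a bead plane at ``plane_z_nm`` from the axis.

    Returns a list of ``(azimuth_rad, required_radial_deflection_nm)`` for
    every curl whose unloaded tip would cross the plane.  The required
    deflection is clamped to the solvable range of ``curl_fd``.
    """
    if plane_z_nm < config.mt_radius_nm:
        raise ValueError("bead plane lies below the microtubule wall")
    h0 = float(curl_fd.tip_height_nm[0])
    h_min = float(curl_fd.tip_height_nm[-1])
    r_tip = config.mt_radius_nm + h0
    out = []
    for phi in _azimuths(config.n_protofilaments, offset_rad):
        c = math.cos(phi)
        if c <= 0.0 or r_tip * c <= plane_z_nm:
            continue
        deflection = h0 - (plane_z_nm / c - config.mt_radius_nm)
        deflection = min(deflection, h0 - h_min)
        out.append((float(phi), float(deflection)))
    return out


def _integer_tip_curve(
    config: TipConfig, n_segments: int, bead_height_grid: np.ndarray
) -> TipFDCurve:
    """Rotation-averaged tip curve for curls of one integer length."""
    curl_fd = fd_curve_from_unit_curve(config.elastica.with_segments(n_segments))
    h0 = float(curl_fd.tip_height_nm[0])
    heights = np.asarray(bead_height_grid, dtype=float)
    plane_z = config.mt_radius_nm + heights

    force_acc = np.zeros_like(heights)
    count_acc = np.zeros_like(heights)
    for offset in config.rotation_offsets_rad:
        for phi in _azimuths(config.n_protofilaments, offset):
            c = math.cos(phi)
            if c <= 0.0:
                continue
            # curl tip height required for its tip to sit on the plane
            h_req = plane_z / c - config.mt_radius_nm
            engaged = h_req < h0
            h_clamped = np.clip(h_req, float(curl_fd.tip_height_nm[-1]), h0)
            f = curl_fd.force_at(h_clamped) * c
            force_acc += np.where(engaged, f, 0.0)
            count_acc += engaged
    n_off = len(config.rotation_offsets_rad)
    return TipFDCurve(
        bead_height_nm=heights,
        normal_force_pn=force_acc / n_off,
        engaged_counts=count_acc / n_off,
    )


def _mixture_height_at_force(curves, weights, force_pn):
    """Weighted mean of bead heights at a common normal force."""
    force_pn = np.asarray(force_pn, dtype=float)
    h = np.zeros_like(force_pn)
    for curve, w in zip(curves, weights):
        h = h + w * curve.height_at(force_pn)
    return h


def _component_curves(config: TipConfig, height_step_nm: float = 0.02):
    lengths = config.integer_lengths_and_weights()
    curves, weights = [], []
    for n_seg, w in lengths:
        curl_fd = fd_curve_from_unit_curve(config.elastica.with_segments(n_seg))
        h0 = float(curl_fd.tip_height_nm[0])
        grid = np.linspace(0.0, h0, max(2, int(round(h0 / height_step_nm)) + 1))
        curves.append(_integer_tip_curve(config, n_seg, grid))
        weights.append(w)
    return curves, weights


def tip_force_curve(config: TipConfig, height_step_nm: float = 0.02) -> TipFDCurve:
    """Whole-tip force vs bead height for the configured mean curl length.

    For a non-integer mean length, the bracketing integer-length curves are
    mixed as bead height at matched force and re-tabulated on a height grid,
    so that monotone inversion of the returned curve reproduces the mixture.
    """
    curves, weights = _component_curves(config, height_step_nm)
    if len(curves) == 1:
        return curves[0]

    f_max = min(float(c.normal_force_pn[0]) for c in curves)
    force_grid = np.linspace(0.0, f_max, 2048)
    h_mix = _mixture_height_at_force(curves, weights, force_grid)
    count_mix = sum(
        w * np.interp(force_grid, c.normal_force_pn[::-1], c.engaged_counts[::-1])
        for c, w in zip(curves, weights)
    )
    # re-tabulate force (and counts) on an ascending bead-height grid
    heights = np.linspace(0.0, h_mix[0], max(2, int(round(h_mix[0] / height_step_nm)) + 1))
    order = np.argsort(h_mix)
    force = np.interp(heights, h_mix[order], force_grid[order])
    counts = np.interp(heights, h_mix[order], count_mix[order])
    return TipFDCurve(
        bead_height_nm=heights, normal_force_pn=force, engaged_counts=counts
    )


def predicted_amplitude_curve(
    config: TipConfig, lever: LeverGeometry, trap_force_grid_pn
) -> AmplitudeCurve:
    """Axial pulse amplitude predicted at each trap force.

    The trap force is converted to a lateral force on the tip, the bead
    height is found by monotone inversion of the (mixture) tip curve, and
    the height is converted back to an axial amplitude.  Trap forces beyond
    the curve's range give amplitude 0 and are flagged as suppressed.
    """
    trap = np.atleast_1d(np.asarray(trap_force_grid_pn, dtype=float))
    f_lat = trap_to_lateral_force(trap, lever)
    curves, weights = _component_curves(config)
    h = _mixture_height_at_force(curves, weights, f_lat)
    amp = h * lever.leverage
    suppressed = amp <= 0.0
    return AmplitudeCurve(
        trap_force_pn=trap, amplitude_nm=amp, suppressed=suppressed
    )
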