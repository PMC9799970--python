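"""Trap-frame / curl-frame conversions via the tethered-bead lever.

In the wave assay the bead is tethered to the microtubule wall by a ~36 nm
flexible link and pressed against the lattice at a secondary contact point.
Curling protofilaments push the bead laterally, and the bead rocks about its
tether, so the measured axial bead displacement exceeds the lateral curl
height by a geometric leverage factor of about two.  Work is frame-invariant
by construction: the force conversion is the virtual-work complement of the
displacement conversion, ``f_trap * amplitude == f_lateral * height``.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants

__all__ = [
    "LeverGeometry",
    "amplitude_to_height",
    "height_to_amplitude",
    "trap_to_lateral_force",
]


@dataclass(frozen=True)
class LeverGeometry:
    """Bead/tether geometry of the wave assay.

    ``leverage`` is the dimensionless axial-amplitude / lateral-height
    amplification factor (~2 for 0.44 µm beads on a 36 nm tether).
    """

    bead_radius_nm: float = constants.DEFAULT_BEAD_RADIUS_NM
    tether_length_nm: float = constants.DEFAULT_TETHER_LENGTH_NM
    leverage: float = constants.DEFAULT_LEVERAGE

    def __post_init__(self) -> None:
        if self.bead_radius_nm <= 0 or self.tether_length_nm <= 0:
            raise ValueError("bead_radius_nm and tether_length_nm must be positive")
        if self.leverage < 1:
            raise ValueError("leverage must be >= 1")


def _check_nonnegative(x, name: str):
    import numpy as np

    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be nonnegative")


def amplitude_to_height(amp_nm, lever: LeverGeometry):
    """Convert an axial bead amplitude to a bead-to-wall lateral height."""
    _check_nonnegative(amp_nm, "amplitude")
    return amp_nm / lever.leverage


def height_to_amplitude(height_nm, lever: LeverGeometry):
    """Convert a bead-to-wall lateral height to an axial bead amplitude."""
    _check_nonnegative(height_nm, "height")
    return height_nm * lever.leverage


def trap_to_lateral_force(f_trap_pn, lever: LeverGeometry):
    """Convert trap force to the lateral force loading the curls.

    Defined as ``leverage * f_trap`` so that work computed in either frame
    is identical.
    """
    _check_nonnegative(f_trap_pn, "force")
    return f_trap_pn * lever.leverage
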