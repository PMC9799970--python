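"""Physical constants and package-wide defaults.

Units are fixed package-wide: nanometres, piconewtons, pN·nm for energy,
radians for angles (degrees accepted in configuration files only).
"""

import math

#: Thermal energy at 25 °C, pN·nm.
KBT_PN_NM = 4.114

#: Energy conversion: 1 kcal/mol expressed in pN·nm per molecule.
PN_NM_PER_KCAL_MOL = 6.95

#: Length of one tubulin dimer segment along a protofilament, nm.
DEFAULT_SEGMENT_LENGTH_NM = 8.2

#: Intrinsic (relaxed) bend per inter-dimer interface, radians (23 degrees).
DEFAULT_RELAXED_ANGLE_RAD = math.radians(23.0)

#: Number of protofilaments in the canonical microtubule wall.
DEFAULT_N_PROTOFILAMENTS = 13

#: Outer wall radius of a 13-protofilament microtubule, nm.
DEFAULT_MT_RADIUS_NM = 12.5

#: Bead radius for the 0.44 µm beads used in the wave assay, nm.
DEFAULT_BEAD_RADIUS_NM = 220.0

#: Length of the single-antibody tubulin tether, nm.
DEFAULT_TETHER_LENGTH_NM = 36.0

#: Axial-bead-displacement / lateral-curl-height amplification factor.
DEFAULT_LEVERAGE = 2.0
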