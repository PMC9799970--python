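import math

import numpy as np
import pytest

from pfwave.bead_lever import LeverGeometry
from pfwave.elastica import ElasticaParams
from pfwave.tip_assembly import CurlParams, TipConfig

THETA23 = math.radians(23.0)


@pytest.fixture(scope="session")
def lever():
    return LeverGeometry()


@pytest.fixture(scope="session")
def bovine_tip():
    """Tip model at the bovine 1 mM magnesium operating point."""
    return TipConfig(
        mean_length_dimers=2.3,
        elastica=CurlParams(kappa_pn_nm_per_rad=176.0),
    )


@pytest.fixture
def params_factory():
    def make(n_segments, kappa=176.0, theta_i=THETA23, r=8.2):
        return ElasticaParams(
            segment_length_nm=r,
            relaxed_angle_rad=theta_i,
            kappa_pn_nm_per_rad=kappa,
            n_segments=n_segments,
        )

    return make


def total_potential(theta, params, force_pn):
    """Independent total-potential oracle: spring energy + F * tip height."""
    theta = np.asarray(theta, float)
    phi = np.cumsum(theta)
    spring = 0.5 * params.kappa_pn_nm_per_rad * np.sum(
        (theta - params.relaxed_angle_rad) ** 2
    )
    return spring + force_pn * params.segment_length_nm * np.sum(np.sin(phi))
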