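import numpy as np
import pytest

from depauperon.birthdeath_core import BirthDeathParams, DiversificationFit, GridSpec


@pytest.fixture
def point_fit():
    """A degenerate fit whose profile region is the single point r=0.1, lam=0.1.

    At eps = 0 and t = ln(2)/0.1 the geometric parameter is beta = 0.5, so the
    clade-size bounds are (~1.0365, ~6.3219) and widest == point bounds.
    """
    return DiversificationFit(
        params_hat=BirthDeathParams(0.1, 0.1),
        loglik_max=0.0,
        profile_ci={"r": (0.1, 0.1), "lam": (0.1, 0.1), "mu": (0.0, 0.0), "eps": (0.0, 0.0)},
        grid_spec=GridSpec(),
        region_r=np.array([0.1]),
        region_lam_lo=np.array([0.1]),
        region_lam_hi=np.array([0.1]),
        n_clades=1,
        dataset_id="ds1",
        interval_id=0,
    )


@pytest.fixture
def t_half():
    """Age at which beta = 0.5 for r = 0.1, eps = 0."""
    return float(np.log(2) / 0.1)
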