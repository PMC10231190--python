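import numpy as np
import pytest

import thermotrait as tt

ASSAY_T = np.arange(0.0, 50.0, 5.0)


@pytest.fixture
def exact_curve():
    """Noise-free full-model bacterial curve, a=0.05, b=0.15, Tmin=-10, Tmax=48."""
    R = np.clip(tt.ratkowsky_sqrt_rate(ASSAY_T, 0.05, -10.0, 0.15, 48.0), 0, None) ** 2
    return tt.RateCurve("siteA", "bacterial_growth", ASSAY_T, R)


@pytest.fixture
def small_survey():
    """Six-site noise-free survey with its true parameters."""
    cfg = tt.SurveyConfig(seed=11, n_sites=6)
    sites = tt.generate_sites(cfg)
    params = tt.generate_trait_params(sites, cfg)
    table = tt.generate_curves(params, cfg, noise_sd=0.0)
    return cfg, sites, params, table


@pytest.fixture
def default_survey():
    """One default 72-site survey (measurement noise on) with fitted indices."""
    cfg = tt.SurveyConfig(seed=1)
    sites = tt.generate_sites(cfg)
    params = tt.generate_trait_params(sites, cfg)
    table = tt.generate_curves(params, cfg)
    indices = tt.fit_survey(tt.curves_from_table(table))
    return cfg, sites, params, indices
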