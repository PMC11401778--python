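import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from octffr import (CoronaryCase, PressureWaveforms, SolverSettings,
                    SyntheticLesionSpec, generate_waveforms, synth_lumen_profile)

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def wf_hyperemia():
    """Driver waveform at the cohort-mean hyperemic state (HR 75, Pa 83)."""
    return generate_waveforms(75.0, 83.0)


@pytest.fixture(scope="session")
def constant_inlet():
    """One 'cycle' of constant aortic pressure with zero LV pressure."""
    n = 800
    return PressureWaveforms(time=np.arange(n) * 1e-3, pa=np.full(n, 100.0),
                             plv=np.zeros(n), heart_rate=75.0, cycle_length=0.8)


def make_case(depth=0.5, territory="LAD", a_prox=10.57, a_dist=5.69,
              roi=50.0, width=3.0, seed=0, noise_sd=0.0, **kw):
    spec = SyntheticLesionSpec(roi_length=roi, a_prox_ref=a_prox,
                               a_dist_ref=a_dist, center=roi / 2, depth=depth,
                               width=width, noise_sd=noise_sd, seed=seed, **kw)
    return CoronaryCase(profile=synth_lumen_profile(spec), a_prox_ref=a_prox,
                        a_dist_ref=a_dist, territory=territory)


@pytest.fixture(scope="session")
def moderate_lad_case():
    return make_case(depth=0.75)


@pytest.fixture
def settings():
    return SolverSettings()
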