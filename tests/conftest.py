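import numpy as np
import pytest

from semscoretree import TemplateModel, fit_ml
from semscoretree.simulate import LGCMParams, CFAParams, generate_model_data


@pytest.fixture(scope="session")
def lgcm_template():
    return TemplateModel.lgcm()


@pytest.fixture(scope="session")
def cfa_template():
    return TemplateModel.cfa_two_factor()


@pytest.fixture(scope="session")
def lgcm_fit():
    """One converged LGCM fit on N=504 homogeneous data, with case data."""
    rng = np.random.default_rng(42)
    Y = generate_model_data(LGCMParams(), 504, rng)
    fit = fit_ml(TemplateModel.lgcm(), Y)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def cfa_fit():
    rng = np.random.default_rng(43)
    Y = generate_model_data(CFAParams(phi=0.3), 500, rng)
    fit = fit_ml(TemplateModel.cfa_two_factor(), Y)
    assert fit.converged
    return fit
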