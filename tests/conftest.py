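import warnings

import pytest

from myospring.control import ControlModel, fit_control_model
from myospring.evaluation import EvaluationModel, ModelDomainWarning


@pytest.fixture(scope="session")
def em() -> EvaluationModel:
    return EvaluationModel()


@pytest.fixture(scope="session")
def cm() -> ControlModel:
    """Control Model with the shipped (printed-table) coefficients."""
    return ControlModel()


@pytest.fixture(scope="session")
def pipeline_result(em):
    """One run of the full extraction + refit pipeline on the default model."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelDomainWarning)
        return fit_control_model(em)
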