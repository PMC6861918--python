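import pytest

from tbitriage.signatures import DifferentialExpressionRecord


@pytest.fixture
def nrf2_axis_records():
    """The four Nrf2-axis genes' published acute (32-h) DE results."""
    return [
        DifferentialExpressionRecord("Nfe2l2", 0.094, 6.41e-1),
        DifferentialExpressionRecord("Gclm", 0.818, 1.88e-8),
        DifferentialExpressionRecord("Hmox1", 2.860, 1.69e-9),
        DifferentialExpressionRecord("Nqo1", 0.424, 6.45e-3),
    ]


@pytest.fixture
def desmethylclomipramine_points():
    """Published component points for the top-ranked compound."""
    return {
        "concordance_acute": 0,
        "concordance_chronic": 3,
        "bbb": 5,
        "water_solubility": 5,
        "tnfa": 2,
        "nitrite": 1,
        "viability": 0,
        "engagement_inflammatory_Nfe2l2": 1,
        "engagement_non_inflammatory_Nfe2l2": 1,
    }
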