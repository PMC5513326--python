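import pytest

from pairedsse import DesignHypotheses, PairedCounts


@pytest.fixture
def app_hypotheses() -> DesignHypotheses:
    """Design of the pancreatic-cancer PET/CT application: sensitivity
    0.81 -> 0.90, specificity 0.66 -> 0.80, prevalence 0.47."""
    return DesignHypotheses(alpha=0.05, beta=0.2, tpr_a=0.9, tpr_b=0.81,
                            tnr_a=0.8, tnr_b=0.66, prevalence=0.47)


@pytest.fixture
def sim_hypotheses() -> DesignHypotheses:
    """Same design with the simulation-study prevalence of 0.45."""
    return DesignHypotheses(alpha=0.05, beta=0.2, tpr_a=0.9, tpr_b=0.81,
                            tnr_a=0.8, tnr_b=0.66, prevalence=0.45)


@pytest.fixture
def interim_counts() -> PairedCounts:
    """The 187-subject interim table of the application (82 diseased)."""
    return PairedCounts(66, 3, 3, 10, 21, 4, 11, 69)
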