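import numpy as np
import pytest

from crosslag import (ModelKind, default_truth, implied_moments,
                      sample_moments, simulate_panel)

ALL_KINDS = [ModelKind.CLPM, ModelKind.RI_CLPM, ModelKind.STARTS]


@pytest.fixture(scope="session")
def truths():
    """Study-default truth parameters for each kind at T=4."""
    return {
        ModelKind.CLPM: default_truth("clpm", 0.5, 0.2, T=4),
        ModelKind.RI_CLPM: default_truth("ri_clpm", 0.5, 0.2, T=4),
        ModelKind.STARTS: default_truth("starts", 0.5, 0.2, 0.2, T=4),
    }


@pytest.fixture(scope="session")
def truth_moments(truths):
    return {kind: implied_moments(p, 4, kind) for kind, p in truths.items()}


@pytest.fixture(scope="session")
def clpm_panel(truths):
    """A moderate CLPM-generated panel reused across estimation tests."""
    return simulate_panel(truths[ModelKind.CLPM], "clpm", N=800, T=4, seed=321)


@pytest.fixture(scope="session")
def clpm_panel_moments(clpm_panel):
    return sample_moments(clpm_panel)
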