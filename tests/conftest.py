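import pytest
from hypothesis import settings

from cbmn_screen import from_inverse_coefficients

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# the published inverse dosimetry line D = -429.54 + 64.37 y (mGy)
PUBLISHED_A = -429.54
PUBLISHED_B = 64.37


@pytest.fixture
def published_curve():
    return from_inverse_coefficients(PUBLISHED_A, PUBLISHED_B)
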