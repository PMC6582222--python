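import hypothesis
import pytest

from smdfe import synth

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    """The packaged gas/solution step-energetics tables."""
    return synth.paper_tables()
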