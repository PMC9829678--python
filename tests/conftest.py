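import pytest

from introtrace import pipeline, synthetic


@pytest.fixture(scope="session")
def default_panel():
    """The study-like default synthetic panel (149 lines, 7 x 60 windows)."""
    return synthetic.generate_panel(synthetic.default_config(seed=0))


@pytest.fixture(scope="session")
def default_result(default_panel):
    """End-to-end mapping result on the default panel."""
    return pipeline.run_panel(default_panel)
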