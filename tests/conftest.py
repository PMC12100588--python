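import pytest

from larchfire import pipeline, synthetic


@pytest.fixture(scope="session")
def default_campaign():
    """One default synthetic campaign (41 burned + 12 control plots)."""
    campaign, ledger = synthetic.generate_campaign(seed=42)
    return campaign, ledger


@pytest.fixture(scope="session")
def compiled_campaign(default_campaign):
    campaign, _ = default_campaign
    return pipeline.compile_campaign(campaign)


@pytest.fixture(scope="session")
def pipeline_results(compiled_campaign):
    return pipeline.run_pipeline(compiled_campaign)
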