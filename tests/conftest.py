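import pytest

from spssodm.fixtures import make_sample_dataset


@pytest.fixture
def sample_ds():
    return make_sample_dataset()


@pytest.fixture
def sample_odm(sample_ds):
    """Sample dataset fully converted with data, keyed on PID."""
    from spssodm.forward import ConvertOptions, convert

    odm_file, report = convert(
        sample_ds,
        ConvertOptions(include_data=True, subjectkey="PID", lang="en"),
        timestamp="2017-01-07T00:00:00",
    )
    return odm_file, report
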