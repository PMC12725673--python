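import pytest

from vcclek.synthetic_data import default_config, generate_survey, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    """The published survey tables as an in-memory bundle."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey shared by fast tests (fixed seed)."""
    cfg = default_config()
    cfg.n_villages = 4
    cfg.fishers_per_village = 25
    return generate_survey(cfg, seed=42)


@pytest.fixture()
def survey_paths(small_survey, tmp_path):
    """The small survey written to disk in the loader formats."""
    return small_survey.write(tmp_path / "survey")
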