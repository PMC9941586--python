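import numpy as np
import pytest

import pelacarb as pc


@pytest.fixture(scope="session")
def survey_cfg():
    return pc.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def survey(survey_cfg):
    return pc.gen_survey(survey_cfg)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, survey_cfg):
    """Synthetic input bundle on disk plus its truth record."""
    from pelacarb import io

    outdir = tmp_path_factory.mktemp("bundle")
    truth = io.write_bundle(survey_cfg, outdir)
    return outdir, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
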