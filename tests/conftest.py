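import logging

import pytest

from nursemap.synthetic import SynthConfig, generate_dataset

# the noise-clause zero-vector warnings are expected under the one-hot
# embedder and would otherwise drown test output
logging.getLogger("nursemap.retrieval").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return SynthConfig(
        n_diagnoses=12,
        n_interventions=15,
        n_records=30,
        n_corpus_examples=40,
        noise_clause_rate=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


TERMINOLOGY_CSV = """\
code,label,category,care_component,source_vocab,description
D01,impaired skin integrity,diagnosis,physiological,CCC,break in skin surface
D02,risk of infection,diagnosis,physiological,CCC,
I01,monitor vital signs,intervention,physiological,CCC,
I02,reposition patient,intervention,functional,NIC,turn every two hours
"""


@pytest.fixture()
def tiny_terms():
    import io

    from nursemap.terminology import load_terminology

    return load_terminology(io.StringIO(TERMINOLOGY_CSV))
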