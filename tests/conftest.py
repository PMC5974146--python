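import numpy as np
import pytest

from plantmito import coexpression as cx, pipeline, synthetic


@pytest.fixture(scope="session")
def small_study():
    """A compact generated study: 60+60 gene-mapped records, class-biased
    profiles and the meta-PCC matrix from 3 expression datasets."""
    config = synthetic.GeneratorConfig(n_pos=60, n_neg=60, seed=7)
    records, profiles, meta = synthetic.generate_study(config)
    return config, records, profiles, meta


@pytest.fixture(scope="session")
def small_feature_set(small_study):
    _, records, profiles, meta = small_study
    knn_config = pipeline.training_knn_config(records)
    return pipeline.build_feature_set(records, profiles, meta, knn_config)


@pytest.fixture()
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">p1\nMKLVAAAAAG\nRRKK\n>p2\nacdefghikl\n")
    return path
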