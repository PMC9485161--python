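import numpy as np
import pandas as pd
import pytest

from ribohet import rp_quant, synthetic_data as sd


@pytest.fixture(scope="session")
def annotation():
    return rp_quant.load_annotation(core_only=True)


@pytest.fixture(scope="session")
def rp_ids(annotation):
    return annotation["rp_id"].tolist()


@pytest.fixture(scope="session")
def ribo_dataset():
    """One deterministic zero-jitter footprint dataset with planted truth."""
    cfg = sd.SimConfig(seed=11)
    reads, models, lib_meta, truth = sd.generate_reads(cfg)
    return cfg, reads, models, lib_meta, truth


@pytest.fixture()
def tiny_reads():
    """Hand-built reads for boundary tests: one transcript, known CDS."""
    model = pd.DataFrame({
        "transcript_id": ["tx1"], "transcript_length": [600],
        "cds_start": [100], "cds_end": [400],
        "utr5_sequence": ["A" * 100],
    })

    def make(five_prime, length=28, library="L1", n=1):
        return pd.DataFrame({
            "transcript_id": ["tx1"] * n,
            "five_prime_pos": [five_prime] * n,
            "length": [length] * n,
            "library_id": [library] * n,
        })

    return model, make


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
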