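import numpy as np
import pytest

from aetrans.model import ArchitectureConfig, AETransModel
from aetrans.preprocess import standardize_features
from aetrans.synthdata import SynthConfig, generate_unpaired_cohort
from aetrans.training import TrainConfig


TINY_ARCH = ArchitectureConfig(
    rna_input_dim=30,
    meth_input_dim=30,
    ae_hidden_dim=8,
    n_tokens=2,
    d_model=4,
    n_encoder_layers=1,
    n_decoder_layers=1,
    n_heads=2,
    ffn_hidden_dim=8,
    mlp_hidden_dims=(8,),
    mask_rate=0.0,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small standardized two-modality cohort with known informative genes."""
    rna, meth, truth = generate_unpaired_cohort(
        SynthConfig(
            n_rna_samples=40,
            n_meth_samples=30,
            n_genes=30,
            n_informative_rna=6,
            n_informative_meth=6,
            seed=11,
        )
    )
    rna, _ = standardize_features(rna)
    meth, _ = standardize_features(meth)
    return rna, meth, truth


@pytest.fixture
def tiny_model():
    return AETransModel(TINY_ARCH, seed=0)


@pytest.fixture(scope="session")
def trained_tiny(tiny_cohort):
    """One quick train/test run on the tiny cohort, shared across tests."""
    from aetrans.training import train_test_run

    rna, meth, _ = tiny_cohort
    cfg = TrainConfig(max_epochs=15, early_stop_patience=6, l2_strength=1e-2, seed=0)
    return train_test_run(rna, meth, TINY_ARCH, cfg)
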