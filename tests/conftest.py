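import numpy as np
import pytest

import stoichiomap as sm


@pytest.fixture(scope="session")
def small_cfg():
    """A fast study: 8 conditions, 120 proteins, 64 cells, 300 channels."""
    return sm.GeneratorConfig(
        n_proteins=120,
        m_conditions=8,
        core_size=30,
        specific_group_sizes=(10, 6),
        cells_per_condition=4,
        replicates=2,
        channel_count=300,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return sm.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Preprocessed spectra, fitted LDA, scores, and condition means."""
    ds = small_dataset
    processed = sm.SpectraPreprocessor().transform(ds["spectra"])
    lda = sm.ConditionLDA().fit(processed.intensities, processed.condition)
    scores = lda.transform(processed.intensities)
    cond_order = ds["conditions"]["condition_id"].to_numpy()
    R_hat = sm.condition_means(scores, processed.condition, cond_order)
    return {
        "processed": processed,
        "lda": lda,
        "scores": scores,
        "R_hat": R_hat,
        "P_hat": ds["proteome"].to_numpy(dtype=float).T,
        "conditions": ds["conditions"],
        "proteome": ds["proteome"],
        "truth": ds["truth"],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
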