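import pytest

import castekit as ck


@pytest.fixture(scope="session")
def small_sim():
    """Small 4-species dataset with planted toolkit and realistic messiness."""
    cfg = ck.SimulationConfig(
        n_species=4,
        n_orthogroups=300,
        toolkit_size=30,
        private_caste_frac=0.05,
        effect_log2fc=1.0,
        lib_size=300_000,
        seed=42,
    )
    counts, ogmap, truth = ck.generate_dataset(cfg)
    return cfg, counts, ogmap, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, counts, ogmap, _ = small_sim
    hm = ck.harmonize(counts, ogmap, mode="isoforms3_na2")
    return ck.normalize_pipeline(hm)


@pytest.fixture(scope="session")
def planted_norm():
    """Six-species dataset with a 150-gene toolkit, normalised, plus its truth."""
    cfg = ck.SimulationConfig(
        n_species=6,
        n_orthogroups=2000,
        toolkit_size=150,
        effect_log2fc=1.0,
        dispersion=0.1,
        seed=7,
    )
    counts, ogmap, truth = ck.generate_dataset(cfg)
    hm = ck.harmonize(counts, ogmap, mode="isoforms3_na2")
    return ck.normalize_pipeline(hm), truth
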