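import pytest

from te_exonize.synthetic import FamilyParams, SyntheticConfig, simulate_bundle


def small_config(**overrides) -> SyntheticConfig:
    """A reduced-scale generator config for fast per-test simulation:
    one 2 Mb chromosome, 150 elements per family, 300 transcripts."""
    cfg = SyntheticConfig(
        genome=[("chr1", 2_000_000)],
        te_families={
            fam: FamilyParams(150, p.length_mean, p.length_sd,
                              p.millidiv_mean, p.millidiv_sd)
            for fam, p in SyntheticConfig().te_families.items()
        },
        n_transcripts=300,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def bundle():
    """One default-scale synthetic study shared across read-only tests."""
    return simulate_bundle(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(small_config(seed=11))
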