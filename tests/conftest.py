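import pytest

from mupan.pipeline import AnalysisConfig, analyze_family
from mupan.simulate import FamilyConfig, GroupSplit, RgpSpec, simulate_family


def small_family_config(seed: int = 42, **overrides) -> FamilyConfig:
    """A 6-genome, 12-core family: the study architecture at unit-test size.

    The frameshift pair lands on core 11/12 and the internal start on
    core 9 (the study-scale defaults clamped to the backbone size).
    """
    defaults = dict(
        n_genomes=6,
        n_core=12,
        rgp_layout=[
            RgpSpec("A", anchor_after=2, n_types=1, p_insert=0.6),
            RgpSpec("B", anchor_after=5, n_types=3, p_insert=0.9, k_range=(1, 2)),
            RgpSpec("C", anchor_after=7, n_types=2, p_insert=0.6, low_gc=True),
        ],
        core_codons_range=(60, 200),
        seed=seed,
    )
    defaults.update(overrides)
    return FamilyConfig(**defaults)


@pytest.fixture(scope="session")
def small_family():
    cfg = small_family_config()
    genomes, orf_sets, truth = simulate_family(cfg)
    return cfg, genomes, orf_sets, truth


@pytest.fixture(scope="session")
def small_analysis(small_family):
    _, genomes, _, _ = small_family
    return analyze_family(genomes, AnalysisConfig(bootstrap_reps=200, seed=9))


@pytest.fixture(scope="session")
def study_family():
    cfg = FamilyConfig(seed=7)
    genomes, orf_sets, truth = simulate_family(cfg)
    return cfg, genomes, orf_sets, truth


@pytest.fixture(scope="session")
def study_analysis(study_family):
    _, genomes, _, _ = study_family
    return analyze_family(genomes, AnalysisConfig(bootstrap_reps=500, seed=11))
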