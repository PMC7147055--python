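import pytest

from afrocnv.synthetic_cohort import CohortConfig, generate


def small_config(seed=11, **overrides):
    """A desk-scale cohort: one 2 Mb chromosome, 3 populations x 12 samples."""
    defaults = dict(
        seed=seed,
        chromosomes=("chr1",),
        chrom_length=2_000_000,
        n_per_population=12,
        n_true_cnvrs=30,
        n_known_decoys=10,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(small_config())


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Caller noise switched off: calls reproduce truth exactly."""
    return generate(
        small_config(
            seed=13,
            caller_a_jitter_sd=0.0,
            caller_a_frac_noise_sd=0.0,
            fp_rate=0.0,
            n_outlier_samples=0,
            snp_missing_rate=0.0,
        )
    )
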