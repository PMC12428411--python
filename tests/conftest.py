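import pytest
from hypothesis import settings

from prrtkit.synth import GeneratorConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def tiny_generator_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A small, fast cohort config used across the suite (40 patients)."""
    kwargs = dict(
        n_patients=40,
        n_noise={"Onco": 2, "Path": 2, "Imm": 2, "Lab": 2},
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_generator_config())


@pytest.fixture(scope="session")
def clean_cohort():
    """Same structure, but without any injected missingness."""
    return generate_cohort(tiny_generator_config(seed=11, apply_missingness=False))
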