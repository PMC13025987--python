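import pytest

from aromastages import SimulationConfig, generate_dataset
from aromastages.datamodel import ChemicalClass
from aromastages.quant import normalize_to_internal_standard, relative_content

NEUTRAL_CLASS_TRENDS = {c: (1.0, 1.0) for c in ChemicalClass}


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default-design dataset (2 batches x 3 stages x 3 reps,
    134 compounds + internal standard)."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_contents(default_dataset):
    """Percent relative contents of the default dataset."""
    table, compounds, samples, truth = default_dataset
    rel = relative_content(normalize_to_internal_standard(table))
    return rel, compounds, samples, truth


def neutral_config(**kwargs) -> SimulationConfig:
    """Config whose only stage effects are the planted ones: class-level
    trends switched off so non-planted compounds are truly null."""
    kwargs.setdefault("class_stage_multipliers", dict(NEUTRAL_CLASS_TRENDS))
    return SimulationConfig(**kwargs)
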