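import pandas as pd
import pytest

from mescore.synthetic_data import CommunitySpec, EffectSpec, generate


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    """Hand-countable flux records: two samples, one metabolite."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1", "s2", "s2"],
            "taxon_id": ["A", "B", "D", "A", "B"],
            "metabolite_id": ["h2s"] * 5,
            "direction": ["export", "import", "import", "export", "import"],
            "flux": [0.5, 0.3, 0.1, 2.0, 1.0],
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-sample null community shared across read-only tests."""
    spec = CommunitySpec(n_species=60, n_metabolites=12, richness_range=(20, 60))
    return generate(spec, [], {"healthy": 10, "disease": 10}, seed=42)


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong consumer loss (70%) planted on one metabolite in the disease cohort."""
    spec = CommunitySpec(n_species=150, n_metabolites=20, richness_range=(34, 150))
    effect = EffectSpec(
        metabolite="m004", cohort="disease", consumer_loss_fraction=0.7
    )
    return generate(spec, [effect], {"healthy": 40, "disease": 40}, seed=7)
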