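import pandas as pd
import pytest

from itvpart import cwm, partition, synthgen


@pytest.fixture(scope="session")
def default_records() -> pd.DataFrame:
    return synthgen.simulate_transplant(synthgen.default_params(seed=1))


@pytest.fixture(scope="session")
def transformed_records(default_records) -> pd.DataFrame:
    return partition.apply_transform(default_records, synthgen.TRAIT_TRANSFORMS)


@pytest.fixture()
def toy_community() -> cwm.CommunityDataset:
    """Two sites, two species, hand-checkable numbers.

    Specific CWMs are (11.6, 18.4), fixed CWMs (12, 18); the decomposition
    of the specific series is SS (23.12, 18, 0.32, 4.8).
    """
    sites = pd.DataFrame({"site": ["s1", "s2"], "gradient": [0.0, 1.0]})
    abundance = pd.DataFrame(
        [[0.8, 0.2], [0.2, 0.8]], index=["s1", "s2"], columns=["A", "B"]
    )
    traits = {
        "trait": pd.DataFrame(
            [[10.0, 18.0], [12.0, 20.0]], index=["s1", "s2"], columns=["A", "B"]
        )
    }
    means = {"trait": pd.Series([10.0, 20.0], index=["A", "B"])}
    return cwm.CommunityDataset(
        sites=sites, abundance=abundance, traits=traits, species_means=means
    )


def percent_e_per_trait(params) -> dict[str, float]:
    """Full pipeline %E for each trait of one simulated transplant study."""
    records = synthgen.simulate_transplant(params)
    rt = partition.apply_transform(records, synthgen.TRAIT_TRANSFORMS)
    out = {}
    for trait in params.trait_names:
        model = partition.fit_trait_model(
            rt, partition.ModelSpec(response=f"{trait}_transformed")
        )
        table = partition.type3_anova(model)
        out[trait] = partition.percent_plasticity(table, trait).percent_e
    return out
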