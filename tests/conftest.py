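import numpy as np
import pandas as pd
import pytest

from metaomix.core import AbundanceMatrix, SampleMetadata, TaxonNode, TaxonomyTree
from metaomix.simulate import Community, CommunitySpec, EffectSpec, make_asv_counts, make_community


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """root -> Bacteria -> {Family_A -> {g1, g2}, Family_B -> {g3}}; species under g1."""
    nodes = {
        "root": TaxonNode("root", "unranked", "root"),
        "Bacteria": TaxonNode("Bacteria", "domain", "root"),
        "Family_A": TaxonNode("Family_A", "family", "Bacteria"),
        "Family_B": TaxonNode("Family_B", "family", "Bacteria"),
        "g1": TaxonNode("g1", "genus", "Family_A"),
        "g2": TaxonNode("g2", "genus", "Family_A"),
        "g3": TaxonNode("g3", "genus", "Family_B"),
        "g1_s1": TaxonNode("g1_s1", "species", "g1"),
        "g1_s2": TaxonNode("g1_s2", "species", "g1"),
    }
    return TaxonomyTree(nodes)


@pytest.fixture(scope="session")
def community(tmp_path_factory) -> Community:
    """Deterministic synthetic community with proteomes and a host."""
    out = tmp_path_factory.mktemp("community")
    return make_community(CommunitySpec(seed=7, duplicate_fraction=0.15), out)


@pytest.fixture(scope="session")
def asv_experiment(community):
    """Two-group ASV experiment with one planted 4-fold genus effect."""
    feature_taxa = {
        f"ASV_{g}_{i + 1}": g for g in community.genera for i in range(2)
    }
    effects = EffectSpec(seed=21, n_per_group=12, effects={"Genus_05": 2.0})
    matrix, metadata, truth = make_asv_counts(
        community.tree, feature_taxa, effects
    )
    return {
        "matrix": matrix,
        "metadata": metadata,
        "truth": truth,
        "feature_taxa": feature_taxa,
    }


@pytest.fixture()
def counts_3x2() -> AbundanceMatrix:
    return AbundanceMatrix(
        pd.DataFrame(
            [[3.0, 1.0], [4.0, 0.0], [2.0, 5.0]],
            index=["f1", "f2", "f3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture()
def two_group_metadata() -> SampleMetadata:
    rng = np.random.default_rng(5)
    samples = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
    table = pd.DataFrame(
        {
            "group": ["A"] * 10 + ["B"] * 10,
            "age": np.round(rng.normal(40, 8, 20), 1),
            "sex": rng.choice(["F", "M"], 20),
        },
        index=pd.Index(samples, name="sample"),
    )
    return SampleMetadata(table, phenotype="group", covariates=["age", "sex"])
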