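import numpy as np
import pytest

from archpan.synthetic_community import CommunityConfig, emit_fosmid_library


@pytest.fixture(scope="session")
def small_config() -> CommunityConfig:
    """A community small enough for fast unit tests: 4 genomes per lineage,
    30 families per lineage."""
    return CommunityConfig(
        seed=11,
        n_genomes=4,
        genes_per_genome=30,
        n_marker_families=3,
        n_ribosomal_families=3,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return emit_fosmid_library(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_tree_newick(
    rng: np.random.Generator, labels: list[str], with_supports: bool = True
) -> str:
    """A random binary topology over the given labels, by sequential random
    joins; supports drawn uniformly (or 1.0 when disabled)."""
    nodes = [f"{lab}:0.1" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        sup = f"{rng.uniform():.2f}" if with_supports else "1.0"
        merged = f"({a},{b}){sup}:0.1"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
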