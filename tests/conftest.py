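from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from variclust.embedding import GeneEmbedding, PhenotypeAnnotation
from variclust.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def toy_embedding() -> GeneEmbedding:
    """Three genes x four dimensions with hand-set components."""
    return GeneEmbedding(
        vocabulary=["GENEA", "GENEB", "GENEC"],
        vectors=np.array(
            [
                [0.1, -0.5, 0.3, 0.0],
                [-0.2, -0.1, -0.4, -0.3],
                [0.7, 0.7, 0.7, 0.7],
            ]
        ),
    )


@pytest.fixture(scope="session")
def toy_annotations() -> list[PhenotypeAnnotation]:
    return [
        PhenotypeAnnotation("HP:0000001", "pheno one", frozenset({"GENEA", "GENEC"})),
        PhenotypeAnnotation("HP:0000002", "pheno two", frozenset({"GENEB", "MISSING"})),
        PhenotypeAnnotation("HP:0000003", "pheno three", frozenset({"ABSENT"})),
    ]


@pytest.fixture(scope="session")
def small_synthetic_cfg() -> SyntheticConfig:
    """Small planted-structure config for fast unit tests."""
    return SyntheticConfig(
        seed=2024,
        n_genes=60,
        embed_dim=16,
        n_modules=3,
        n_phenotypes=24,
        genes_per_phenotype=8,
        n_subtypes=3,
        individuals_per_subtype=12,
        genes_per_individual=10,
        n_terms=12,
        genes_per_term=8,
    )
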