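import random

import pytest

from mitoarch import datasets
from mitoarch.gene_order import SignedGeneOrder


@pytest.fixture
def antarctica():
    return datasets.laevipilina_antarctica()


@pytest.fixture
def vema():
    return datasets.vema_ewingi()


@pytest.fixture
def hyalina():
    return datasets.laevipilina_hyalina()


@pytest.fixture
def ground():
    return datasets.ground_pattern()


def random_signed_order(rng: random.Random, n: int,
                        taxon: str = "rand") -> SignedGeneOrder:
    """A random signed circular order over n distinct placeholder tRNA-like
    tokens (uses real tokens so kind inference stays valid)."""
    from mitoarch.nomenclature import ALL_TOKENS

    tokens = rng.sample(list(ALL_TOKENS), n)
    genes = tuple((t, rng.choice((1, -1))) for t in tokens)
    return SignedGeneOrder(taxon, genes)
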