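from __future__ import annotations

import numpy as np
import pytest

from komnet import GeneCatalogue, ReactionPairMap


@pytest.fixture
def small_catalogue() -> GeneCatalogue:
    """Five genes, two KOs, one unannotated gene, one multi-KO gene."""
    return GeneCatalogue(
        effective_length={"g1": 100, "g2": 200, "g3": 50, "g4": 400, "g5": 10},
        ko_ids={
            "g1": frozenset({"K00001"}),
            "g2": frozenset({"K00001"}),
            "g3": frozenset({"K00002"}),
            "g4": frozenset(),
            "g5": frozenset({"K00001", "K00002"}),
        },
    )


def random_pair_map(rng: np.random.Generator, n_kos: int, n_mets: int) -> ReactionPairMap:
    """Random reaction-pair map; some KOs share pair-sets, some are empty."""
    mets = [f"C{i:05d}" for i in range(n_mets)]
    pools: list[frozenset] = []
    pairs = {}
    for i in range(n_kos):
        if pools and rng.random() < 0.25:
            ps = pools[rng.integers(len(pools))]  # duplicate an existing pair-set
        else:
            k = int(rng.integers(0, 4))
            ps = frozenset(
                (mets[rng.integers(n_mets)], mets[rng.integers(n_mets)])
                for _ in range(k)
            )
            pools.append(ps)
        pairs[f"K{i + 1:05d}"] = ps
    return ReactionPairMap(pairs=pairs)


def random_network(rng: np.random.Generator, n_kos: int = 20, n_mets: int = 12):
    """A buildable random network (guarantees at least one non-empty pair-set)."""
    from komnet import build_network

    while True:
        pm = random_pair_map(rng, n_kos, n_mets)
        kos = {k for k, v in pm.pairs.items() if v}
        if kos:
            return pm, build_network(pm, kos)
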