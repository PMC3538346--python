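from __future__ import annotations

import pytest

from meiomap.tetrads import MarkerMap, SporeGenotype, Tetrad


@pytest.fixture
def two_marker_map() -> MarkerMap:
    return MarkerMap("X", (("A", 0.0), ("B", 50.0)))


def make_tetrad(pairs, tetrad_id="t1", markers=("A", "B"), viable=None):
    """Build a tetrad from four (alleleA, alleleB) pairs."""
    if viable is None:
        viable = [all(x != "-" for x in p) or True for p in pairs]
        viable = [True] * 4
    spores = tuple(
        SporeGenotype(
            tetrad_id=tetrad_id,
            spore_index=i + 1,
            viable=viable[i],
            alleles=(
                dict(zip(markers, pairs[i]))
                if viable[i]
                else {m: "-" for m in markers}
            ),
        )
        for i in range(4)
    )
    return Tetrad(tetrad_id=tetrad_id, spores=spores)


@pytest.fixture
def pd_tetrad():
    return make_tetrad([("P", "P"), ("P", "P"), ("M", "M"), ("M", "M")])


@pytest.fixture
def tt_tetrad():
    return make_tetrad([("P", "P"), ("M", "M"), ("P", "M"), ("M", "P")])


@pytest.fixture
def npd_tetrad():
    return make_tetrad([("P", "M"), ("P", "M"), ("M", "P"), ("M", "P")])
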