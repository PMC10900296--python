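import pytest

from chemspacekit import synthetic as syn


@pytest.fixture(scope="session")
def tag_library():
    """Exhaustive glycerol tri-esters over a 4-acid saturated pool (C8-C14)."""
    return syn.gen_triacylglycerols(
        [(8, ()), (10, ()), (12, ()), (14, ())], name="tag"
    )


@pytest.fixture(scope="session")
def scaffold_series_532():
    """Library with planted scaffold frequency vector (5, 3, 2)."""
    return syn.gen_scaffold_series(
        ["c1ccccc1", "c1ccncc1", "C1CCCCC1"], [5, 3, 2], name="series532"
    )


@pytest.fixture(scope="session")
def ring_diverse_library():
    """Scaffold-rich aromatic library used as diversity contrast to the TAGs."""
    return syn.gen_scaffold_series(
        ["c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccoc1", "C1CCNCC1"],
        [8, 8, 8, 8, 8],
        name="rings",
    )


PLANTED_REGIONS = {
    ("A",): 3,
    ("B",): 2,
    ("C",): 2,
    ("A", "B"): 4,
    ("A", "C"): 2,
    ("B", "C"): 1,
    ("A", "B", "C"): 1,
}
PLANTED_SIZES = (10, 8, 6)


@pytest.fixture(scope="session")
def overlap_triple():
    """Three libraries with planted Venn regions; pairwise totals (5, 3, 2), triple 1."""
    return syn.gen_overlap_triple(PLANTED_SIZES, PLANTED_REGIONS, seed=0)


@pytest.fixture(scope="session")
def npl_corpora():
    """NP-like / synthetic-like corpora (40 + 40) with disjoint class signals."""
    return syn.gen_npl_corpora(40, 40, seed=11)
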