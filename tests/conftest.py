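import numpy as np
import pytest

from mitoblocks.aligner import AlignParams, local_align
from mitoblocks.orfscan import classify_orfs, find_orfs, predict_tm, screen_candidates
from mitoblocks.repeats import detect_repeats
from mitoblocks.synteny import build_blocks, order_and_junctions, unique_regions
from mitoblocks.synthetic_data import SimConfig, generate_pair

BASES = np.array(list("ACGT"))


def random_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_config():
    """A light-weight synthetic pair: same structure as the default study
    conditions, scaled down for fast unit tests."""
    return SimConfig(
        L_target=45_000,
        n_blocks=4,
        block_len_range=(5_000, 10_000),
        n_inversions=1,
        n_transpositions=1,
        unique_insert_lens=(4_000, 2_000),
        n_repeat_pairs=2,
        repeat_len_range=(250, 600),
        snp_rate=0.005,
        n_plastid_inserts=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return generate_pair(small_config)


@pytest.fixture(scope="session")
def default_pair():
    """The default study conditions (~150 kb, 8 blocks) at a fixed seed."""
    return generate_pair(SimConfig(seed=1))


def analyse(A, B):
    """The core analysis chain used by several test modules."""
    hits = local_align(A, B, AlignParams(min_len=500, min_ident=90.0))
    blocks = build_blocks(hits, 2000, 95.0)
    junctions = {g.id: order_and_junctions(g, blocks) for g in (A, B)}
    unique = {g.id: unique_regions(g, blocks) for g in (A, B)}
    repeats = {g.id: detect_repeats(g) for g in (A, B)}
    orfs = {}
    candidates = {}
    for focal, other in ((A, B), (B, A)):
        found = find_orfs(focal)
        classify_orfs(found, focal, other)
        for o in found:
            o.tm, o.tm_segments = predict_tm(o.protein)
        orfs[focal.id] = found
        candidates[focal.id] = screen_candidates(
            found, blocks, repeats[focal.id], focal
        )
    return {
        "alignments": hits,
        "blocks": blocks,
        "junctions": junctions,
        "unique": unique,
        "repeats": repeats,
        "orfs": orfs,
        "candidates": candidates,
    }


@pytest.fixture(scope="session")
def small_result(small_pair):
    A, B, _ = small_pair
    return analyse(A, B)


@pytest.fixture(scope="session")
def default_result(default_pair):
    A, B, _ = default_pair
    return analyse(A, B)
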