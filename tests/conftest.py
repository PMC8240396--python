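"""Shared test helpers: seeded tree-pair generation at oracle-checkable sizes."""

import pytest

from rfs2.fixtures import overlapping_pair, random_binary_tree


def small_pair(seed: int):
    """A deterministic pair of overlapping binary source trees with at
    most 7 leaves in the union, suitable for exhaustive certification."""
    n_overlap = 4 + seed % 2
    extra = (seed // 2) % 2
    spr = seed % 3
    model = random_binary_tree([f"l{i}" for i in range(7)], seed=seed * 31 + 1)
    overlap = sorted(model.leaves)[:n_overlap]
    return overlapping_pair(
        model, overlap, extra_per_side=extra, disagreement_spr=spr, seed=seed * 31 + 2
    )


def medium_pair(seed: int):
    """A deterministic pair with a 10-leaf model: big enough to exercise
    paths, extra subtrees and multiple refinement steps."""
    model = random_binary_tree([f"m{i:02d}" for i in range(10)], seed=seed * 17 + 3)
    overlap = sorted(model.leaves)[: 5 + seed % 2]
    return overlapping_pair(
        model,
        overlap,
        extra_per_side=2,
        disagreement_spr=seed % 3,
        seed=seed * 17 + 4,
    )


@pytest.fixture
def lemma4():
    from rfs2.fixtures import lemma4_trees

    return lemma4_trees()
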