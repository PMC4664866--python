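"""Small shared helpers: canonical node pairs and seeded RNG derivation."""

from __future__ import annotations

import numpy as np

#: A node pair is stored as a tuple ordered lexicographically by str() of the
#: identifiers, so that (x, y) and (y, x) map to the same key regardless of
#: the node type. Node identifiers are opaque; only determinism matters.
Pair = tuple


def canon_pair(u, v) -> Pair:
    """Canonical (order-free) form of an undirected node pair."""
    if str(u) <= str(v):
        return (u, v)
    return (v, u)


def pair_sort_key(pair: Pair):
    """Deterministic lexicographic sort key for a canonical pair."""
    return (str(pair[0]), str(pair[1]))


def derive_rng(seed, *indices) -> np.random.Generator:
    """A reproducible child generator for replicate `indices` of a base seed.

    Child seeds stay below 2**31 so they remain portable as plain ints.
    """
    if seed is None:
        return np.random.default_rng()
    mixed = int(seed) % (2**31)
    for ix in indices:
        mixed = (mixed * 1_000_003 + int(ix) + 1) % (2**31)
    return np.random.default_rng(mixed)
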