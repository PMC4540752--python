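"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the local-alignment
oracle is a plain Gotoh dynamic program written here, the Jaccard oracle
works on explicit Python sets, and random networks are built directly
from dense arrays.
"""

from __future__ import annotations

import numpy as np

from dtwalk import (
    HetNet,
    InteractionTable,
    SimilarityLayer,
    assemble,
)


def sw_gotoh_oracle(a, b, sub, gap_open, gap_extend):
    """Smith-Waterman local alignment score, affine gaps, cell by cell.

    ``sub(x, y)`` returns the substitution score; ``gap_open`` is the cost
    of the first gap position and ``gap_extend`` of each further one
    (both positive costs).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def blosum62_fn():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(mat[x][y])


def set_jaccard(s1: set, s2: set) -> float:
    if not s1 and not s2:
        return 0.0
    return len(s1 & s2) / len(s1 | s2)


def random_similarity(rng: np.random.Generator, ids) -> SimilarityLayer:
    n = len(ids)
    r = rng.random((n, n))
    vals = (r + r.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityLayer(ids=tuple(ids), values=vals)


def random_hetnet(
    rng: np.random.Generator,
    n_drugs: int,
    n_targets: int,
    p_link: float = 0.2,
) -> HetNet:
    drug_ids = tuple(f"d{i}" for i in range(n_drugs))
    target_ids = tuple(f"t{j}" for j in range(n_targets))
    links = frozenset(
        (d, t)
        for d in drug_ids
        for t in target_ids
        if rng.random() < p_link
    )
    interactions = InteractionTable(
        drug_ids=drug_ids, target_ids=target_ids, links=links
    )
    return assemble(
        drug_layer=random_similarity(rng, drug_ids),
        target_layer=random_similarity(rng, target_ids),
        interactions=interactions,
    )
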