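"""Cytosine sequence-context classification (CpG / CHG / CHH, strand-symmetric).

H denotes A, C or T. Contexts are evaluated on both strands: a G on the plus
strand is classified from the reverse-complement triplet, so a G preceded by a
C is a CpG site, exactly as the C on the minus strand would be.
"""

from __future__ import annotations

import numpy as np

# codes: A=0, C=1, G=2, T=3
C, G = 1, 2

CONTEXT_NAMES = ["CpG", "CHG", "CHH", "nonC"]


def classify_contexts(codes: np.ndarray, pos0: np.ndarray) -> np.ndarray:
    """Context label index (0=CpG, 1=CHG, 2=CHH, 3=nonC) for each position.

    Positions within 2 bp of either chromosome end whose context window is
    incomplete are classified conservatively as nonC unless decidable.
    """
    n = len(codes)
    pos0 = np.asarray(pos0)
    out = np.full(pos0.shape, 3, dtype=np.int8)
    base = codes[pos0]

    is_c = base == C
    is_g = base == G

    nxt1 = np.where(pos0 + 1 < n, codes[np.minimum(pos0 + 1, n - 1)], -1)
    nxt2 = np.where(pos0 + 2 < n, codes[np.minimum(pos0 + 2, n - 1)], -1)
    prv1 = np.where(pos0 - 1 >= 0, codes[np.maximum(pos0 - 1, 0)], -1)
    prv2 = np.where(pos0 - 2 >= 0, codes[np.maximum(pos0 - 2, 0)], -1)

    # plus-strand cytosines
    out[is_c & (nxt1 == G)] = 0
    out[is_c & (nxt1 != G) & (nxt1 >= 0) & (nxt2 == G)] = 1
    out[is_c & (nxt1 != G) & (nxt1 >= 0) & (nxt2 != G) & (nxt2 >= 0)] = 2
    # minus-strand cytosines (plus-strand G); mirror with preceding bases
    out[is_g & (prv1 == C)] = 0
    out[is_g & (prv1 != C) & (prv1 >= 0) & (prv2 == C)] = 1
    out[is_g & (prv1 != C) & (prv1 >= 0) & (prv2 != C) & (prv2 >= 0)] = 2
    return out


def genome_context_counts(chroms: dict[str, np.ndarray]) -> dict[str, int]:
    """Number of genomic positions in each context class, both strands collapsed."""
    counts = np.zeros(4, dtype=np.int64)
    for codes in chroms.values():
        labels = classify_contexts(codes, np.arange(len(codes)))
        counts += np.bincount(labels, minlength=4)
    return dict(zip(CONTEXT_NAMES, counts.tolist()))


def context_name(index: int) -> str:
    return CONTEXT_NAMES[index]
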