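"""Pairwise sequence distances: Tamura–Nei 1993 for DNA, p-distance for protein.

The TN93 distance corrects the observed proportions of the two transition
types and of transversions for multiple hits, using empirical base
frequencies pooled over the pair:

    d = -(2 pA pG / pR) ln(1 - pR P1/(2 pA pG) - Q/(2 pR))
        -(2 pC pT / pY) ln(1 - pY P2/(2 pC pT) - Q/(2 pY))
        -2 (pR pY - pA pG pY/pR - pC pT pR/pY) ln(1 - Q/(2 pR pY))

where P1, P2 and Q are the A<->G, C<->T and transversion mismatch
proportions, pR = pA + pG and pY = pC + pT. Saturated pairs (any log
argument <= 0) have no finite distance and return NaN.
"""

from __future__ import annotations

import math

import numpy as np

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = "ACGT"


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """TN93 distance (substitutions/site) between two aligned DNA sequences.

    The pair must be gap-free and equal-length (apply complete gap deletion
    first); sites where either sequence carries a non-ACGT character are
    excluded. Returns NaN when the correction saturates.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) == 0:
        raise ValueError("sequences must be non-empty")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_chars = np.frombuffer(_VALID.encode(), dtype="S1")
    ok = np.isin(a, valid_chars) & np.isin(b, valid_chars)
    if "-" in seq_a or "-" in seq_b:
        raise ValueError("gaps present; strip gap columns before computing TN93")
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        raise ValueError("no comparable ACGT sites")

    # empirical base frequencies pooled over both sequences
    pooled = np.concatenate([a, b])
    freqs = {c: float((pooled == c.encode()).mean()) for c in _VALID}
    p_a, p_c, p_g, p_t = (freqs[c] for c in "ACGT")
    p_r, p_y = p_a + p_g, p_c + p_t

    diff = a != b
    pair = np.char.add(a[diff].astype("U1"), b[diff].astype("U1"))
    purine_ts = np.isin(pair, ["AG", "GA"]).sum()
    pyrimidine_ts = np.isin(pair, ["CT", "TC"]).sum()
    transversions = int(diff.sum()) - int(purine_ts) - int(pyrimidine_ts)
    p1 = purine_ts / n
    p2 = pyrimidine_ts / n
    q = transversions / n
    return tn93_from_proportions(p1, p2, q, (p_a, p_c, p_g, p_t))


def tn93_from_proportions(
    p1: float, p2: float, q: float, pi: tuple[float, float, float, float]
) -> float:
    """Evaluate the TN93 closed form from mismatch proportions and base
    frequencies (A, C, G, T order). NaN on saturation.

    Degenerate compositions (a missing purine or pyrimidine) drop the
    corresponding transition term, which then cannot have any counts.
    """
    p_a, p_c, p_g, p_t = pi
    p_r, p_y = p_a + p_g, p_c + p_t
    d = 0.0
    if p_a * p_g > 0:
        k1 = 2 * p_a * p_g / p_r
        arg = 1 - p_r * p1 / (2 * p_a * p_g) - q / (2 * p_r)
        if arg <= 0:
            return math.nan
        d -= k1 * math.log(arg)
    elif p1 > 0:
        return math.nan
    if p_c * p_t > 0:
        k2 = 2 * p_c * p_t / p_y
        arg = 1 - p_y * p2 / (2 * p_c * p_t) - q / (2 * p_y)
        if arg <= 0:
            return math.nan
        d -= k2 * math.log(arg)
    elif p2 > 0:
        return math.nan
    if p_r * p_y > 0:
        k3 = 2 * (p_r * p_y - p_a * p_g * p_y / p_r - p_c * p_t * p_r / p_y)
        arg = 1 - q / (2 * p_r * p_y)
        if arg <= 0:
            return math.nan
        d -= k3 * math.log(arg)
    elif q > 0:
        return math.nan
    return d


def p_distance(seq_a: str, seq_b: str, *, alphabet: str | None = None) -> float:
    """Proportion of differing sites, ignoring gap columns.

    Used for protein distance matrices (NJ partitioning of sequence sets).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    compared = diffs = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in "-." or y in "-.":
            continue
        if alphabet is not None and (x not in alphabet or y not in alphabet):
            continue
        compared += 1
        diffs += x != y
    if compared == 0:
        raise ValueError("no comparable sites")
    return diffs / compared


def distance_matrix(seqs: list[str], labels: list[str], metric=tn93_distance):
    """Symmetric pairwise distance matrix; raises naming the first
    undefined (saturated) pair."""
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = metric(seqs[i], seqs[j])
            if math.isnan(d):
                raise ValueError(
                    f"distance undefined (saturated) for pair "
                    f"({labels[i]}, {labels[j]})"
                )
            dm[i, j] = dm[j, i] = d
    return dm
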