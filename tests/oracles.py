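"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: transitive closure by
boolean matrix powers for consensus components, substring search over the
full k-mer expansion for motif scanning, and exhaustive enumeration for the
hypergeometric and Fisher tails.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Consensus peaks: (start, end) per replicate -> components via closure
# ---------------------------------------------------------------------------


def brute_force_hcpeaks(
    replicate_intervals: Sequence[Sequence[Tuple[int, int]]],
    min_support: int = 2,
    min_overlap: int = 100,
) -> Set[Tuple[int, int, frozenset]]:
    """Enumerate replicate-spanning overlap components by transitive closure.

    Returns a set of (union_start, union_end, replicate-id frozenset).
    Assumes intervals within one replicate do not overlap each other.
    """
    nodes = [
        (r, s, e)
        for r, ivs in enumerate(replicate_intervals)
        for (s, e) in ivs
    ]
    n = len(nodes)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            ri, si, ei = nodes[i]
            rj, sj, ej = nodes[j]
            if ri == rj:
                continue
            ov = min(ei, ej) - max(si, sj)
            if ov >= min(min_overlap, ei - si, ej - sj):
                adj[i, j] = True
    closure = adj.copy()
    for _ in range(n):
        new = closure @ closure
        if (new == closure).all():
            break
        closure = new
    seen, out = set(), set()
    for i in range(n):
        comp = frozenset(np.flatnonzero(closure[i]))
        if comp in seen:
            continue
        seen.add(comp)
        reps = frozenset(nodes[k][0] for k in comp)
        if len(reps) >= min_support:
            out.add(
                (
                    min(nodes[k][1] for k in comp),
                    max(nodes[k][2] for k in comp),
                    reps,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Motif scanning: substring search over the explicit expansion
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_expand(pattern: str) -> List[str]:
    pattern = pattern.upper().replace("U", "T")
    return [
        "".join(k) for k in itertools.product(*[_IUPAC[c] for c in pattern])
    ]


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def naive_scan(
    seq: str, pattern: str, both_strands: bool = False
) -> Set[Tuple[int, str]]:
    """All motif hit starts via explicit k-mer substring comparison."""
    seq = seq.upper()
    kmers = set(naive_expand(pattern))
    k = len(pattern)
    hits = {
        (i, "+") for i in range(len(seq) - k + 1) if seq[i : i + k] in kmers
    }
    if both_strands:
        rc_kmers = {naive_revcomp(m) for m in kmers}
        hits |= {
            (i, "-")
            for i in range(len(seq) - k + 1)
            if seq[i : i + k] in rc_kmers
        }
    return hits


# ---------------------------------------------------------------------------
# Exact tails by enumeration
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for a hypergeometric(N, K, n), by direct summation."""
    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(x, min(K, n) + 1)
        if n - i <= N - K
    ) / total


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by enumerating all tables with
    the same margins and summing probabilities <= the observed one."""
    row1, col1, N = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        return (
            comb(row1, x)
            * comb(N - row1, col1 - x)
            / comb(N, col1)
        )

    lo = max(0, col1 - (N - row1))
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))
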