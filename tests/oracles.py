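"""Independent brute-force oracles used across the test suite.

Each oracle is deliberately naive (enumeration or quadratic scans) and
shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import random

_CAN_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# -- folding: exhaustive enumeration of nested structures ---------------------

def enumerate_max_pairs(seq: str, min_loop: int = 3, nolp: bool = True) -> int:
    """Maximum pair count over every nested structure satisfying the
    minimum-loop and (optionally) no-lonely-pair constraints."""
    n = len(seq)
    if n == 0:
        return 0

    def can(i: int, j: int) -> bool:
        return j - i - 1 >= min_loop and (seq[i], seq[j]) in _CAN_PAIR

    def structures(i: int, j: int):
        if i >= j:
            yield frozenset()
            return
        for s in structures(i + 1, j):
            yield s
        for k in range(i + min_loop + 1, j + 1):
            if can(i, k):
                for left in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        yield left | right | {(i, k)}

    def helices_ok(pairs: frozenset) -> bool:
        if not nolp:
            return True
        ps = set(pairs)
        for a, b in ps:
            run = 1
            t = 1
            while (a + t, b - t) in ps:
                run += 1
                t += 1
            t = 1
            while (a - t, b + t) in ps:
                run += 1
                t += 1
            if run < 2:
                return False
        return True

    return max((len(s) for s in structures(0, n - 1) if helices_ok(s)), default=0)


# -- mirror score: two-pass position check ------------------------------------

def naive_mirror_score(window: str) -> int:
    rc = naive_revcomp(window)
    return sum(1 for a, b in zip(window, rc) if a == b and a != "N")


# -- intervals: quadratic all-pairs scans -------------------------------------

def quadratic_overlaps(a_intervals, b_intervals):
    """All (i, j) index pairs with >= 1 bp overlap, same contig.

    Items are (contig, start, end) triples; half-open arithmetic.
    """
    out = set()
    for i, (ca, sa, ea) in enumerate(a_intervals):
        for j, (cb, sb, eb) in enumerate(b_intervals):
            if ca == cb and sa < eb and sb < ea:
                out.add((i, j))
    return out


def quadratic_cluster(intervals, max_gap: int):
    """Single-linkage clusters of (contig, start, end) triples, brute force."""
    items = list(enumerate(intervals))
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i, (_, (ci, si, ei)) in enumerate(items):
        for j, (_, (cj, sj, ej)) in enumerate(items):
            if i < j and ci == cj and si <= ej + max_gap and sj <= ei + max_gap:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)
    result = []
    for members in clusters.values():
        ivs = [intervals[m] for m in members]
        result.append((
            ivs[0][0], min(s for _, s, _ in ivs), max(e for _, _, e in ivs),
            len(members),
        ))
    return sorted(result)


def random_genome(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
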