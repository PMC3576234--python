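"""Secondary-structure prediction for hairpin screening.

The default backend is a deterministic maximum-base-pair dynamic program
(Nussinov-style) over the DNA alphabet with G.T treated as the wobble pair:
it returns a nested (pseudoknot-free) structure maximizing the number of
base pairs subject to a minimum hairpin-loop length and, by default, a
no-lonely-pairs constraint (every helix carries at least two stacked
pairs). The hairpin validation criteria downstream operate on any
dot-bracket, so a thermodynamic folder can be substituted via the
``backend`` argument of :func:`fold`.

Grammar for the no-lonely-pairs optimum (maximizing pair count):

    M[i,j] = best free structure      = max(M[i+1,j], max_k H[i,k] + M[k+1,j])
    H[i,j] = (i,j) starts a helix     = 1 + E[i+1,j-1]   requires both
                                        (i,j) and (i+1,j-1) pairable
    E[a,b] = (a,b) paired, stacked on  = 1 + max(M[a+1,b-1],
             an outer pair                        E[a+1,b-1] if pairable)

Ties are broken deterministically: prefer pairing over leaving the 5'-most
base unpaired, then the smallest pairing partner, then helix continuation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

from .config import PipelineConfig

__all__ = ["FoldResult", "StemLoop", "fold", "parse_stemloops", "pairs_to_dotbracket"]

# Allowed pairs in the DNA alphabet, wobble included; N pairs with nothing.
_CAN_PAIR = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

_NEG = -(10**9)


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure for one window sequence."""

    window_seq: str
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]
    score: int


@dataclass(frozen=True)
class StemLoop:
    """One hairpin loop and the stem enclosing it up to the first branch.

    ``arm5``/``arm3`` span [outer5, inner5] and [inner3, outer3] inclusive;
    the paired-base fraction counts both bases of every stem pair over all
    bases in the two arms (bulges and internal loops dilute it, the
    terminal loop is excluded).
    """

    outer5: int
    inner5: int
    inner3: int
    outer3: int
    n_pairs: int

    @property
    def loop_len(self) -> int:
        return self.inner3 - self.inner5 - 1

    @property
    def arm_len(self) -> int:
        return (self.inner5 - self.outer5 + 1) + (self.outer3 - self.inner3 + 1)

    @property
    def stem_paired_frac(self) -> float:
        return 2.0 * self.n_pairs / self.arm_len

    def contains(self, pos: int) -> bool:
        """Whether a window position lies inside the stem arms."""
        return (self.outer5 <= pos <= self.inner5) or (self.inner3 <= pos <= self.outer3)

    def in_loop(self, pos: int) -> bool:
        return self.inner5 < pos < self.inner3


def pairs_to_dotbracket(length: int, pairs: Sequence[tuple[int, int]]) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def fold(seq: str, cfg: PipelineConfig,
         backend: Callable[[str, PipelineConfig], FoldResult] | None = None) -> FoldResult:
    """Fold a window; raises on symbols outside {A,C,G,T,N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot fold sequence with symbols {sorted(bad)}")
    if backend is not None:
        return backend(seq, cfg)
    pairs = _max_pairs_structure(seq, cfg.min_loop, cfg.no_lonely_pairs)
    return FoldResult(
        window_seq=seq,
        dotbracket=pairs_to_dotbracket(len(seq), pairs),
        pairs=tuple(sorted(pairs)),
        score=len(pairs),
    )


def _max_pairs_structure(seq: str, min_loop: int, nolp: bool) -> list[tuple[int, int]]:
    n = len(seq)
    if n == 0:
        return []

    def can(i: int, j: int) -> bool:
        return j - i - 1 >= min_loop and (seq[i], seq[j]) in _CAN_PAIR

    if not nolp:
        return _nussinov(seq, min_loop, can)

    # Tables as flat dicts keyed by (i, j); M defaults handled by helper.
    M = [[0] * n for _ in range(n)]
    H = [[_NEG] * n for _ in range(n)]
    E = [[_NEG] * n for _ in range(n)]

    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if can(i, j):
                inner_m = M[i + 1][j - 1] if j - 1 >= i + 1 else 0
                best = inner_m
                if can(i + 1, j - 1) and E[i + 1][j - 1] > best:
                    best = E[i + 1][j - 1]
                E[i][j] = 1 + best
                if can(i + 1, j - 1):
                    H[i][j] = 1 + E[i + 1][j - 1]
            best = M[i + 1][j] if i + 1 <= j else 0
            for k in range(i + min_loop + 1, j + 1):
                if H[i][k] > 0:
                    rest = M[k + 1][j] if k + 1 <= j else 0
                    if H[i][k] + rest > best:
                        best = H[i][k] + rest
            M[i][j] = best

    pairs: list[tuple[int, int]] = []

    def smallest_partner(i: int, j: int) -> int | None:
        """Smallest k such that pairing (i, k) as a helix start stays optimal."""
        target = M[i][j]
        for k in range(i + min_loop + 1, j + 1):
            if H[i][k] > 0:
                rest = M[k + 1][j] if k + 1 <= j else 0
                if H[i][k] + rest == target:
                    return k
        return None

    def trace_m(i: int, j: int) -> None:
        while i < j and M[i][j] > 0:
            k = smallest_partner(i, j)
            if k is None:
                i += 1  # i unpaired in every optimum that starts here
                continue
            trace_h(i, k)
            i = k + 1

    def trace_h(i: int, j: int) -> None:
        pairs.append((i, j))
        trace_e(i + 1, j - 1)

    def trace_e(a: int, b: int) -> None:
        # (a, b) is paired; choose the smallest optimal partner for a+1,
        # considering both a fresh helix inside and continuing this one.
        while True:
            pairs.append((a, b))
            target = E[a][b] - 1
            m_ok = a + 1 <= b - 1 and (M[a + 1][b - 1] if a + 1 <= b - 1 else 0) == target
            e_ok = can(a + 1, b - 1) and E[a + 1][b - 1] == target
            k = smallest_partner(a + 1, b - 1) if m_ok and a + 1 < b - 1 else None
            if k is not None and (not e_ok or k <= b - 1):
                trace_m(a + 1, b - 1)  # trace_m re-finds k deterministically
                return
            if e_ok:
                a, b = a + 1, b - 1  # continue the helix
                continue
            if m_ok:
                trace_m(a + 1, b - 1)
                return
            raise AssertionError("traceback inconsistency")

    trace_m(0, n - 1)
    assert len(pairs) == M[0][n - 1]
    return pairs


def _nussinov(seq: str, min_loop: int, can) -> list[tuple[int, int]]:
    n = len(seq)
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            best = M[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can(i, k):
                    left = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = M[k + 1][j] if k + 1 <= j else 0
                    if 1 + left + rest > best:
                        best = 1 + left + rest
            M[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j and M[i][j] > 0:
            target = M[i][j]
            chosen = None
            for k in range(i + min_loop + 1, j + 1):
                if can(i, k):
                    left = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = M[k + 1][j] if k + 1 <= j else 0
                    if 1 + left + rest == target:
                        chosen = k
                        break
            if chosen is None:
                i += 1
                continue
            pairs.append((i, chosen))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))
            i, j = i + 1, chosen - 1
    return pairs


def parse_stemloops(result: FoldResult) -> list[StemLoop]:
    """One stem-loop per hairpin loop, extended outward to the first branch.

    A stem-loop starts at an innermost pair (a hairpin loop) and grows
    through enclosing pairs as long as each enclosing pair holds exactly one
    child helix; a multiloop branch point stops the extension. Returned in
    5' order.
    """
    pairs = sorted(result.pairs)
    if not pairs:
        return []
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:  # sorted by i; nesting via a stack over j
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        par = stack[-1] if stack else None
        parent[p] = par
        children.setdefault(p, [])
        children.setdefault(par, []).append(p)
        stack.append(p)

    loops: list[StemLoop] = []
    for p in pairs:
        if children[p]:
            continue  # not innermost
        chain = [p]
        cur = p
        while True:
            par = parent[cur]
            if par is None or len(children[par]) != 1:
                break
            chain.append(par)
            cur = par
        inner5, inner3 = chain[0]
        outer5, outer3 = chain[-1]
        loops.append(
            StemLoop(outer5=outer5, inner5=inner5, inner3=inner3, outer3=outer3,
                     n_pairs=len(chain))
        )
    loops.sort(key=lambda s: s.outer5)
    return loops
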