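"""Intra-molecule repeat-pair detection by seed-and-extend self-comparison.

Exact k-mer seeds between a sequence and itself (direct) and its reverse
complement (inverted) are grouped per diagonal, chained, and extended
greedily outward while the running identity stays at or above the minimum;
main-diagonal self-hits and mirror duplicates are removed.  Circular
molecules (plastomes) can be scanned with a wrap-around of min_len - 1
bases appended, coordinates reported modulo the length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RepeatPair:
    start1: int  # 0-based half-open intervals on the (ungapped) sequence
    end1: int
    start2: int
    end2: int
    orientation: str  # 'direct' | 'inverted'
    identity: float
    length: int  # aligned match length (bp)

    def canonical(self) -> "RepeatPair":
        if (self.start1, self.end1) > (self.start2, self.end2):
            return RepeatPair(
                self.start2, self.end2, self.start1, self.end1,
                self.orientation, self.identity, self.length,
            )
        return self

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.start1, self.end1), (self.start2, self.end2)


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in sequence")


def _seed_diagonals(query: np.ndarray, target: np.ndarray, k: int) -> dict[int, list[int]]:
    """diagonal (j - i) -> sorted query offsets i of exact k-mer matches."""
    index: dict[bytes, list[int]] = {}
    tb = target.tobytes()
    for j in range(len(target) - k + 1):
        kmer = tb[j : j + k]
        index.setdefault(kmer, []).append(j)
    qb = query.tobytes()
    diags: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(qb[i : i + k], ()):
            diags.setdefault(j - i, []).append(i)
    return diags


_MATCH_SCORE = 1
_MISMATCH_SCORE = -2
_X_DROP = 15


def _extend_run(
    query: np.ndarray,
    target: np.ndarray,
    i0: int,
    i1: int,
    diag: int,
    min_identity: float,
) -> tuple[int, int, float]:
    """X-drop extension of the gapless run query[i0:i1] ~ target[i0+diag:i1+diag].

    Each direction extends base by base (match +1, mismatch -2) until the
    score falls ``_X_DROP`` below its running maximum, then retreats to the
    maximum-scoring endpoint, so both ends land on a match and an exact
    repeat keeps its exact boundaries.  Returns (i0, i1, identity) — the
    caller applies the min_identity / min_len filters.
    """
    def is_match(i: int) -> bool:
        j = i + diag
        return 0 <= j < len(target) and query[i] == target[j]

    def extend(pos: int, step: int, limit: int) -> int:
        best, score, best_pos = 0, 0, pos
        i = pos
        while i != limit:
            probe = i if step > 0 else i - 1
            score += _MATCH_SCORE if is_match(probe) else _MISMATCH_SCORE
            i += step
            if score > best:
                best, best_pos = score, i
            elif best - score > _X_DROP:
                break
        return best_pos

    right_limit = min(len(query), len(target) - diag)
    left_limit = max(0, -diag)
    i1 = extend(i1, +1, right_limit)
    i0 = extend(i0, -1, left_limit)
    while i0 < i1 and not is_match(i0):
        i0 += 1
    while i1 > i0 and not is_match(i1 - 1):
        i1 -= 1
    length = i1 - i0
    matches = int(sum(is_match(i) for i in range(i0, i1)))
    identity = matches / length if length else 0.0
    return i0, i1, identity


def _chain_and_extend(
    query: np.ndarray,
    target: np.ndarray,
    diags: dict[int, list[int]],
    k: int,
    min_len: int,
    min_identity: float,
    max_chain_gap: int = 50,
) -> list[tuple[int, int, int, float]]:
    """(i0, i1, diag, identity) for each extended chained seed run."""
    hits = []
    for diag, offsets in diags.items():
        offsets = sorted(offsets)
        chains: list[list[int]] = [[offsets[0]]]
        for i in offsets[1:]:
            if i - chains[-1][-1] <= k + max_chain_gap:
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            i0, i1 = chain[0], chain[-1] + k
            i0, i1, ident = _extend_run(query, target, i0, i1, diag, min_identity)
            if i1 - i0 >= min_len and ident >= min_identity:
                hits.append((i0, i1, diag, ident))
    return hits


def find_repeat_pairs(
    seq: str,
    min_len: int,
    min_identity: float = 0.90,
    *,
    k: int = 15,
    circular: bool = False,
) -> list["RepeatPair"]:
    """Direct and inverted repeat pairs within one ungapped sequence.

    Self-hits on the main diagonal and mirror duplicates are removed; pairs
    shorter than ``min_len`` or below ``min_identity`` are discarded, and
    nested/redundant hits are collapsed by :func:`deduplicate_repeats`.
    For ``circular`` molecules the first min_len - 1 bases are appended and
    coordinates are reported modulo the length.
    """
    seq = seq.upper()
    _check_alphabet(seq)
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    k = min(k, min_len)
    L = len(seq)
    scan = seq + seq[: min_len - 1] if circular else seq
    arr = np.frombuffer(scan.encode(), dtype="S1")
    pairs: list[RepeatPair] = []

    # direct: sequence vs itself, skip the main diagonal, keep j > i half
    diags = _seed_diagonals(arr, arr, k)
    diags = {d: off for d, off in diags.items() if d > 0}
    for i0, i1, diag, ident in _chain_and_extend(arr, arr, diags, k, min_len, min_identity):
        p = RepeatPair(i0, i1, i0 + diag, i1 + diag, "direct", ident, i1 - i0)
        pairs.append(p)

    # inverted: sequence vs its reverse complement; a hit q[i0:i1] ~ rc[j0:j1]
    # maps to forward intervals [i0,i1) and [Ls - j1, Ls - j0)
    rc = np.frombuffer(revcomp(scan).encode(), dtype="S1")
    Ls = len(scan)
    rdiags = _seed_diagonals(arr, rc, k)
    for i0, i1, diag, ident in _chain_and_extend(arr, rc, rdiags, k, min_len, min_identity):
        j0, j1 = i0 + diag, i1 + diag
        s2, e2 = Ls - j1, Ls - j0
        if max(i0, s2) < min(i1, e2):
            # the run maps (near) onto itself: an inverted pair with a short
            # spacer reads as one palindrome — split it into its two arms
            arm = _split_palindrome(scan, min(i0, s2), max(i1, e2))
            if arm is not None:
                a0, a1, b0, b1, aident = arm
                if a1 - a0 >= min_len and aident >= min_identity:
                    pairs.append(
                        RepeatPair(a0, a1, b0, b1, "inverted", aident, a1 - a0)
                    )
            continue
        if (s2, e2) < (i0, i1):
            continue  # mirror duplicate; the swapped copy is found too
        pairs.append(RepeatPair(i0, i1, s2, e2, "inverted", ident, i1 - i0))

    if circular:
        pairs = [_wrap_pair(p, L) for p in pairs]
        # drop artifacts living entirely in the appended wrap
        pairs = [p for p in pairs if p.start1 < L and p.start2 < L]
    pairs = [p.canonical() for p in pairs]
    # drop exact duplicates arising from the wrap or symmetric seeding
    seen = set()
    uniq = []
    for p in pairs:
        key = (p.start1, p.end1, p.start2, p.end2, p.orientation)
        if key not in seen:
            seen.add(key)
            uniq.append(p)
    return deduplicate_repeats(uniq)


def _split_palindrome(
    scan: str, t0: int, t1: int
) -> tuple[int, int, int, int, float] | None:
    """Split a self-reverse-complementary run [t0, t1) into its two arms.

    Position p pairs with t0 + t1 - 1 - p; mismatching outer/inner
    boundary pairs (the spacer between the arms) are trimmed off.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    while t1 - t0 >= 2 and scan[t0] != comp[scan[t1 - 1]]:
        t0 += 1
        t1 -= 1
    h = (t1 - t0) // 2
    while h > 0 and scan[t0 + h - 1] != comp[scan[t1 - h]]:
        h -= 1
    if h == 0:
        return None
    arm_a = scan[t0 : t0 + h]
    arm_b_rc = revcomp(scan[t1 - h : t1])
    matches = sum(x == y for x, y in zip(arm_a, arm_b_rc))
    return t0, t0 + h, t1 - h, t1, matches / h


def _wrap_pair(p: RepeatPair, L: int) -> RepeatPair:
    def wrap(s: int, e: int) -> tuple[int, int]:
        return (s % L, e if e <= L else e - L) if s < L else (s - L, e - L)

    s1, e1 = wrap(p.start1, p.end1)
    s2, e2 = wrap(p.start2, p.end2)
    return RepeatPair(s1, e1, s2, e2, p.orientation, p.identity, p.length)


def _containment(inner: tuple[int, int], outer: tuple[int, int]) -> float:
    s = max(inner[0], outer[0])
    e = min(inner[1], outer[1])
    span = inner[1] - inner[0]
    return max(0, e - s) / span if span else 0.0


def deduplicate_repeats(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs redundantly covered by a longer retained pair.

    A pair is dropped when both of its intervals are each >= 80% contained
    in the corresponding intervals of a longer retained pair of the same
    orientation.  Retention order: longer, then higher identity, then
    smaller coordinates.
    """
    ordered = sorted(
        (p.canonical() for p in pairs),
        key=lambda p: (-p.length, -p.identity, p.start1, p.start2),
    )
    kept: list[RepeatPair] = []
    for p in ordered:
        redundant = False
        for q in kept:
            if q.orientation != p.orientation:
                continue
            i1, i2 = p.intervals()
            o1, o2 = q.intervals()
            if (
                (_containment(i1, o1) >= 0.8 and _containment(i2, o2) >= 0.8)
                or (_containment(i1, o2) >= 0.8 and _containment(i2, o1) >= 0.8)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(p)
    kept.sort(key=lambda p: (p.start1, p.start2))
    return kept


def pairs_to_frame(pairs: list[RepeatPair]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start1": p.start1,
                "end1": p.end1,
                "start2": p.start2,
                "end2": p.end2,
                "orientation": p.orientation,
                "identity": p.identity,
                "length": p.length,
            }
            for p in pairs
        ]
    )
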