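"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the algorithms under test: reversal distances come
from breadth-first search over the full reversal graph, and the repeat /
hairpin oracles are direct string re-reads.
"""

from collections import deque
from itertools import permutations, product


def all_signed_permutations(m):
    for base in permutations(range(1, m + 1)):
        for signs in product((1, -1), repeat=m):
            yield tuple(b * s for b, s in zip(base, signs))


def bfs_reversal_distances(m):
    """Exact reversal distance to identity for EVERY signed permutation of
    1..m, by breadth-first search from the identity (reversals are
    involutions, so distances are symmetric)."""
    identity = tuple(range(1, m + 1))
    dist = {identity: 0}
    queue = deque([identity])
    while queue:
        p = queue.popleft()
        d = dist[p]
        for i in range(m):
            for j in range(i, m):
                q = p[:i] + tuple(-x for x in reversed(p[i : j + 1])) + p[j + 1 :]
                if q not in dist:
                    dist[q] = d + 1
                    queue.append(q)
    return dist


def brute_tandem_repeats(seq, min_period=2, max_period=60, min_copies=3):
    """Tandem repeats by direct unit comparison: at each start the qualifying
    period with the longest span (full copies + partial) wins, smallest
    period breaking ties; scan leftmost-first without overlap."""
    s = seq.upper()
    n = len(s)
    hits = []
    i = 0
    while i < n:
        found = None
        best_span = -1
        for p in range(min_period, min(max_period, (n - i) // 2) + 1):
            unit = s[i : i + p]
            copies = 1
            while s[i + copies * p : i + (copies + 1) * p] == unit:
                copies += 1
            if copies < min_copies:
                continue
            partial = 0
            tail = i + copies * p
            while tail + partial < n and s[tail + partial] == unit[partial % p]:
                partial += 1
            span = copies * p + partial
            if span > best_span:
                best_span = span
                found = (unit, p, copies, partial, i + 1, tail + partial)
        if found:
            hits.append(found)
            i = found[5]
        else:
            i += 1
    return hits


def brute_homopolymers(seq, min_len=6):
    s = seq.upper()
    hits = []
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        if j - i >= min_len:
            hits.append((s[i], j - i, i + 1, j))
        i = j
    return hits


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def brute_hairpins(seq, min_stem=5, max_loop=30, max_mismatch=1, min_loop=3):
    """All maximal inverted repeats by exhaustive arm-pair enumeration."""
    s = seq.upper()
    n = len(s)
    best = {}
    for a_end in range(n):  # last base of arm1 (0-based)
        for loop in range(min_loop, max_loop + 1):
            b_start = a_end + 1 + loop
            if b_start >= n:
                break
            stem, mism, k, last_ok = 0, 0, 0, -1
            while a_end - k >= 0 and b_start + k < n:
                if _COMP.get(s[a_end - k]) == s[b_start + k]:
                    last_ok = k
                elif mism < max_mismatch:
                    mism += 1
                else:
                    break
                k += 1
            stem = last_ok + 1
            if stem >= min_stem:
                used = sum(1 for t in range(stem) if _COMP.get(s[a_end - t]) != s[b_start + t])
                key = (a_end + 1, b_start + 1)
                if key not in best or stem > best[key][0]:
                    best[key] = (stem, loop, a_end - stem + 2, b_start + stem, used)
    return sorted(best.values(), key=lambda h: (-h[0], h[2]))
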