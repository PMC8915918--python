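"""Independent brute-force oracles used only by tests.

Deliberately naive, plain-Python implementations kept structurally separate
from the package code paths they check.
"""

from __future__ import annotations

import itertools
import math


def naive_tanimoto(a, b) -> float:
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return 0.0 if union == 0 else 1.0 - inter / union


def naive_ward_labels(dist, cut_height, dialect="D2"):
    """O(n^3) Ward agglomeration on a dense distance matrix.

    Clusters are plain member-index lists; the merge criterion is carried in
    a dict keyed by frozen member tuples and updated with the Lance-Williams
    Ward recurrence (on squared distances for the D2 dialect).  Ties pick the
    pair with the lexicographically smallest sorted member lists.  Returns
    flat labels (1..k by first appearance) after cutting.
    """
    n = len(dist)
    clusters: list[list[int]] = [[i] for i in range(n)]
    crit: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i][j]
            crit[(i, j)] = d * d if dialect == "D2" else d
    merges = []  # (members_a, members_b, height)
    while len(clusters) > 1:
        best = None
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                key = (min(clusters[ia]), min(clusters[ib]))
                key = (min(key), max(key))
                c = crit[key]
                tag = (c, sorted(clusters[ia] + clusters[ib]))
                if best is None or tag < best[0]:
                    best = (tag, ia, ib, key)
        (c, _), ia, ib, key = best
        a, b = clusters[ia], clusters[ib]
        height = math.sqrt(c) if dialect == "D2" else c
        merges.append((list(a), list(b), height))
        na, nb = len(a), len(b)
        merged = sorted(a + b)
        kab = crit.pop(key)
        for ic, other in enumerate(clusters):
            if ic in (ia, ib):
                continue
            nk = len(other)
            ka = (min(min(a), min(other)), max(min(a), min(other)))
            kb = (min(min(b), min(other)), max(min(b), min(other)))
            cka, ckb = crit.pop(ka), crit.pop(kb)
            new = ((na + nk) * cka + (nb + nk) * ckb - nk * kab) / (na + nb + nk)
            km = (min(min(merged), min(other)), max(min(merged), min(other)))
            crit[km] = new
        clusters = [c for ic, c in enumerate(clusters) if ic not in (ia, ib)]
        clusters.append(merged)
    # cut: union members of merges with height <= cut
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, h in merges:
        if h <= cut_height:
            parent[find(a[0])] = find(b[0])
    labels = {}
    out = []
    for i in range(n):
        r = find(i)
        if r not in labels:
            labels[r] = len(labels) + 1
        out.append(labels[r])
    return out


def brute_min_cover_size(assay_sets: dict[str, set], coverable: set) -> int:
    """Smallest number of assays whose union covers ``coverable`` (exhaustive)."""
    assays = list(assay_sets)
    if not coverable:
        return 0
    for k in range(1, len(assays) + 1):
        for combo in itertools.combinations(assays, k):
            union = set()
            for a in combo:
                union |= assay_sets[a]
            if coverable <= union:
                return k
    raise AssertionError("coverable set not coverable by the full pool")


def naive_two_by_two(label, activity, eligible):
    tp = fp = fn = tn = 0
    for l, a, e in zip(label, activity, eligible):
        if not e:
            continue
        if l and a:
            tp += 1
        elif l and not a:
            fn += 1
        elif not l and a:
            fp += 1
        else:
            tn += 1
    return tp, fp, fn, tn
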