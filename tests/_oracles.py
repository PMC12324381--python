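"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive every quantity from first principles
(exhaustive neighbour counting, breadth-first reachability, direct
formula evaluation, full rank-arrangement enumeration) and share no
code with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """Reference DBSCAN: returns (core set, outlier set, partition, labels).

    Core points: ≥ min_pts points (self included) within the closed
    eps-ball. Clusters: exhaustive reachability across core points.
    Boundary points attach to the cluster of the lowest-index core
    point within eps. Labels are numbered by first core point index.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    within = d <= eps
    core = {i for i in range(n) if int(within[i].sum()) >= min_pts}

    labels = [-1] * n
    clusters = []
    seen = set()
    for i in range(n):  # ascending order fixes cluster numbering
        if i not in core or i in seen:
            continue
        comp = {i}
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k2 in range(n):
                if k2 in core and k2 not in comp and within[j, k2]:
                    comp.add(k2)
                    frontier.append(k2)
        seen |= comp
        idx = len(clusters)
        clusters.append(comp)
        for j in comp:
            labels[j] = idx
    for i in range(n):
        if i in core:
            continue
        for j in range(n):  # lowest-index core neighbour wins
            if j in core and within[i, j]:
                labels[i] = labels[j]
                break
    outliers = {i for i in range(n) if labels[i] == -1}
    partition = [frozenset(c) for c in clusters]
    return core, outliers, partition, labels


def direct_silhouette(points: np.ndarray, labels) -> np.ndarray:
    """Per-point silhouette by literal evaluation of the formula.

    s(i) = (b_i − a_i)/max(a_i, b_i) with a_i the mean distance to the
    other members of i's cluster and b_i the minimum over other
    clusters of the mean distance to their members; 0 where undefined
    (outliers, singleton clusters, fewer than two clusters).
    """
    pts = np.asarray(points, dtype=float)
    labels = list(labels)
    n = len(pts)
    ids = sorted({c for c in labels if c != -1})
    s = np.zeros(n)
    if len(ids) < 2:
        return s
    members = {c: [i for i in range(n) if labels[i] == c] for c in ids}
    for i in range(n):
        c = labels[i]
        if c == -1 or len(members[c]) < 2:
            continue
        a = float(
            np.mean([np.linalg.norm(pts[i] - pts[j]) for j in members[c] if j != i])
        )
        b = min(
            float(np.mean([np.linalg.norm(pts[i] - pts[j]) for j in members[o]]))
            for o in ids
            if o != c
        )
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return s


def enumerated_mwu_pvalue(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data).

    Enumerates every assignment of the pooled ranks to the first sample
    and compares the resulting U distribution with the observed one.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"
    n_a, n_b = len(a), len(b)
    rank = {v: r for r, v in enumerate(pooled)}
    obs_u = sum(1 for x in a for y in b if x > y)
    total = comb(n_a + n_b, n_a)
    count_le = count_ge = 0
    idx = list(range(n_a + n_b))
    for chosen in combinations(idx, n_a):
        chosen_set = set(chosen)
        u = sum(
            1
            for i in chosen_set
            for j in idx
            if j not in chosen_set and i > j
        )
        if u <= obs_u:
            count_le += 1
        if u >= obs_u:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return float(obs_u), min(p, 1.0)
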