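"""Independent brute-force oracles used to cross-check the implementation."""

import math


def brute_force_dbscan(points, eps, min_pts):
    """Textbook DBSCAN by exhaustive epsilon-neighborhood expansion.

    Points are scanned in lexicographic order; clusters are grown one at a
    time with breadth-first expansion from core points, so border points go
    to the first core cluster that reaches them. Returns (clusters, noise)
    as sets of point tuples.
    """
    pts = sorted(map(tuple, points))
    n = len(pts)

    def neighbors(i):
        return [j for j in range(n) if math.dist(pts[i], pts[j]) <= eps]

    core = [len(neighbors(i)) >= min_pts for i in range(n)]
    labels: list[int | None] = [None] * n
    n_clusters = 0
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        labels[i] = n_clusters
        queue = [i]
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in neighbors(j):
                if labels[k] is None:
                    labels[k] = n_clusters
                    queue.append(k)
        n_clusters += 1
    clusters = [
        frozenset(pts[i] for i in range(n) if labels[i] == lab)
        for lab in range(n_clusters)
    ]
    noise = frozenset(pts[i] for i in range(n) if labels[i] is None)
    return clusters, noise


def hand_scores(tp, tn, fp, fn):
    """The five summary metrics written out directly; None when undefined."""
    out = {}
    total = tp + tn + fp + fn
    out["accuracy"] = (tp + tn) / total if total else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["recall"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    p, r = out["precision"], out["recall"]
    out["f1"] = (2 * p * r / (p + r)) if p is not None and r is not None and p + r else None
    return out
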