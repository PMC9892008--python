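"""Independent oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np


def mrca_patristic_oracle(tree, leaves: list[str]) -> np.ndarray:
    """Brute-force patristic distances via root paths and MRCA depths.

    Walks parent chains explicitly: depth(x) is the summed edge length from
    the root to x, and d(x, y) = depth(x) + depth(y) - 2 * depth(mrca(x, y)),
    where the MRCA is the deepest node common to both root paths. Independent
    of any library distance-matrix routine.
    """
    node_of = {}
    for leaf in tree.leaf_node_iter():
        node_of[leaf.taxon.label] = leaf

    def root_path(node):
        chain = []  # (node id, distance from the leaf) walking up to the root
        dist = 0.0
        while node is not None:
            chain.append((id(node), dist))
            dist += node.edge.length or 0.0
            node = node.parent_node
        leaf_depth = dist
        depth_of = {nid: leaf_depth - d for nid, d in chain}
        return depth_of, leaf_depth

    info = {label: root_path(node_of[label]) for label in leaves}
    n = len(leaves)
    out = np.zeros((n, n))
    for i in range(n):
        anc_i, depth_i = info[leaves[i]]
        for j in range(i + 1, n):
            anc_j, depth_j = info[leaves[j]]
            common = set(anc_i) & set(anc_j)
            mrca_depth = max(anc_i[c] for c in common)
            out[i, j] = out[j, i] = depth_i + depth_j - 2 * mrca_depth
    return out


def chi2_yates_oracle(a: int, b: int, c: int, d: int) -> float:
    """Textbook 2x2 chi-squared with Yates correction:
    n (|ad - bc| - n/2)^2 / (r1 r2 c1 c2), clamped at 0 when the
    correction exceeds |ad - bc|."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    num = abs(a * d - b * c) - n / 2.0
    num = max(num, 0.0)
    return n * num**2 / (r1 * r2 * c1 * c2)


def chi2_plain_oracle(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected Pearson chi-squared: n (ad - bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def youden_bruteforce(same, unrelated, fp_bound=None):
    """Enumerate every candidate threshold (midpoints of consecutive sorted
    unique pooled values plus a below-minimum candidate) and scan J by
    direct counting. Returns (threshold, J, fp_fraction)."""
    same = np.asarray(same, float)
    unrel = np.asarray(unrelated, float)
    uniq = np.unique(np.concatenate([same, unrel]))
    below = uniq[0] / 2.0 if uniq[0] > 0 else -1e-12
    cands = [below] + [(uniq[k] + uniq[k + 1]) / 2.0 for k in range(len(uniq) - 1)]
    best = None
    for t in cands:
        tpr = np.mean(same <= t)
        fp = np.mean(unrel <= t)
        if fp_bound is not None and fp > fp_bound + 1e-12:
            continue
        j = tpr + (1 - fp) - 1
        if best is None or j > best[1] + 1e-15:
            best = (t, j, fp)
    return best
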