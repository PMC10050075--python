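"""Exhaustive domain-criteria oracle, independent of the production path.

Re-evaluates the calling criteria for every internal node of the
chromosome tree with naive loops straight from the data matrix, then
applies the no-qualifying-ancestor rule.
"""

import numpy as np
from scipy import stats

from crdomics import crd

# --------------------------------------------------------------------------

def oracle_call(matrix, window, factor=2.0, pair_alpha=0.01, cohesion=True):
    """Exhaustive evaluation of the domain criteria over all internal
    nodes of the chromosome tree, keeping nodes without a qualifying
    ancestor. Independent of the production path except for the tree
    itself (the traversal under test)."""
    assert len(set(matrix.chrom)) == 1
    x = matrix.values
    n = x.shape[0]
    ns = x.shape[1]
    r = np.corrcoef(x)
    tested = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and abs(i - j) <= window:
                tested[i, j] = True
    n_pairs = tested.sum() // 2
    if pair_alpha is None:
        thr = 0.0
    else:
        tcrit = stats.t.isf(pair_alpha / (2 * n_pairs), df=ns - 2)
        thr = tcrit / np.sqrt(ns - 2 + tcrit**2)

    def masked_abs(i, j):
        v = abs(r[i, j])
        return v if v >= thr else 0.0

    def mean_pairs(pairs):
        vals = [masked_abs(i, j) for i, j in pairs]
        return float(np.mean(vals)) if vals else None

    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if tested[i, j]]
    baseline_all = mean_pairs(all_pairs) or 0.0
    end_pairs = [(0, j) for j in range(1, n) if tested[0, j]]
    end_pairs += [(i, n - 1) for i in range(1, n - 1) if tested[i, n - 1]]
    baseline_ends = mean_pairs(end_pairs) or 0.0

    cmap = crd.correlation_map(matrix, window=window)[str(matrix.chrom[0])]
    tree = crd.build_tree(cmap)
    sat = {}
    for node in tree.internal_nodes():
        m = list(tree.members(node))
        pairs = [(i, j) for i in m for j in m if i < j and tested[i, j]]
        v_all = mean_pairs(pairs)
        ok = v_all is not None and v_all > 0 and v_all >= factor * baseline_all
        if ok:
            first = min(m, key=lambda i: matrix.start[i])
            last = max(m, key=lambda i: matrix.start[i])
            ep = [(min(first, j), max(first, j)) for j in m
                  if j != first and tested[first, j]]
            ep += [(min(last, j), max(last, j)) for j in m
                   if j != last and j != first and tested[last, j]]
            v_edge = mean_pairs(list(dict.fromkeys(ep)))
            ok = v_edge is not None and v_edge > 0 and v_edge >= factor * baseline_ends
        if ok:
            starts = matrix.start[m]
            ends = matrix.end[m]
            ok = bool(starts.max() >= ends.min())
        if ok and cohesion:
            a, b = tree.children(node)
            la, lb = list(tree.members(a)), list(tree.members(b))
            cross = [(min(i, j), max(i, j)) for i in la for j in lb if tested[i, j]]
            v_cross = mean_pairs(cross)
            ok = v_cross is not None and v_cross > 0 and v_cross >= factor * baseline_all
        sat[node] = ok

    ancestors = {}
    for node in tree.internal_nodes():
        a, b = tree.children(node)
        for ch in (a, b):
            ancestors[ch] = node
    result = []
    for node, ok in sat.items():
        if not ok:
            continue
        anc = ancestors.get(node)
        blocked = False
        while anc is not None:
            if sat.get(anc):
                blocked = True
                break
            anc = ancestors.get(anc)
        if not blocked:
            result.append(frozenset(int(i) for i in tree.members(node)))
    return set(result)


def _called_sets(matrix, crds):
    index = {str(pid): i for i, pid in enumerate(matrix.ids)}
    return {frozenset(index[m] for m in c.members) for c in crds}


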