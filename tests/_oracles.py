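"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's branch-matrix machinery: branches
are enumerated by walking each leaf's path to the root, and test statistics
are computed from explicit design/hat matrices. They are slow and simple on
purpose.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def leaf_root_paths(tree):
    """leaf name -> list of nodes on the path leaf -> root (root excluded)."""
    paths = {}
    for tip in tree.tips():
        node, path = tip, []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path
    return paths


def enumerate_branches(tree):
    """[(length, set_of_descendant_leaf_names)] for every non-root edge."""
    branches = {}
    for leaf, path in leaf_root_paths(tree).items():
        for node in path:
            entry = branches.setdefault(id(node),
                                        [float(node.length or 0.0), set()])
            entry[1].add(leaf)
    return [(length, leaves) for length, leaves in branches.values()]


def brute_shannon(counts):
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)


def brute_faith_pd(present, tree):
    return sum(length for length, leaves in enumerate_branches(tree)
               if leaves & set(present))


def brute_weighted_pd(count_by_leaf, tree, normalized=True):
    total = sum(count_by_leaf.values())
    p = {leaf: c / total for leaf, c in count_by_leaf.items()}
    present = {leaf for leaf, c in count_by_leaf.items() if c > 0}
    num, denom = 0.0, 0.0
    for length, leaves in enumerate_branches(tree):
        sub = leaves & present
        if not sub:
            continue
        a = sum(p[leaf] for leaf in sub) / len(sub)
        num += length * a
        denom += a
    if not normalized:
        return num
    return len(present) * num / denom


def brute_weighted_unifrac(x_by_leaf, y_by_leaf, tree, normalized=True):
    tx = sum(x_by_leaf.values())
    ty = sum(y_by_leaf.values())
    num, denom = 0.0, 0.0
    for length, leaves in enumerate_branches(tree):
        px = sum(x_by_leaf.get(leaf, 0) for leaf in leaves) / tx
        py = sum(y_by_leaf.get(leaf, 0) for leaf in leaves) / ty
        num += length * abs(px - py)
        denom += length * (px + py)
    if not normalized:
        return num
    return 0.0 if denom == 0 else num / denom


def _permanova_f(d, x):
    """Pseudo-F via explicit hat matrix from the design [1, x]."""
    n = len(x)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (np.asarray(d) ** 2) @ j
    X = np.column_stack([np.ones(n), x])
    h = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_model = np.trace(h @ g @ h)
    ss_resid = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
    return (ss_model / 1) / (ss_resid / (n - 2)), ss_model, ss_resid


def brute_permanova_exact(d, x):
    """(F_obs, exact p) by enumerating all n! covariate permutations."""
    x = np.asarray(x, dtype=float)
    f_obs, _, _ = _permanova_f(d, x)
    n = len(x)
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        f, _, _ = _permanova_f(d, x[list(perm)])
        count += f >= f_obs - 1e-12
        total += 1
    return f_obs, count / total


def brute_anova_f(values, codes, k):
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    ssb = sum(((values[codes == g].mean() - grand) ** 2) * (codes == g).sum()
              for g in range(k))
    ssw = sum(((values[codes == g] - values[codes == g].mean()) ** 2).sum()
              for g in range(k))
    return (ssb / (k - 1)) / (ssw / (len(values) - k))
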