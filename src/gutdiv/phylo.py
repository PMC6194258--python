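"""Branch-incidence representation of a rooted phylogeny.

Every diversity quantity used here (Faith's PD, abundance-weighted PD,
weighted UniFrac) is a sum over branches of the tree in which each branch
contributes through the set of leaves that descend from it. Precomputing a
boolean branch x leaf incidence matrix turns all of them into dense linear
algebra, which matters when the same tree is reused over thousands of
rarefaction runs.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


class BranchMatrix:
    """Branch lengths and leaf-descendancy incidence for a fixed leaf order.

    Branches are the edges above every non-root node; the root's own length
    is treated as 0 and excluded.
    """

    def __init__(self, tree: TreeNode, otu_ids) -> None:
        self.otu_ids = list(otu_ids)
        index = {name: i for i, name in enumerate(self.otu_ids)}
        if len(index) != len(self.otu_ids):
            raise ValueError("otu_ids must be unique")
        tip_names = {t.name for t in tree.tips()}
        missing = [o for o in self.otu_ids if o not in tip_names]
        if missing:
            raise ValueError(f"OTUs not found as tree leaves: {missing}")

        lengths: list[float] = []
        rows: list[np.ndarray] = []
        # postorder so a node's leaf set is the union of its children's
        leafsets: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(self.otu_ids), dtype=bool)
                if node.name in index:
                    mask[index[node.name]] = True
            else:
                mask = np.zeros(len(self.otu_ids), dtype=bool)
                for child in node.children:
                    mask |= leafsets[id(child)]
            leafsets[id(node)] = mask
            if node is not tree:
                lengths.append(float(node.length or 0.0))
                rows.append(mask)
        self.lengths = np.asarray(lengths, dtype=float)
        self.incidence = np.asarray(rows, dtype=bool)

    @property
    def n_branches(self) -> int:
        return self.lengths.size

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def branch_fractions(self, counts: np.ndarray) -> np.ndarray:
        """Fraction of each sample's reads descending from every branch.

        ``counts`` is (n_otus,) or (n_otus, n_samples); returns
        (n_branches,) or (n_branches, n_samples).
        """
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("every sample must have positive total reads")
        return self.incidence @ (counts / totals)
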