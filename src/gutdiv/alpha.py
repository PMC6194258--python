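"""Alpha-diversity indices: Shannon, Faith's PD and abundance-weighted PD.

All three are computed over a sample's OTU read counts; the phylogenetic
pair additionally needs the OTU tree, supplied as a
:class:`~gutdiv.phylo.BranchMatrix`. No rRNA copy-number correction is
applied anywhere.
"""

from __future__ import annotations

import numpy as np

from .phylo import BranchMatrix


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i, natural log by default.

    ``base`` switches the logarithm base (2 or 10) when set.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index needs at least one read")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def faith_pd(present_otus, bm: BranchMatrix, rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of a set of present OTUs.

    Sum of branch lengths of the minimal subtree connecting the present
    leaves and the root. ``rooted=False`` drops the branches on the path
    from the subtree's own most recent common ancestor up to the root.
    """
    present = set(present_otus)
    if not present:
        raise ValueError("at least one OTU must be present")
    unknown = present - set(bm.otu_ids)
    if unknown:
        raise ValueError(f"present OTUs not in tree: {sorted(unknown)}")
    mask = np.isin(bm.otu_ids, list(present))
    # per branch: number of present descendants
    spans = bm.incidence.astype(np.int64) @ mask.astype(np.int64)
    on_subtree = spans > 0
    if not rooted:
        # branches whose descendant set contains *all* present leaves lie on
        # the root path above the MRCA and are excluded
        on_subtree &= spans < mask.sum()
    return float(bm.lengths[on_subtree].sum())


def weighted_pd(counts, bm: BranchMatrix, normalized: bool = True) -> float:
    """Abundance-weighted phylogenetic diversity (weighted-Faith form).

    PD_w = S * (sum_b l_b A_b) / (sum_b A_b) over the branches b of the
    spanning subtree of present taxa, where l_b is branch length, A_b the
    mean relative abundance of present OTUs descending from b, and S the
    number of present OTUs. ``normalized=False`` returns the plain
    branch-abundance sum ``sum_b l_b A_b`` instead.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(bm.otu_ids),):
        raise ValueError("counts must align with the BranchMatrix OTU order")
    total = counts.sum()
    if total <= 0:
        raise ValueError("weighted PD needs at least one read")
    p = counts / total
    present = counts > 0
    # present OTUs below each branch
    n_under = bm.incidence.astype(np.int64) @ present.astype(np.int64)
    on_subtree = n_under > 0
    p_under = bm.incidence @ p
    a = p_under[on_subtree] / n_under[on_subtree]
    lengths = bm.lengths[on_subtree]
    if not normalized:
        return float((lengths * a).sum())
    s = int(present.sum())
    return float(s * (lengths * a).sum() / a.sum())


def alpha_table(counts_matrix: np.ndarray, bm: BranchMatrix,
                weighted_normalized: bool = True) -> np.ndarray:
    """Vectorised (shannon, pd, weighted_pd) for an OTU x sample count matrix.

    Returns an array of shape (3, n_samples). Used by the rarefaction
    ensemble summaries where the per-sample scalar functions would dominate
    the run time.
    """
    counts = np.asarray(counts_matrix, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample must have positive total reads")
    p = counts / totals

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    h = -(p * logp).sum(axis=0)

    present = counts > 0
    n_under = bm.incidence.astype(float) @ present  # (B, S)
    on = n_under > 0
    pd_vals = (bm.lengths[:, None] * on).sum(axis=0)

    p_under = bm.incidence @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(on, p_under / np.where(on, n_under, 1.0), 0.0)
    la = (bm.lengths[:, None] * a).sum(axis=0)
    if weighted_normalized:
        s = present.sum(axis=0)
        wpd = s * la / a.sum(axis=0)
    else:
        wpd = la
    return np.vstack([h, pd_vals, wpd])
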