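"""Permutational multivariate statistics and the diet regressions.

PERMANOVA with a single continuous covariate (pseudo-F on a Gower-centered
inner-product matrix, significance by permuting the covariate), a
betadisper-style homogeneity-of-dispersions permutation test, the
multivariate variance sum(d_i^2)/(n-1) of replicate communities around their
treatment centroid, one-way ANOVA with Tukey HSD, and ordinary least squares
of log10-transformed abundance ratios on dietary yeast concentration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .beta import DistanceMatrix, pcoa


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J D^2 J."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    return (g + g.T) / 2


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p: float
    df_model: int
    df_resid: int
    n_perm: int


def permanova(dist: DistanceMatrix, covariate, n_perm: int = 999,
              seed: int | None = 0,
              method: str = "monte_carlo") -> PermanovaResult:
    """Distance-based pseudo-F test for one continuous covariate.

    With the design X = [1, x], SS_model = tr(HGH) and SS_resid =
    tr((I-H)G(I-H)); for a single centered covariate u this reduces to
    SS_model = u'Gu with SS_resid = tr(G) - u'Gu. Significance comes from
    whole-row permutation of the covariate: the Monte Carlo p-value counts
    the observed statistic ((1 + #{F* >= F}) / (n_perm + 1)); with
    ``method="exact"`` all n! permutations are enumerated instead (only
    sensible for small n) and p = #{F* >= F} / n!.
    """
    x = np.asarray(covariate, dtype=float)
    d = dist.data
    n = d.shape[0]
    if x.shape != (n,):
        raise ValueError("covariate must align with the distance matrix")
    if n < 3:
        raise ValueError("PERMANOVA needs at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: no model degrees of freedom")

    g = gower_center(d)
    ss_total = float(np.trace(g))
    df_model, df_resid = 1, n - 2

    def f_of(xs: np.ndarray) -> np.ndarray:
        """Pseudo-F for covariate rows of xs (m, n)."""
        xc = xs - xs.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(xc, axis=1)
        u = xc / norms[:, None]
        ss_model = np.einsum("pi,ij,pj->p", u, g, u)
        ss_resid = ss_total - ss_model
        return (ss_model / df_model) / (ss_resid / df_resid)

    f_obs = float(f_of(x[None, :])[0])
    xc = x - x.mean()
    u = xc / np.linalg.norm(xc)
    ss_model = float(u @ g @ u)
    r2 = ss_model / ss_total

    if method == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = f_of(x[perms])
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_used = len(perms)
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        f_perm = f_of(x[perms])
        p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (n_perm + 1)
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(F=f_obs, R2=float(r2), p=float(p),
                           df_model=df_model, df_resid=df_resid,
                           n_perm=n_used)


@dataclass
class DispersionResult:
    distances: pd.Series
    group_variances: pd.Series
    F: float
    p: float
    df_model: int
    df_resid: int
    n_perm: int


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int
             ) -> np.ndarray:
    """One-way ANOVA F for one or many label assignments (vectorised).

    ``codes`` is (m, n) of integer group codes; returns (m,) F statistics.
    """
    m, n = codes.shape
    onehot = np.zeros((m, n, n_groups))
    rows = np.arange(n)
    for i in range(m):
        onehot[i, rows, codes[i]] = 1.0
    counts = onehot.sum(axis=1)  # (m, k)
    sums = np.einsum("mnk,n->mk", onehot, values)
    means = sums / counts
    grand = values.mean()
    ss_between = (counts * (means - grand) ** 2).sum(axis=1)
    ss_total = ((values - grand) ** 2).sum()
    ss_within = ss_total - ss_between
    df_b, df_w = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.where(np.isfinite(f), f, 0.0)


def dispersion_test(dist: DistanceMatrix, groups, n_perm: int = 999,
                    seed: int | None = 0,
                    method: str = "monte_carlo") -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Samples are embedded by PCoA; each sample's distance to its group
    centroid is the corrected Euclidean distance (squared distance on the
    positive axes minus squared distance on the negative axes, floored at 0
    before the square root, the standard correction for non-Euclidean
    distance matrices). The F statistic is a one-way ANOVA on these
    distances and its null distribution comes from permuting group labels.
    """
    labels = pd.Series(list(groups), index=dist.sample_ids)
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")

    emb = pcoa(dist)
    cat = labels.astype("category")
    codes = cat.cat.codes.to_numpy()
    k = len(cat.cat.categories)
    d = np.empty(len(labels))
    for gcode in range(k):
        m = codes == gcode
        cp = emb.coords[m] - emb.coords[m].mean(axis=0)
        cn = emb.neg_coords[m] - emb.neg_coords[m].mean(axis=0)
        d2 = (cp ** 2).sum(axis=1) - (cn ** 2).sum(axis=1)
        d[m] = np.sqrt(np.maximum(d2, 0.0))

    ns = np.array([(codes == gcode).sum() for gcode in range(k)])
    variances = pd.Series(
        [float((d[codes == gcode] ** 2).sum() / (ns[gcode] - 1))
         for gcode in range(k)],
        index=list(cat.cat.categories))

    f_obs = float(_anova_f(d, codes[None, :], k)[0])
    if method == "exact":
        perms = np.array(list(set(
            itertools.permutations(codes.tolist()))))
        f_perm = _anova_f(d, perms, k)
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        f_perm = _anova_f(d, perms, k)
        p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (n_perm + 1)
        n_used = n_perm
    return DispersionResult(
        distances=pd.Series(d, index=dist.sample_ids),
        group_variances=variances, F=f_obs, p=float(p),
        df_model=k - 1, df_resid=len(labels) - k, n_perm=n_used)


def multivariate_variance(coords: np.ndarray, sample_ids, groups
                          ) -> pd.Series:
    """Per-group multivariate variance sum(d_i^2)/(n-1).

    d_i is the Euclidean distance of community i to its group centroid in
    the supplied ordination coordinates (NMDS space in the main analysis).
    """
    coords = np.asarray(coords, dtype=float)
    labels = pd.Series(list(groups), index=list(sample_ids))
    out = {}
    for name, members in labels.groupby(labels):
        idx = [list(sample_ids).index(s) for s in members.index]
        if len(idx) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        pts = coords[idx]
        centroid = pts.mean(axis=0)
        d2 = ((pts - centroid) ** 2).sum(axis=1)
        out[name] = float(d2.sum() / (len(idx) - 1))
    return pd.Series(out)


@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    df_model: int
    df_resid: int
    tukey: pd.DataFrame  # columns group1, group2, meandiff, p_adj


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA omnibus test plus Tukey HSD pairwise comparisons."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[labels == g] for g in uniq]
    if any(len(v) < 2 for v in by_group):
        raise ValueError("every group needs at least 2 observations")
    if np.allclose(values, values[0]):
        raise ValueError("degenerate data: all values identical")
    f, p = sps.f_oneway(*by_group)
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(hsd.summary().data[1:],
                         columns=hsd.summary().data[0])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})[
        ["group1", "group2", "meandiff", "p_adj"]]
    tukey["p_adj"] = tukey["p_adj"].astype(float)
    return AnovaTukeyResult(F=float(f), p=float(p),
                            df_model=len(uniq) - 1,
                            df_resid=len(values) - len(uniq), tukey=tukey)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p: float
    n: int


def loglinear_regression(y, x) -> RegressionResult:
    """OLS of log10(y) on x with adjusted R^2 and a t-test on the slope.

    ``y`` must be strictly positive; a zero or negative value is an error
    naming the offending sample (index when y is a Series).
    """
    ys = pd.Series(y, dtype=float)
    x = np.asarray(x, dtype=float)
    bad = ys <= 0
    if bad.any():
        raise ValueError(
            f"log-transform undefined for non-positive ratios at "
            f"{list(ys.index[bad])}")
    if len(ys) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = sps.linregress(x, np.log10(ys.to_numpy()))
    n = len(ys)
    r2 = float(res.rvalue ** 2)
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept), r2=r2,
                            adj_r2=float(adj), p=float(res.pvalue), n=n)
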