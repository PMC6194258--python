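"""One-call orchestration of the full analysis chain.

filter -> rarefy -> alpha indices + diet regression -> beta distances ->
PERMANOVA / dispersion permutation tests / NMDS-space multivariate
variances -> absolute-abundance regressions (read-ratio and qPCR), with a
JSON-serialisable report carrying medians and ranges across rarefaction
runs plus full provenance (config and seeds). Robustness variants: diet as
a categorical factor, rarefying to a fraction of the smallest sample, and
restricting to the N most abundant OTUs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import TreeNode

from . import __version__
from .abundance import (abundance_regression, conc_relative_to_mock,
                        qpcr_ratio_series, read_ratio)
from .beta import distance_matrix, nmds
from .filtering import FilterParams, apply_two_step_filter
from .io import CountMatrix, partition_wolbachia
from .phylo import BranchMatrix
from .rarefaction import (build_ensemble, summarize_alpha, summarize_stats)
from .stats import (anova_tukey, dispersion_test, multivariate_variance,
                    permanova)


@dataclass
class PipelineConfig:
    """Tunable parameters of a full pipeline run."""

    filter_params: FilterParams = field(default_factory=FilterParams)
    alpha_runs: int = 1000
    beta_runs: int = 100
    depth: object = "auto"
    depth_fraction: float | None = None  # e.g. 0.75 robustness variant
    top_n: int | None = None  # e.g. 20 most abundant OTUs
    metrics: tuple[str, ...] = ("bray_curtis", "weighted_unifrac")
    unifrac_normalized: bool = True
    n_perm: int = 999
    nmds_restarts: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        d["depth"] = self.depth if self.depth == "auto" else int(self.depth)
        return d


def top_n_otus(cm: CountMatrix, n: int = 20,
               by: str = "mean_relative") -> CountMatrix:
    """Keep the n OTUs most abundant on average across samples.

    ``by="mean_relative"`` ranks by the mean of per-sample relative
    abundances (robust to depth differences); ``by="pooled_reads"`` ranks
    by total reads instead. Ties break by total reads, then OTU id.
    """
    if n > len(cm.otu_ids):
        raise ValueError(f"n={n} exceeds the {len(cm.otu_ids)} OTUs")
    totals = cm.counts.sum(axis=0)
    rel = cm.counts.div(totals.replace(0, 1), axis=1)
    if by == "mean_relative":
        score = rel.mean(axis=1)
    elif by == "pooled_reads":
        score = cm.counts.sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown ranking {by!r}")
    order = pd.DataFrame({
        "score": score, "reads": cm.counts.sum(axis=1),
    }).sort_values(["score", "reads"], ascending=False,
                   kind="mergesort")
    keep = sorted(order.index[:n], key=cm.otu_ids.index)
    return cm.select_otus(keep)


def diet_regression_block(values: pd.Series, meta: pd.DataFrame) -> dict:
    """Continuous diet regression + categorical ANOVA/Tukey on index values."""
    diets = meta.loc[values.index, "diet_yeast_pct"].astype(float)
    res = sps.linregress(diets.to_numpy(), values.to_numpy())
    n = len(values)
    r2 = float(res.rvalue ** 2)
    cat = anova_tukey(values.to_numpy(), [f"{d:g}%" for d in diets])
    return {
        "slope": float(res.slope), "intercept": float(res.intercept),
        "adj_r2": 1 - (1 - r2) * (n - 1) / (n - 2), "p": float(res.pvalue),
        "anova_F": cat.F, "anova_p": cat.p,
        "tukey": [{"group1": str(r.group1), "group2": str(r.group2),
                   "p_adj": float(r.p_adj)} for r in cat.tukey.itertuples()],
    }


def run_pipeline(counts: CountMatrix, tree: TreeNode, taxonomy: pd.Series,
                 qpcr: pd.DataFrame, metadata: pd.DataFrame,
                 cfg: PipelineConfig | None = None) -> dict:
    """Run the full analysis and return a JSON-serialisable report.

    Deterministic for a fixed config: every random stage draws its seed
    from ``cfg.seed`` through a seed sequence. The same beta-diversity
    rarefaction ensemble is shared by both distance metrics.
    """
    if cfg is None:
        cfg = PipelineConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seed_alpha, seed_beta, seed_perm, seed_nmds = [
        int(s) & 0x7FFFFFFF for s in ss.generate_state(4)]

    micro, wb_reads = partition_wolbachia(counts, taxonomy)
    conc = conc_relative_to_mock(qpcr, counts.mock_sample)
    total_reads = counts.sample_totals()
    filtered, filter_report = apply_two_step_filter(
        micro, conc, cfg.filter_params, total_reads=total_reads)
    if cfg.top_n is not None:
        filtered = top_n_otus(filtered, cfg.top_n)

    bm = BranchMatrix(tree, filtered.otu_ids)
    diets = metadata.loc[filtered.sample_ids, "diet_yeast_pct"].astype(float)
    diet_labels = [f"{d:g}%" for d in diets]

    # --- alpha diversity across independently rarefied tables
    alpha_ens = build_ensemble(filtered, depth=cfg.depth,
                               n_runs=cfg.alpha_runs,
                               master_seed=seed_alpha,
                               depth_fraction=cfg.depth_fraction)
    alpha = summarize_alpha(alpha_ens, bm)
    alpha_tests = {
        name: diet_regression_block(alpha[f"{name}_mean"], metadata)
        for name in ("shannon", "pd", "weighted_pd")}

    # --- beta diversity: one shared ensemble, per-run test statistics
    beta_ens = build_ensemble(filtered, depth=cfg.depth,
                              n_runs=cfg.beta_runs, master_seed=seed_beta,
                              depth_fraction=cfg.depth_fraction)
    beta_report = {}
    for metric in cfg.metrics:
        per_run: dict[str, list[float]] = {}
        var_runs: dict[str, list[float]] = {}
        for i in range(beta_ens.n_runs):
            table = beta_ens.run_frame(i)
            dm = distance_matrix(table, metric, bm=bm,
                                 normalized=cfg.unifrac_normalized)
            ad = permanova(dm, diets.to_numpy(), n_perm=cfg.n_perm,
                           seed=seed_perm + i)
            disp = dispersion_test(dm, diet_labels, n_perm=cfg.n_perm,
                                   seed=seed_perm + i)
            ord_ = nmds(dm, k=2, restarts=cfg.nmds_restarts,
                        seed=seed_nmds + i)
            mv = multivariate_variance(ord_.coords, dm.sample_ids,
                                       diet_labels)
            for k, v in [("adonis_F", ad.F), ("adonis_p", ad.p),
                         ("adonis_R2", ad.R2), ("dispersion_F", disp.F),
                         ("dispersion_p", disp.p),
                         ("nmds_stress", ord_.stress)]:
                per_run.setdefault(k, []).append(v)
            for grp, v in mv.items():
                var_runs.setdefault(str(grp), []).append(float(v))
        summaries = summarize_stats(per_run)
        beta_report[metric] = {
            "tests": {k: s.to_dict() for k, s in summaries.items()},
            "multivariate_variance": {
                grp: {"mean": float(np.mean(v)), "min": float(np.min(v)),
                      "max": float(np.max(v)), "n_runs": len(v)}
                for grp, v in sorted(var_runs.items())},
        }

    # --- absolute abundance: read ratio and qPCR, each with diet regression
    rr = read_ratio(filtered, wb_reads)
    abundance_report = {"read_ratio": abundance_regression(rr, metadata
                                                           ).to_dict()}
    ratio_by_diet = {
        f"{d:g}%": float(rr.ratios[diets[diets == d].index].mean())
        for d in sorted(diets.unique())}
    abundance_report["read_ratio"]["mean_ratio_by_diet"] = ratio_by_diet
    for target in ("Acetobacteraceae", "Firmicutes"):
        series = qpcr_ratio_series(qpcr, target)
        series.ratios = series.ratios.loc[
            [s for s in filtered.sample_ids if s in series.ratios.index]]
        abundance_report[f"qpcr_{target}"] = abundance_regression(
            series, metadata).to_dict()

    report = {
        "provenance": {
            "gutdiv_version": __version__,
            "config": cfg.to_dict(),
            "seeds": {"alpha": seed_alpha, "beta": seed_beta,
                      "perm": seed_perm, "nmds": seed_nmds},
            "alpha_depth": alpha_ens.depth,
            "beta_depth": beta_ens.depth,
        },
        "filter": filter_report.to_dict(),
        "alpha": {
            "per_sample": {
                s: {c: float(alpha.loc[s, c]) for c in alpha.columns}
                for s in alpha.index},
            "diet_tests": alpha_tests,
        },
        "beta": beta_report,
        "abundance": abundance_report,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialisation used for determinism checks."""
    return json.dumps(report, indent=2, sort_keys=True)
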