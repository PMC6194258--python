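#!/usr/bin/env python
"""Beta diversity, permutational tests and NMDS-space variances.

Builds one 100-run rarefaction ensemble shared by both distance metrics
(Bray-Curtis and weighted UniFrac). For every rarefied table it computes
the distance matrix, runs PERMANOVA on yeast content (continuous, 999
permutations), the centroid-based dispersion permutation test on diet
groups, and the per-diet multivariate variance sum(d_i^2)/(n-1) in 2-D NMDS
space; medians and ranges across runs are reported.
"""

import json
import warnings
from pathlib import Path

import numpy as np

from gutdiv import io
from gutdiv.beta import distance_matrix, nmds
from gutdiv.phylo import BranchMatrix
from gutdiv.rarefaction import build_ensemble, summarize_stats
from gutdiv.stats import dispersion_test, multivariate_variance, permanova

SRC_SIM = Path("results/simulated")
SRC_FILT = Path("results/filtering")
OUT = Path("results/beta")

N_RUNS = 100
N_PERM = 999
SEED = 202


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    filtered = io.read_count_table(SRC_FILT / "filtered_counts.tsv")
    tree = io.read_tree(SRC_SIM / "tree.nwk")
    meta = io.read_metadata(SRC_SIM / "metadata.csv")

    bm = BranchMatrix(tree, filtered.otu_ids)
    diets = meta.loc[filtered.sample_ids, "diet_yeast_pct"].astype(float)
    labels = [f"{d:g}%" for d in diets]
    ensemble = build_ensemble(filtered, depth="auto", n_runs=N_RUNS,
                              master_seed=SEED)

    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for metric in ("bray_curtis", "weighted_unifrac"):
            per_run, var_runs = {}, {}
            for i in range(ensemble.n_runs):
                dm = distance_matrix(ensemble.run_frame(i), metric, bm=bm)
                ad = permanova(dm, diets.to_numpy(), n_perm=N_PERM,
                               seed=SEED + i)
                disp = dispersion_test(dm, labels, n_perm=N_PERM,
                                       seed=SEED + i)
                ord_ = nmds(dm, k=2, restarts=4, seed=SEED + i)
                mv = multivariate_variance(ord_.coords, dm.sample_ids,
                                           labels)
                for k, v in (("adonis_F", ad.F), ("adonis_p", ad.p),
                             ("adonis_R2", ad.R2), ("dispersion_F", disp.F),
                             ("dispersion_p", disp.p),
                             ("nmds_stress", ord_.stress)):
                    per_run.setdefault(k, []).append(v)
                for grp, v in mv.items():
                    var_runs.setdefault(grp, []).append(float(v))
            results[metric] = {
                "tests": {k: s.to_dict()
                          for k, s in summarize_stats(per_run).items()},
                "nmds_variance": {
                    g: {"mean": float(np.mean(v)), "min": float(np.min(v)),
                        "max": float(np.max(v))}
                    for g, v in sorted(var_runs.items())},
            }

    (OUT / "beta_tests.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n")

    print(f"beta diversity over {N_RUNS} rarefactions "
          f"(median [min-max] across runs):")
    for metric, block in results.items():
        t = block["tests"]
        print(f"  {metric}:")
        print(f"    adonis     F = {t['adonis_F']['median']:.2f} "
              f"[{t['adonis_F']['min']:.2f}-{t['adonis_F']['max']:.2f}], "
              f"p = {t['adonis_p']['median']:.3f}, "
              f"R2 = {t['adonis_R2']['median']:.2f}")
        print(f"    dispersion F = {t['dispersion_F']['median']:.2f}, "
              f"p = {t['dispersion_p']['median']:.3f}")
        v = block["nmds_variance"]
        parts = ", ".join(f"{g}: {v[g]['mean']:.3f}" for g in sorted(v))
        print(f"    NMDS-space variance {parts}")
    print(f"  outputs in {OUT}/")


if __name__ == "__main__":
    main()
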