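"""Repeated independent rarefaction and uncertainty propagation.

Each rarefaction run subsamples every sample's reads without replacement
(multivariate hypergeometric) to a common depth. Downstream statistics are
computed once per run and reported as median plus [min, max] across runs,
so that rarefaction randomness is carried through to every F, p and R^2
rather than being averaged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .alpha import alpha_table
from .io import CountMatrix
from .phylo import BranchMatrix

ALPHA_INDICES = ("shannon", "pd", "weighted_pd")


def rarefy_sample(counts, depth: int, seed=None,
                  rng: np.random.Generator | None = None,
                  sample_id: str = "?") -> np.ndarray:
    """Subsample one sample's per-OTU reads to ``depth`` without replacement."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(
            f"depth {depth} exceeds the {total} reads of sample {sample_id}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(counts: pd.DataFrame, depth: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Rarefy every column of an OTU x sample table; returns an int array."""
    out = np.empty(counts.shape, dtype=np.int64)
    mat = counts.to_numpy()
    for j, sample in enumerate(counts.columns):
        out[:, j] = rarefy_sample(mat[:, j], depth, rng=rng,
                                  sample_id=str(sample))
    return out


@dataclass
class RarefactionEnsemble:
    """n_runs independently rarefied tables at a common depth.

    ``runs`` has shape (n_runs, n_otus, n_samples); every sample in every
    run sums to exactly ``depth``.
    """

    depth: int
    seeds: list[int]
    runs: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def run_frame(self, i: int) -> pd.DataFrame:
        return pd.DataFrame(self.runs[i], index=self.otu_ids,
                            columns=self.sample_ids)


def resolve_depth(cm: CountMatrix, depth="auto",
                  depth_fraction: float | None = None) -> int:
    """``"auto"`` resolves to the minimum per-sample read total; an optional
    fraction (e.g. 0.75) scales it down."""
    if depth == "auto":
        d = int(cm.sample_totals().min())
    else:
        d = int(depth)
    if depth_fraction is not None:
        d = int(np.floor(d * depth_fraction))
    if d < 1:
        raise ValueError("resolved rarefaction depth is below 1 read")
    return d


def run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds stretched from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_runs)
    return [int(s) & 0x7FFFFFFF for s in state]


def build_ensemble(cm: CountMatrix, depth="auto", n_runs: int = 100,
                   master_seed: int = 0,
                   depth_fraction: float | None = None
                   ) -> RarefactionEnsemble:
    """Build n_runs independently rarefied tables.

    Samples with fewer reads than the depth are dropped with a warning
    before ensembling (none are dropped at the default auto depth, which is
    the smallest sample total).
    """
    d = resolve_depth(cm, depth, depth_fraction)
    totals = cm.sample_totals()
    shallow = totals[totals < d].index.tolist()
    if shallow:
        warnings.warn(f"dropping samples below depth {d}: {shallow}",
                      stacklevel=2)
        cm = CountMatrix(cm.counts.drop(columns=shallow),
                         cm.mock_sample if cm.mock_sample not in shallow
                         else None)
        if not cm.sample_ids:
            raise ValueError("rarefaction depth exceeds every sample total")
    seeds = run_seeds(master_seed, n_runs)
    runs = np.empty((n_runs, len(cm.otu_ids), len(cm.sample_ids)),
                    dtype=np.int64)
    for i, s in enumerate(seeds):
        runs[i] = rarefy_table(cm.counts, d, np.random.default_rng(s))
    return RarefactionEnsemble(depth=d, seeds=seeds, runs=runs,
                               otu_ids=list(cm.otu_ids),
                               sample_ids=list(cm.sample_ids))


def summarize_alpha(ensemble: RarefactionEnsemble, bm: BranchMatrix
                    ) -> pd.DataFrame:
    """Per-sample mean and SD of each alpha index across rarefaction runs.

    Returns a DataFrame indexed by sample with columns
    ``{index}_mean``/``{index}_sd`` for shannon, pd, weighted_pd. With a
    single run the SD is reported as 0 by convention.
    """
    if ensemble.n_runs == 0:
        raise ValueError("empty ensemble")
    vals = np.empty((ensemble.n_runs, 3, len(ensemble.sample_ids)))
    for i in range(ensemble.n_runs):
        vals[i] = alpha_table(ensemble.runs[i], bm)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0) if ensemble.n_runs > 1 else np.zeros_like(mean)
    data = {}
    for k, name in enumerate(ALPHA_INDICES):
        data[f"{name}_mean"] = mean[k]
        data[f"{name}_sd"] = sd[k]
    return pd.DataFrame(data, index=ensemble.sample_ids)


@dataclass
class TestSummary:
    """Median and [min, max] of a statistic across rarefaction runs."""

    statistic: str
    median: float
    min: float
    max: float
    n_runs: int

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "median": self.median,
                "min": self.min, "max": self.max, "n_runs": self.n_runs}


def summarize_stats(per_run: dict[str, list[float]]) -> dict[str, TestSummary]:
    out = {}
    for name, vals in per_run.items():
        arr = np.asarray(vals, dtype=float)
        out[name] = TestSummary(statistic=name, median=float(np.median(arr)),
                                min=float(arr.min()), max=float(arr.max()),
                                n_runs=len(arr))
    return out


def summarize_beta(ensemble: RarefactionEnsemble,
                   test: Callable[[pd.DataFrame], dict[str, float]]
                   ) -> dict[str, TestSummary]:
    """Run a statistic-producing test once per rarefied table.

    ``test`` maps a rarefied OTU x sample DataFrame to a dict of named
    statistics (e.g. adonis F/p/R2, dispersion F/p); the summary carries
    the median and range of each across runs.
    """
    per_run: dict[str, list[float]] = {}
    for i in range(ensemble.n_runs):
        stats = test(ensemble.run_frame(i))
        for name, val in stats.items():
            per_run.setdefault(name, []).append(float(val))
    return summarize_stats(per_run)
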