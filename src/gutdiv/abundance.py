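"""Absolute microbiota abundance from read ratios and qPCR.

Two complementary quantifications: (1) the ratio of 16S microbiota reads to
reads attributed to the intracellular symbiont *Wolbachia*, and (2)
efficiency-corrected qPCR quantification of taxon 16S copies relative to a
host single-copy gene (rp49). Both ratios are log10-transformed and
regressed on dietary yeast concentration; a categorical ANOVA + Tukey HSD
variant is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix
from .stats import AnovaTukeyResult, RegressionResult, anova_tukey, \
    loglinear_regression


@dataclass
class RatioSeries:
    """Per-sample positive abundance ratios with their provenance."""

    ratios: pd.Series
    source: str  # "reads" or "qpcr"
    taxon: str
    flagged_zero: list[str]


def read_ratio(microbiota: CountMatrix, wolbachia_reads: pd.Series
               ) -> RatioSeries:
    """Total microbiota reads divided by *Wolbachia* reads, per sample.

    Samples whose microbiota column is all zero get ratio 0 and are flagged
    (they cannot enter a log regression); zero *Wolbachia* reads are an
    error naming the sample.
    """
    wb = pd.Series(wolbachia_reads, dtype=float)
    samples = microbiota.gut_samples
    missing = [s for s in samples if s not in wb.index]
    if missing:
        raise ValueError(f"missing Wolbachia read counts for: {missing}")
    zero_wb = [s for s in samples if wb.loc[s] <= 0]
    if zero_wb:
        raise ValueError(f"zero Wolbachia reads in samples: {zero_wb}")
    totals = microbiota.counts[samples].sum(axis=0).astype(float)
    ratios = totals / wb.loc[samples]
    flagged = [s for s in samples if totals.loc[s] == 0]
    return RatioSeries(ratios=ratios, source="reads",
                       taxon="microbiota", flagged_zero=flagged)


def qpcr_ratio(ct_target, ct_ref, eff_target: float, eff_ref: float):
    """Efficiency-corrected relative quantity of target vs reference.

    ratio = (1+eff_ref)^ct_ref / (1+eff_target)^ct_target, the standard
    delta-Ct model with per-primer amplification efficiencies (an
    efficiency of 1.0 means perfect doubling each cycle).
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    out = (1.0 + eff_ref) ** ct_ref / (1.0 + eff_target) ** ct_target
    return float(out) if out.ndim == 0 else out


def _mean_ct(qpcr: pd.DataFrame, target: str) -> tuple[pd.Series, float]:
    """Technical replicates averaged on the Ct scale; returns (Ct, efficiency)."""
    sub = qpcr[qpcr["target"] == target]
    if sub.empty:
        raise ValueError(f"no qPCR rows for target {target!r}")
    effs = sub["efficiency"].unique()
    if len(effs) != 1:
        raise ValueError(f"inconsistent efficiencies for target {target!r}")
    return sub.groupby("sample")["ct"].mean(), float(effs[0])


def qpcr_ratio_series(qpcr: pd.DataFrame, target: str,
                      reference: str = "rp49",
                      assume_perfect_efficiency: bool = False) -> RatioSeries:
    """Per-sample efficiency-corrected target:reference quantity ratios."""
    ct_t, eff_t = _mean_ct(qpcr, target)
    ct_r, eff_r = _mean_ct(qpcr, reference)
    samples = [s for s in ct_t.index if s in ct_r.index]
    missing = [s for s in ct_t.index if s not in ct_r.index]
    if missing:
        raise ValueError(
            f"missing reference ({reference}) Ct for samples: {missing}")
    if assume_perfect_efficiency:
        eff_t = eff_r = 1.0
    ratios = pd.Series(
        qpcr_ratio(ct_t.loc[samples].to_numpy(), ct_r.loc[samples].to_numpy(),
                   eff_t, eff_r),
        index=samples)
    return RatioSeries(ratios=ratios, source="qpcr", taxon=target,
                       flagged_zero=[])


def conc_relative_to_mock(qpcr: pd.DataFrame, mock_sample: str,
                          target: str = "universal_16S") -> pd.Series:
    """Per-sample total 16S concentration relative to the mock.

    conc_j = (1+eff)^(Ct_mock - Ct_j); the mock's own value is exactly 1.
    """
    ct, eff = _mean_ct(qpcr, target)
    if mock_sample not in ct.index:
        raise ValueError(f"mock sample {mock_sample!r} has no {target} Ct")
    return (1.0 + eff) ** (ct.loc[mock_sample] - ct)


@dataclass
class AbundanceRegressionReport:
    taxon: str
    source: str
    continuous: RegressionResult
    categorical: AnovaTukeyResult
    n_flagged_zero: int

    def to_dict(self) -> dict:
        c = self.continuous
        a = self.categorical
        return {
            "taxon": self.taxon, "source": self.source,
            "slope": c.slope, "intercept": c.intercept,
            "adj_r2": c.adj_r2, "p": c.p, "n": c.n,
            "anova_F": a.F, "anova_p": a.p,
            "tukey": [
                {"group1": str(r.group1), "group2": str(r.group2),
                 "p_adj": float(r.p_adj)}
                for r in a.tukey.itertuples()],
            "n_flagged_zero": self.n_flagged_zero,
        }


def abundance_regression(series: RatioSeries, meta: pd.DataFrame
                         ) -> AbundanceRegressionReport:
    """Log-linear diet regression plus the categorical ANOVA/Tukey variant.

    Flagged zero-ratio samples are excluded from the log regression but
    counted in the report.
    """
    usable = series.ratios[series.ratios > 0]
    diets = meta.loc[usable.index, "diet_yeast_pct"].astype(float)
    cont = loglinear_regression(usable, diets.to_numpy())
    cat = anova_tukey(np.log10(usable.to_numpy()),
                      [f"{d:g}%" for d in diets])
    return AbundanceRegressionReport(
        taxon=series.taxon, source=series.source, continuous=cont,
        categorical=cat, n_flagged_zero=len(series.flagged_zero))
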