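"""Two-step OTU filtering against sequencing noise and contamination.

Step 1 retains OTUs present in at least ``min_samples`` gut samples (the
mock is excluded from both criteria) and represented by at least
``min_total_reads`` reads summed over the gut samples. Step 2 estimates each
OTU's absolute abundance per sample -- relative read abundance scaled by the
sample's 16S DNA concentration measured relative to the mock -- and keeps an
OTU only if that abundance exceeds its mock abundance at least ``fold``-fold
in at least ``min_samples`` gut samples. Comparisons at the stated
thresholds are inclusive (>=); an OTU absent from the mock passes step 2
whenever it is present in enough gut samples, since fold x 0 = 0 makes the
rule vacuous there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class AbundanceMatrix:
    """Estimated per-OTU per-sample absolute 16S abundance (mock-relative units)."""

    abundance: pd.DataFrame  # otu x sample, non-negative reals
    mock_sample: str | None = None

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if (self.mock_sample is not None
                and self.mock_sample not in self.abundance.columns):
            raise ValueError("mock sample missing from abundance matrix")


@dataclass
class FilterParams:
    min_samples: int = 3
    min_total_reads: int = 24
    fold: float = 10.0


@dataclass
class FilterReport:
    n_input_otus: int
    n_pass_step1: int
    n_detected_in_mock: int
    n_removed_step2: int
    n_final: int
    params: FilterParams
    step_order: tuple[str, str] = ("prevalence", "mock_contamination")
    decisions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_otus": self.n_input_otus,
            "n_pass_step1": self.n_pass_step1,
            "n_detected_in_mock": self.n_detected_in_mock,
            "n_removed_step2": self.n_removed_step2,
            "n_final": self.n_final,
            "params": {"min_samples": self.params.min_samples,
                       "min_total_reads": self.params.min_total_reads,
                       "fold": self.params.fold},
            "step_order": list(self.step_order),
            "decisions": self.decisions,
        }


def prevalence_filter(cm: CountMatrix, min_samples: int = 3,
                      min_total_reads: int = 24) -> set[str]:
    """OTUs present (reads > 0) in >= min_samples gut samples with
    >= min_total_reads reads summed over gut samples."""
    gut = cm.gut_samples
    if min_samples > len(gut):
        raise ValueError(
            f"min_samples={min_samples} exceeds the {len(gut)} non-mock samples")
    sub = cm.counts[gut]
    prevalence = (sub > 0).sum(axis=1)
    totals = sub.sum(axis=1)
    keep = (prevalence >= min_samples) & (totals >= min_total_reads)
    return set(sub.index[keep])


def estimate_absolute_abundance(cm: CountMatrix, conc_16s: pd.Series,
                                total_reads: pd.Series | None = None
                                ) -> AbundanceMatrix:
    """a_ij = (reads_ij / total reads_j) * conc_j.

    ``conc_16s`` is the per-sample 16S DNA concentration relative to the
    mock (whose own value is 1 by definition). ``total_reads`` defaults to
    the table's column sums but can be supplied separately when the table
    holds only a subset of the sequenced reads (e.g. after partitioning out
    *Wolbachia*, while the concentration refers to total 16S DNA).
    """
    conc = pd.Series(conc_16s, dtype=float)
    missing = [s for s in cm.sample_ids if s not in conc.index]
    if missing:
        raise ValueError(f"missing 16S concentration for samples: {missing}")
    if (conc.loc[cm.sample_ids] <= 0).any():
        raise ValueError("16S concentrations must be positive")
    totals = (cm.sample_totals() if total_reads is None
              else pd.Series(total_reads, dtype=float).loc[cm.sample_ids])
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"samples with zero total reads get all-zero "
                      f"abundances: {zero}", stacklevel=2)
    safe = totals.replace(0, 1).astype(float)
    rel = cm.counts.div(safe, axis=1)
    ab = rel.mul(conc.loc[cm.sample_ids], axis=1)
    return AbundanceMatrix(ab, cm.mock_sample)


def mock_contamination_filter(abund: AbundanceMatrix, fold: float = 10.0,
                              min_samples: int = 3) -> set[str]:
    """OTUs whose gut abundance is >= fold x the mock abundance in >=
    min_samples gut samples; mock-absent OTUs need only presence."""
    if abund.mock_sample is None:
        raise ValueError("abundance matrix has no mock column")
    mock = abund.abundance[abund.mock_sample]
    gut_cols = [c for c in abund.abundance.columns if c != abund.mock_sample]
    gut = abund.abundance[gut_cols]
    threshold = fold * mock
    n_over = gut.ge(threshold, axis=0).sum(axis=1)
    n_present = (gut > 0).sum(axis=1)
    keep = np.where(mock > 0, n_over >= min_samples,
                    n_present >= min_samples)
    return set(gut.index[keep])


def apply_two_step_filter(cm: CountMatrix, conc_16s: pd.Series,
                          params: FilterParams | None = None,
                          total_reads: pd.Series | None = None
                          ) -> tuple[CountMatrix, FilterReport]:
    """Prevalence filter, then mock-anchored contamination filter.

    Returns the filtered CountMatrix (mock column dropped) and a report
    with a per-OTU decision trail. The step order is fixed: prevalence
    first, as recorded in the report.
    """
    if params is None:
        params = FilterParams()
    if cm.mock_sample is None:
        raise ValueError("two-step filter requires a designated mock sample")
    decisions: list[dict] = []

    pass1 = prevalence_filter(cm, params.min_samples, params.min_total_reads)
    gut = cm.gut_samples
    sub = cm.counts[gut]
    prevalence = (sub > 0).sum(axis=1)
    totals = sub.sum(axis=1)
    for otu in cm.otu_ids:
        if otu not in pass1:
            decisions.append({
                "otu": otu, "step": "prevalence", "decision": "removed",
                "n_samples_present": int(prevalence[otu]),
                "total_reads": int(totals[otu])})

    step1_cm = cm.select_otus([o for o in cm.otu_ids if o in pass1])
    abund = estimate_absolute_abundance(step1_cm, conc_16s, total_reads)
    mock_abund = abund.abundance[cm.mock_sample]
    n_in_mock = int((mock_abund > 0).sum())
    pass2 = mock_contamination_filter(abund, params.fold, params.min_samples)
    n_over = abund.abundance[gut].ge(params.fold * mock_abund,
                                     axis=0).sum(axis=1)
    for otu in step1_cm.otu_ids:
        decisions.append({
            "otu": otu, "step": "mock_contamination",
            "decision": "retained" if otu in pass2 else "removed",
            "mock_abundance": float(mock_abund[otu]),
            "n_samples_over_threshold": int(n_over[otu])})

    final_ids = [o for o in step1_cm.otu_ids if o in pass2]
    filtered = CountMatrix(cm.counts.loc[final_ids, gut], None)
    report = FilterReport(
        n_input_otus=len(cm.otu_ids),
        n_pass_step1=len(pass1),
        n_detected_in_mock=n_in_mock,
        n_removed_step2=len(pass1) - len(final_ids),
        n_final=len(final_ids),
        params=params,
        decisions=decisions)
    return filtered, report
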