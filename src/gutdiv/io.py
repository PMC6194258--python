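"""Readers, writers and the typed data model shared by every analysis stage.

The external formats are deliberately plain text: OTU tables as TSV (taxa as
rows, samples as columns), trees as Newick, taxonomy as two-column TSV, qPCR
and sample metadata as CSV. A count table may carry *Wolbachia* either as an
ordinary OTU row (identified through its taxonomy lineage) or as a reserved
row ``__wolbachia__`` holding a pre-computed per-sample total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

WOLBACHIA_ROW_ID = "__wolbachia__"

QPCR_TARGETS = ("Firmicutes", "Acetobacteraceae", "universal_16S", "rp49")


@dataclass
class CountMatrix:
    """Integer OTU x sample read counts with an optional mock-sample flag.

    ``counts`` is a pandas DataFrame indexed by OTU id with sample ids as
    columns. Counts are non-negative integers; ids are unique; the mock
    sample, when set, must be one of the columns.
    """

    counts: pd.DataFrame
    mock_sample: str | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.issubdtype(df.to_numpy().dtype, np.integer):
            raise ValueError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.mock_sample is not None and self.mock_sample not in df.columns:
            raise ValueError(
                f"mock sample {self.mock_sample!r} is not a column of the table"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gut_samples(self) -> list[str]:
        """Sample ids with the mock excluded."""
        return [s for s in self.counts.columns if s != self.mock_sample]

    def select_otus(self, otu_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(otu_ids)], self.mock_sample)

    def drop_mock(self) -> "CountMatrix":
        if self.mock_sample is None:
            return self
        return CountMatrix(self.counts[self.gut_samples], None)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_count_table(path, mock_sample_id: str | None = None) -> CountMatrix:
    """Read a tab-separated OTU table (first column OTU id, header sample ids).

    Non-integer cells raise a parse error naming the offending (OTU, sample)
    cell; duplicate ids and an absent mock id are errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
        if bad.any():
            otu = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer count at (OTU {otu!r}, sample {col!r}): "
                f"{raw.loc[otu, col]!r}"
            )
        parsed[col] = numeric
    counts = parsed.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    return CountMatrix(counts, mock_sample=mock_sample_id)


def write_count_table(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="otu_id")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0 (warned)."""
    tree = TreeNode.read(str(path), format="newick")
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        seen, dups = set(), set()
        for name in leaves:
            (dups if name in seen else seen).add(name)
        raise ValueError(f"duplicate leaf labels: {sorted(dups)}")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            if node is not tree:  # a rootless length is the normal case
                n_missing += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} branches had no length in the Newick input; set to 0",
            stacklevel=2,
        )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path) -> pd.Series:
    """Two-column TSV (otu_id, lineage) -> Series mapping OTU id to lineage."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"],
                     dtype=str)
    if df["otu_id"].duplicated().any():
        raise ValueError("duplicate OTU ids in taxonomy map")
    return df.set_index("otu_id")["lineage"]


def write_taxonomy(tax: pd.Series, path) -> None:
    tax.rename("lineage").rename_axis("otu_id").reset_index().to_csv(
        path, sep="\t", header=False, index=False
    )


def read_qpcr(path) -> pd.DataFrame:
    """CSV with header ``sample,target,ct,efficiency``.

    Technical replicates appear as repeated rows and are averaged downstream
    on the Ct scale. Efficiencies are fractions (1.03 = 103%).
    """
    df = pd.read_csv(path)
    expected = {"sample", "target", "ct", "efficiency"}
    if set(df.columns) != expected:
        raise ValueError(f"qPCR table must have columns {sorted(expected)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    if ((df["efficiency"] < 0.8) | (df["efficiency"] > 1.2)).any():
        raise ValueError("primer efficiencies must lie in [0.8, 1.2]")
    return df


def write_qpcr(df: pd.DataFrame, path) -> None:
    df[["sample", "target", "ct", "efficiency"]].to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """CSV with header ``sample,diet_yeast_pct,population``; indexed by sample."""
    df = pd.read_csv(path, dtype={"sample": str, "population": str})
    expected = {"sample", "diet_yeast_pct", "population"}
    if set(df.columns) != expected:
        raise ValueError(f"metadata must have columns {sorted(expected)}")
    return df.set_index("sample")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample").reset_index()[
        ["sample", "diet_yeast_pct", "population"]
    ].to_csv(path, index=False)


def is_wolbachia_lineage(lineage: str) -> bool:
    """Case-insensitive substring test for the genus *Wolbachia*.

    RDP-style lineage strings vary in rank prefixes and separators, so a
    substring match on the lineage is the robust rule.
    """
    return "wolbachia" in str(lineage).lower()


def partition_wolbachia(
    cm: CountMatrix, tax: pd.Series | dict
) -> tuple[CountMatrix, pd.Series]:
    """Split *Wolbachia* reads out of the table.

    Returns the microbiota-only CountMatrix and the per-sample *Wolbachia*
    read totals. The reserved row id ``__wolbachia__`` is treated as
    *Wolbachia* regardless of taxonomy. Per-sample reads are conserved:
    microbiota + wolbachia = input, exactly.
    """
    tax = pd.Series(tax)
    wb_rows = []
    for otu in cm.otu_ids:
        if otu == WOLBACHIA_ROW_ID:
            wb_rows.append(otu)
            continue
        if otu not in tax.index:
            raise ValueError(f"OTU {otu!r} has no taxonomy entry")
        if is_wolbachia_lineage(tax.loc[otu]):
            wb_rows.append(otu)
    if not wb_rows:
        warnings.warn("no Wolbachia-assigned OTU found; returning zeros",
                      stacklevel=2)
        wb_reads = pd.Series(0, index=cm.sample_ids, dtype=np.int64)
        return cm, wb_reads
    wb_reads = cm.counts.loc[wb_rows].sum(axis=0)
    keep = [o for o in cm.otu_ids if o not in set(wb_rows)]
    micro = CountMatrix(cm.counts.loc[keep], cm.mock_sample)
    return micro, wb_reads
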