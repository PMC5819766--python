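"""In-memory containers shared across the pipeline.

The universal currency is the :class:`FoldChangeMatrix`: a genes x
comparisons matrix of log2 fold changes, where each comparison (one
treatment-vs-control contrast) carries a study label. Gene identifiers are
opaque, case-sensitive strings; mapping probes to genes is upstream of this
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError


@dataclass
class FoldChangeMatrix:
    """Log2 fold changes for genes (rows) across comparisons (columns).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per comparison id.
        Must be fully numeric with no missing entries.
    study_ids
        One study label per comparison, aligned with ``values.columns``.
        When omitted, each comparison is treated as its own study.
    """

    values: pd.DataFrame
    study_ids: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate comparison ids: {list(dups[:5])}")
        if self.study_ids is None:
            self.study_ids = pd.Series(
                list(self.values.columns), index=self.values.columns, dtype=object
            )
        else:
            self.study_ids = pd.Series(self.study_ids, dtype=object)
            if len(self.study_ids) != self.values.shape[1]:
                raise FormatError(
                    "study_ids length does not match number of comparisons"
                )
            self.study_ids.index = self.values.columns
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("fold-change matrix body must be numeric")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                "missing value at gene "
                f"{self.values.index[i]!r}, comparison {self.values.columns[j]!r}; "
                "rows with missing values must be dropped upstream"
            )
        self.values = self.values.astype(float)

    # -- basic views -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_comparisons(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- subsetting --------------------------------------------------------
    def subset_comparisons(self, comparison_ids: Sequence[str]) -> "FoldChangeMatrix":
        missing = [c for c in comparison_ids if c not in self.values.columns]
        if missing:
            raise InputError(f"unknown comparison ids: {missing[:5]}")
        return FoldChangeMatrix(
            self.values.loc[:, list(comparison_ids)],
            self.study_ids.loc[list(comparison_ids)],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "FoldChangeMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise InputError(f"unknown gene ids: {missing[:5]}")
        return FoldChangeMatrix(self.values.loc[list(gene_ids)], self.study_ids)


@dataclass
class DesignTable:
    """Treatment/control sample groupings defining each comparison.

    Each row pairs the treatment sample ids against control sample ids
    within one study (series). Mirrors the curated-annotation table layout:
    Series, ID, Samples_A (treatment), Samples_B (control), with sample
    lists ';'-separated on disk.
    """

    rows: list[tuple[str, str, list[str], list[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for series_id, comparison_id, treat, ctrl in self.rows:
            if comparison_id in seen:
                raise FormatError(f"duplicate comparison id {comparison_id!r}")
            seen.add(comparison_id)
            if not treat or not ctrl:
                raise FormatError(
                    f"comparison {comparison_id!r} needs >=1 treatment and "
                    ">=1 control sample"
                )

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); membership is exact case-sensitive match."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restrict(self, universe: Iterable[str]) -> dict[str, frozenset[str]]:
        """Pathway membership intersected with a gene universe (may be empty)."""
        uni = frozenset(universe)
        return {name: members & uni for name, members in self.sets.items()}


@dataclass
class ImportanceScores:
    """Per-gene diversity (DIS), co-expression (CIS) and overall (OIS) scores.

    ``table`` has one row per gene with columns DIS, CIS, rank_DIS,
    rank_CIS, OIS. Ranks are ascending (1 = smallest score, N = largest)
    and form a permutation of 1..N; ties are resolved by ascending gene id.
    OIS(g) = sqrt((rank_CIS^2 + rank_DIS^2) / 2) / N.
    """

    table: pd.DataFrame

    REQUIRED = ("DIS", "CIS", "rank_DIS", "rank_CIS", "OIS")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"scores table missing columns {missing}")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate gene ids in scores table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_genes(self) -> int:
        return len(self.table)

    @property
    def ois(self) -> pd.Series:
        return self.table["OIS"]


@dataclass
class SentinelSelection:
    """An ordered gene panel with per-gene provenance.

    Provenance is one of ``data_driven`` (chosen by OIS ranking),
    ``coverage_replacement`` (swapped in during pathway refinement) or
    ``nominated`` (merged from an external nomination list).
    """

    genes: list[str]
    provenance: dict[str, str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("selection contains duplicate genes")
        unknown = set(self.provenance) - set(self.genes)
        if unknown:
            raise InputError(f"provenance for genes not in selection: {unknown}")
        for g in self.genes:
            self.provenance.setdefault(g, "data_driven")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    @property
    def data_driven_size(self) -> int:
        return sum(1 for g in self.genes if self.provenance[g] != "nominated")
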