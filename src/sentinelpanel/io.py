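"""Readers and writers for every on-disk representation the pipeline touches.

All tabular files are UTF-8, tab-separated, '.' decimal, unquoted. Lines
starting with '#' are treated as comments (the CLI writes provenance
headers this way). Gene sets use the MSigDB GMT dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .containers import (
    DesignTable,
    FoldChangeMatrix,
    GeneSetCollection,
    ImportanceScores,
    SentinelSelection,
)
from .errors import FormatError, ParseError, SampleLookupError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fold-change matrices and signal matrices
# ---------------------------------------------------------------------------

def read_fold_change_matrix(
    path: str | Path,
    study_map: Mapping[str, str] | None = None,
) -> FoldChangeMatrix:
    """Read a genes x comparisons log2 fold-change TSV.

    First row holds comparison ids, first column gene ids. ``study_map``
    assigns each comparison to a study; without it every comparison is its
    own study.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise FormatError(f"duplicate gene row label(s): {list(dups[:5])}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique()
        raise FormatError(f"duplicate comparison column label(s): {list(dups[:5])}")
    try:
        numeric = df.astype(float)
    except ValueError:
        numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ParseError(
            f"non-numeric or missing cell {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, comparison {df.columns[j]!r}",
            row=df.index[i],
            column=df.columns[j],
        )
    study_ids = None
    if study_map is not None:
        missing = [c for c in numeric.columns if c not in study_map]
        if missing:
            raise FormatError(f"study_map missing comparisons: {missing[:5]}")
        study_ids = pd.Series([study_map[c] for c in numeric.columns],
                              index=numeric.columns, dtype=object)
    return FoldChangeMatrix(numeric, study_ids)


def write_fold_change_matrix(
    fcm: FoldChangeMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fcm.values.to_csv(fh, sep="\t", float_format="%.12g", lineterminator="\n")


def read_study_map(path: str | Path) -> dict[str, str]:
    """Read a two-column comparison->study TSV (header: comparison, study)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("study map needs two columns: comparison, study")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_study_map(fcm: FoldChangeMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"comparison": fcm.comparison_ids, "study": fcm.study_ids.to_numpy()}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_signal_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 signal TSV (same dialect as fold changes)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise FormatError("duplicate gene ids in signal matrix")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in signal matrix")
    return df.astype(float)


# ---------------------------------------------------------------------------
# design tables
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ("Series", "ID", "Samples_A", "Samples_B")


def read_design_table(path: str | Path) -> DesignTable:
    """Read a design TSV: Series, ID, Samples_A, Samples_B.

    Samples_A are treatment sample ids, Samples_B controls; each is a
    ';'-separated list.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design table missing columns {missing}")
    rows = []
    for _, r in df.iterrows():
        treat = [s for s in str(r["Samples_A"]).split(";") if s]
        ctrl = [s for s in str(r["Samples_B"]).split(";") if s]
        rows.append((str(r["Series"]), str(r["ID"]), treat, ctrl))
    return DesignTable(rows)


def write_design_table(design: DesignTable, path: str | Path) -> None:
    recs = [
        {"Series": s, "ID": c, "Samples_A": ";".join(t), "Samples_B": ";".join(b)}
        for s, c, t, b in design.rows
    ]
    pd.DataFrame(recs, columns=list(_DESIGN_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def compute_fold_changes(signal: pd.DataFrame, design: DesignTable) -> FoldChangeMatrix:
    """Per-comparison log2 fold changes from a log2 signal matrix.

    For each design row the fold change of a gene is the arithmetic mean of
    its log2 treatment signals minus the mean of its log2 control signals
    (the standard limma-style contrast on the log scale). Study labels are
    the design's series ids.
    """
    cols = {}
    studies = []
    sample_index = set(signal.columns)
    for series_id, comparison_id, treat, ctrl in design.rows:
        for sid in [*treat, *ctrl]:
            if sid not in sample_index:
                raise SampleLookupError(
                    f"sample {sid!r} (comparison {comparison_id!r}) not in signal matrix"
                )
        cols[comparison_id] = (
            signal[treat].mean(axis=1) - signal[ctrl].mean(axis=1)
        )
        studies.append(series_id)
    values = pd.DataFrame(cols, index=signal.index)
    return FoldChangeMatrix(values, pd.Series(studies, index=values.columns))


def collapse_probes(
    signal: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Average probe-level rows mapping to the same gene (mean on log2 scale).

    Probes absent from the map are dropped. Convenience utility; the
    pipeline itself assumes gene-level input.
    """
    mapped = signal.loc[[p for p in signal.index if p in probe_to_gene]]
    genes = [probe_to_gene[p] for p in mapped.index]
    return mapped.groupby(pd.Index(genes, name=signal.index.name)).mean()


# ---------------------------------------------------------------------------
# gene sets and gene lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then one or more genes per line."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and >=1 gene"
                )
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}: duplicate pathway name {name!r} "
                                  f"at line {lineno}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise FormatError(f"{path}: pathway {name!r} has no genes")
            sets[name] = members
            descriptions[name] = desc
    if n_lines == 0:
        logger.warning("GMT file %s is empty", path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "na")
            genes = sorted(collection[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene id per line; '#' comments and blanks ignored.

    Only the first whitespace-delimited token of each line is used, so
    panel files with an extra provenance column read back cleanly.
    Duplicates are dropped (order-preserving) with a warning.
    """
    out: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            gene = line.split()[0]
            if gene in seen:
                logger.warning("duplicate gene %r in %s dropped", gene, path)
                continue
            seen.add(gene)
            out.append(gene)
    return out


def write_selection(
    selection: SentinelSelection, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a panel as gene<TAB>provenance lines (readable by read_gene_list)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for g in selection.genes:
            fh.write(f"{g}\t{selection.provenance[g]}\n")


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

def write_scores_table(
    scores: ImportanceScores,
    path: str | Path,
    selected: Iterable[str] = (),
    header_lines: Sequence[str] = (),
) -> None:
    """Write per-gene scores: gene, DIS, CIS, rank_DIS, rank_CIS, OIS, selected."""
    sel = set(selected)
    out = scores.table.copy()
    out["selected"] = [int(g in sel) for g in out.index]
    out.index.name = "gene"
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", float_format="%.12g", lineterminator="\n")


def read_scores_table(path: str | Path) -> ImportanceScores:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df = df.drop(columns=[c for c in ("selected",) if c in df.columns])
    return ImportanceScores(df)


# ---------------------------------------------------------------------------
# extrapolation model serialization (HDF5)
# ---------------------------------------------------------------------------

def save_extrapolation_model(model, path: str | Path) -> None:
    """Serialize an ExtrapolationModel to an HDF5 container."""
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("sentinel_genes",
                         data=np.array(model.sentinel_genes, dtype=object),
                         dtype=str_dt)
        f.create_dataset("target_genes",
                         data=np.array(model.target_genes, dtype=object),
                         dtype=str_dt)
        f.create_dataset("loadings", data=model.loadings)
        f.create_dataset("coefficients", data=model.coefficients)
        f.create_dataset("extrapolation_matrix", data=model.extrapolation_matrix)
        f.create_dataset("eigenvalues", data=model.eigenvalues)
        if model.sentinel_means is not None:
            f.create_dataset("sentinel_means", data=model.sentinel_means)
            f.create_dataset("target_means", data=model.target_means)
        f.attrs["K"] = model.K
        f.attrs["lambda"] = model.lam
        f.attrs["center"] = model.center


def load_extrapolation_model(path: str | Path):
    from .extrapolation import ExtrapolationModel  # local import; avoids cycle

    with h5py.File(path, "r") as f:
        sentinel_means = f["sentinel_means"][...] if "sentinel_means" in f else None
        target_means = f["target_means"][...] if "target_means" in f else None
        return ExtrapolationModel(
            sentinel_genes=[s.decode() if isinstance(s, bytes) else str(s)
                            for s in f["sentinel_genes"][...]],
            target_genes=[s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["target_genes"][...]],
            K=int(f.attrs["K"]),
            loadings=f["loadings"][...],
            coefficients=f["coefficients"][...],
            extrapolation_matrix=f["extrapolation_matrix"][...],
            eigenvalues=f["eigenvalues"][...],
            lam=float(f.attrs["lambda"]),
            center=str(f.attrs["center"]),
            sentinel_means=sentinel_means,
            target_means=target_means,
        )
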