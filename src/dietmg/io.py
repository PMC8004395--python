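"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain text: tables as TSV, gene counts as dense TSV or
MatrixMarket, the MSP catalog and annotation maps as two-column mappings,
distance matrices as square TSV with a shared header row/column, and trees
as newick.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from skbio import DistanceMatrix

from .msp_subspecies import MSPCatalog

__all__ = [
    "write_table",
    "read_table",
    "write_gene_counts",
    "read_gene_counts",
    "write_catalog",
    "read_catalog",
    "write_annotation",
    "read_annotation",
    "write_distance",
    "read_distance",
]


def write_table(df: pd.DataFrame, path, index=True):
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0):
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gene_counts(counts: pd.DataFrame, path, fmt: str = "tsv"):
    """Write a genes x samples matrix as dense TSV or MatrixMarket.

    The MatrixMarket form writes ``<stem>.mtx`` plus ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` id lists.
    """
    path = Path(path)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        path.with_suffix(".samples.txt").write_text(
            "\n".join(map(str, counts.columns)) + "\n"
        )
    else:
        raise ValueError("fmt must be 'tsv' or 'mtx'")


def read_gene_counts(path, fmt: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    if fmt == "mtx":
        mat = scipy.io.mmread(str(path)).toarray()
        genes = path.with_suffix(".genes.txt").read_text().splitlines()
        samples = path.with_suffix(".samples.txt").read_text().splitlines()
        return pd.DataFrame(mat, index=genes, columns=samples)
    raise ValueError("fmt must be 'tsv' or 'mtx'")


def write_catalog(catalog: MSPCatalog, path):
    """Two-column mapping: gene id -> ``msp:role`` (role = core/accessory)."""
    with open(path, "w") as fh:
        fh.write("gene\tmsp_role\n")
        for msp, sets in catalog.members.items():
            for g in sets["core"]:
                fh.write(f"{g}\t{msp}:core\n")
            for g in sets["accessory"]:
                fh.write(f"{g}\t{msp}:accessory\n")


def read_catalog(path) -> MSPCatalog:
    df = pd.read_csv(path, sep="\t")
    members = {}
    for _, row in df.iterrows():
        msp, role = row["msp_role"].rsplit(":", 1)
        members.setdefault(msp, {"core": [], "accessory": []})[role].append(row["gene"])
    return MSPCatalog(members=members)


def write_annotation(mapping: pd.Series, path, value_name: str = "family"):
    mapping.rename(value_name).rename_axis("gene").to_csv(path, sep="\t")


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_distance(dm: DistanceMatrix, path):
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
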