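"""Readers and writers for the pipeline's table and tree formats.

Count tables move as TSV (samples in rows by default, orientation
auto-detected with an explicit override) or BIOM v2.1 HDF5; trees as Newick
via scikit-bio; designs, function matrices, distance matrices and edge lists
as TSV.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse
from skbio import TreeNode

from ._util import as_count_frame

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_biom",
    "write_biom",
    "read_tree",
    "write_tree",
    "read_table_tsv",
    "write_table_tsv",
]


def read_table_tsv(path) -> pd.DataFrame:
    """Generic labelled TSV matrix (first column is the row index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def _looks_like_taxa(labels) -> bool:
    labels = [str(x) for x in labels]
    return sum(x.upper().startswith(("ASV", "OTU")) for x in labels) > len(labels) / 2


def read_count_table(path, fmt: str = "auto", orientation: str = "auto") -> pd.DataFrame:
    """Read a samples x taxa count table from TSV or BIOM.

    ``orientation`` may be ``samples`` (rows are samples), ``taxa`` (rows
    are taxa; the table is transposed) or ``auto``, which transposes when
    the row labels look like ASV/OTU identifiers and the columns do not.
    Negative or non-numeric cells raise with the offending coordinates.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "biom" if path.suffix == ".biom" else "tsv"
    if fmt == "biom":
        df = read_biom(path)
    elif fmt == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        for j, col in enumerate(raw.columns):
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric cell {raw[col].iloc[i]!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                )
            raw[col] = converted
        if raw.isna().any().any():
            i, j = np.argwhere(raw.isna().to_numpy())[0]
            raise ValueError(f"missing cell at row {raw.index[i]!r}, column {raw.columns[j]!r}")
        df = raw
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "taxa":
        df = df.T
    elif orientation == "auto":
        if _looks_like_taxa(df.index) and not _looks_like_taxa(df.columns):
            df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return as_count_frame(df)


def write_count_table(df: pd.DataFrame, path, fmt: str = "auto") -> None:
    """Write a samples x taxa count table as TSV (samples in rows) or BIOM."""
    path = Path(path)
    if fmt == "auto":
        fmt = "biom" if path.suffix == ".biom" else "tsv"
    if fmt == "tsv":
        write_table_tsv(df, path)
    elif fmt == "biom":
        write_biom(df, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_biom(path) -> pd.DataFrame:
    """Read a BIOM v2.1 HDF5 table, returned as samples x taxa."""
    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    dense = pd.DataFrame(mat.toarray(), index=obs_ids, columns=sample_ids)
    return dense.T  # observations (taxa) are BIOM rows; we use samples x taxa


def write_biom(df: pd.DataFrame, path) -> None:
    """Write a samples x taxa table as minimal BIOM v2.1 HDF5."""
    df = as_count_frame(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    obs = sparse.csr_matrix(df.T.to_numpy())  # BIOM stores observations x samples
    samp = sparse.csr_matrix(df.to_numpy())
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-url"] = "http://biom-format.org"
        fh.attrs["format-version"] = (2, 1)
        fh.attrs["generated-by"] = "soilcomm"
        fh.attrs["creation-date"] = datetime.datetime.now().isoformat()
        fh.attrs["shape"] = (df.shape[1], df.shape[0])
        fh.attrs["nnz"] = int(obs.nnz)
        for name, ids, mat in (
            ("observation", df.columns, obs),
            ("sample", df.index, samp),
        ):
            grp = fh.create_group(name)
            grp.create_dataset(
                "ids", data=np.array([str(x).encode() for x in ids])
            )
            m = grp.create_group("matrix")
            m.create_dataset("data", data=mat.data.astype(float))
            m.create_dataset("indices", data=mat.indices.astype(np.int64))
            m.create_dataset("indptr", data=mat.indptr.astype(np.int64))
            grp.create_group("metadata")
            grp.create_group("group-metadata")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path), format="newick")
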