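"""Plain-text and PNG serialization for the pipeline's containers.

Expression sections and metacell matrices round-trip as MatrixMarket (MTX)
matrices with TSV sidecars; images round-trip as RGBA PNG at 300 DPI with
whatever alpha the array carries.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image
from scipy import sparse
from scipy.io import mmread, mmwrite

from .metacells import MetacellMatrix
from .synthdata import ExpressionSection

__all__ = [
    "write_section",
    "read_section",
    "write_metacells",
    "read_metacells",
    "write_image",
    "read_image",
]

_CELL_COLUMNS = ["cell_id", "celltype", "x", "y", "condition"]


def write_section(section: ExpressionSection, directory: str) -> None:
    """Write a section as matrix.mtx + genes.tsv + cells.tsv."""
    os.makedirs(directory, exist_ok=True)
    mmwrite(os.path.join(directory, "matrix.mtx"), sparse.csr_matrix(section.values))
    genes = pd.DataFrame({"gene": list(section.genes)})
    if section.raw_gene_names is not None:
        genes["raw_name"] = list(section.raw_gene_names)
    genes.to_csv(os.path.join(directory, "genes.tsv"), sep="\t", index=False)
    cells = section.cells.copy()
    cells["condition"] = section.condition
    cells[_CELL_COLUMNS].to_csv(os.path.join(directory, "cells.tsv"), sep="\t", index=False)


def read_section(directory: str) -> ExpressionSection:
    values = np.asarray(mmread(os.path.join(directory, "matrix.mtx")).todense())
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(directory, "cells.tsv"), sep="\t")
    conditions = cells["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(f"section must carry a single condition, found {list(conditions)}")
    raw = tuple(genes["raw_name"]) if "raw_name" in genes.columns else None
    return ExpressionSection(
        values=values,
        genes=tuple(genes["gene"]),
        cells=cells[["cell_id", "celltype", "x", "y"]].reset_index(drop=True),
        condition=str(conditions[0]),
        raw_gene_names=raw,
    )


def write_metacells(m: MetacellMatrix, directory: str) -> None:
    """Write a metacell matrix as matrix.mtx + genes.tsv + metacells.tsv
    (members serialized as comma-joined cell ids)."""
    os.makedirs(directory, exist_ok=True)
    mmwrite(os.path.join(directory, "matrix.mtx"), sparse.csr_matrix(m.values))
    pd.DataFrame({"gene": list(m.genes)}).to_csv(
        os.path.join(directory, "genes.tsv"), sep="\t", index=False
    )
    meta = pd.DataFrame(
        {
            "metacell": [f"mc{i:05d}" for i in range(m.n_metacells)],
            "group": m.group,
            "source_section": m.source_section,
            "members": [",".join(mem) for mem in m.members],
        }
    )
    meta.to_csv(os.path.join(directory, "metacells.tsv"), sep="\t", index=False)


def read_metacells(directory: str) -> MetacellMatrix:
    values = np.asarray(mmread(os.path.join(directory, "matrix.mtx")).todense())
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t")
    meta = pd.read_csv(os.path.join(directory, "metacells.tsv"), sep="\t")
    sections = meta["source_section"].unique()
    if len(sections) != 1:
        raise ValueError("metacell matrix must come from a single section")
    return MetacellMatrix(
        values=values,
        genes=tuple(genes["gene"]),
        members=[str(s).split(",") for s in meta["members"]],
        group=list(meta["group"]),
        source_section=str(sections[0]),
    )


def write_image(pixels: np.ndarray, path: str, dpi: int = 300) -> None:
    """Write an RGBA uint8 array as PNG (300 DPI metadata by default)."""
    if pixels.ndim != 3 or pixels.shape[2] != 4 or pixels.dtype != np.uint8:
        raise ValueError("expected an RGBA uint8 array")
    Image.fromarray(pixels, mode="RGBA").save(path, dpi=(dpi, dpi))


def read_image(path: str) -> np.ndarray:
    """Read a PNG into an RGBA uint8 array (origin top-left, row-major)."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGBA"))
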