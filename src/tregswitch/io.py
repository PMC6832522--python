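"""File-format round-trips: 8-bit masks (TIFF/PNG), MatrixMarket count
matrices with sidecar gene/label files, and slide manifests."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .errors import ParameterError
from .fractal_spatial import BinaryImage
from .synthetic_data import CountMatrix


def write_mask(img: BinaryImage, path) -> None:
    """Write a mask as single-channel 8-bit (0 background, 255 foreground)."""
    path = Path(path)
    data = img.pixels.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_mask(path, threshold: float = 0) -> BinaryImage:
    """Read a single-channel image; pixels above ``threshold`` are foreground."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3:  # collapse an (H, W, 1) or RGB read to one channel
        data = data[..., 0]
    return BinaryImage(pixels=data > threshold, provenance=str(path))


def write_count_matrix(matrix: CountMatrix, prefix) -> dict:
    """Write counts as MTX plus gene and cell-label sidecar files.

    Returns the paths written: ``{"matrix": ..., "genes": ..., "cells": ...}``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx_path = prefix.with_suffix(".mtx")
    genes_path = prefix.parent / (prefix.name + "_genes.txt")
    cells_path = prefix.parent / (prefix.name + "_cells.tsv")
    spio.mmwrite(mtx_path, sparse.coo_matrix(matrix.counts))
    genes_path.write_text("\n".join(matrix.gene_ids) + "\n")
    pd.DataFrame({"cell": matrix.cell_ids, "group": matrix.groups}).to_csv(
        cells_path, sep="\t", index=False
    )
    return {"matrix": str(mtx_path), "genes": str(genes_path), "cells": str(cells_path)}


def read_count_matrix(mtx_path, genes_path, cells_path) -> CountMatrix:
    raw = spio.mmread(mtx_path)
    counts = np.asarray(raw.todense()) if sparse.issparse(raw) else np.asarray(raw)
    gene_ids = Path(genes_path).read_text().split()
    labels = pd.read_csv(cells_path, sep="\t")
    return CountMatrix(
        counts=np.asarray(counts, dtype=np.int64),
        gene_ids=gene_ids,
        cell_ids=labels["cell"].astype(str).tolist(),
        groups=labels["group"].to_numpy(),
    )


def read_manifest(path) -> pd.DataFrame:
    """Slide manifest CSV with columns ``path`` and ``group``."""
    frame = pd.read_csv(path)
    missing = {"path", "group"} - set(frame.columns)
    if missing:
        raise ParameterError(f"manifest missing columns: {sorted(missing)}")
    return frame
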