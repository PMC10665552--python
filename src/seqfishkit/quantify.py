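"""Cell-level quantification: transcript→cell assignment, duplicate-cell
removal in FOV overlaps, optional neighbour smoothing, and the sparse
cell × gene matrix.

A decoded transcript belongs to the segmented cell whose mask label
contains its rounded pixel; background (label 0) transcripts are kept in
an explicit unassigned list, so counts are conserved.  Cells imaged twice
in the overlap between adjacent FOVs are deduplicated by the rule that
the duplicate with fewer detected transcripts is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.spatial import cKDTree

from .decoder import DecodedTranscript

__all__ = [
    "CellRecord",
    "CellGeneMatrix",
    "assign_to_cells",
    "build_matrix",
    "dedup_fov_overlap",
    "neighbor_smooth",
    "write_matrix_market",
    "read_matrix_market",
]


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    fov: int
    label: int
    x_global: float
    y_global: float
    n_transcripts: int


@dataclass
class CellGeneMatrix:
    """Sparse cell × gene counts with per-cell metadata.

    ``cells`` carries cell_id, fov, label, x_global, y_global,
    n_transcripts; row i of ``counts`` belongs to ``cells.iloc[i]``.
    """

    cells: pd.DataFrame
    genes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape does not match cells × genes")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_ids")

    def subset_cells(self, cell_ids: Sequence[str]) -> "CellGeneMatrix":
        keep = self.cells["cell_id"].isin(set(cell_ids)).to_numpy()
        return CellGeneMatrix(
            cells=self.cells.loc[keep].reset_index(drop=True),
            genes=list(self.genes),
            counts=self.counts[keep],
        )


def assign_to_cells(
    transcripts: Sequence[DecodedTranscript] | pd.DataFrame,
    mask: np.ndarray,
    fov: int,
    fov_origin_global: tuple[float, float] = (0.0, 0.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign one FOV's transcripts to mask labels.

    A transcript at local (x, y) lands in ``mask[round(y), round(x)]``;
    label 0 is background and such transcripts are returned unassigned,
    as are transcripts whose rounded pixel falls outside the mask (warned).
    Counts conserve: len(assigned) + len(unassigned) == len(input).

    Returns (assigned, unassigned) DataFrames; ``assigned`` has columns
    gene_id, x, y, label, cell_id plus global coordinates.
    """
    if isinstance(transcripts, pd.DataFrame):
        df = transcripts.copy()
    else:
        from .decoder import transcripts_to_frame

        df = transcripts_to_frame(transcripts)
    ox, oy = fov_origin_global
    h, w = mask.shape
    labels = np.zeros(len(df), dtype=np.int64)
    outside = 0
    xs = df["x"].to_numpy()
    ys = df["y"].to_numpy()
    for i, (x, y) in enumerate(zip(xs, ys)):
        px, py = int(round(x)), int(round(y))
        if 0 <= px < w and 0 <= py < h:
            labels[i] = mask[py, px]
        else:
            outside += 1
            labels[i] = 0
    if outside:
        warnings.warn(f"{outside} transcripts outside the mask; treated as unassigned")
    df = df.assign(
        label=labels,
        fov=fov,
        x_global=xs + ox,
        y_global=ys + oy,
    )
    assigned = df[df["label"] > 0].copy()
    assigned["cell_id"] = [f"fov{fov}_cell{l}" for l in assigned["label"]]
    unassigned = df[df["label"] == 0].copy()
    return assigned.reset_index(drop=True), unassigned.reset_index(drop=True)


def build_matrix(
    assigned: pd.DataFrame,
    genes: Sequence[str],
    cell_meta: Optional[pd.DataFrame] = None,
) -> CellGeneMatrix:
    """Aggregate assigned transcripts into a sparse cell × gene count matrix.

    ``cell_meta`` (cell_id, fov, label, x_global, y_global), e.g. from
    segmentation centroids, may list cells with zero transcripts; absent
    that, cells and their centroids come from the assigned transcripts.
    """
    genes = list(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    if cell_meta is None:
        cell_meta = (
            assigned.groupby("cell_id", sort=True)
            .agg(
                fov=("fov", "first"),
                label=("label", "first"),
                x_global=("x_global", "mean"),
                y_global=("y_global", "mean"),
            )
            .reset_index()
        )
    cells = cell_meta.copy().reset_index(drop=True)
    cell_pos = {c: i for i, c in enumerate(cells["cell_id"])}

    rows, cols = [], []
    for rec in assigned.itertuples(index=False):
        if rec.cell_id in cell_pos and rec.gene_id in gene_pos:
            rows.append(cell_pos[rec.cell_id])
            cols.append(gene_pos[rec.gene_id])
    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(cells), len(genes)),
    ).tocsr()
    cells["n_transcripts"] = np.asarray(counts.sum(axis=1)).ravel()
    return CellGeneMatrix(cells=cells, genes=genes, counts=counts)


def dedup_fov_overlap(
    cells: pd.DataFrame, match_radius_px: float
) -> list[str]:
    """Remove duplicate observations of cells in FOV-overlap regions.

    Cells from *different* FOVs whose global centroids lie within
    ``match_radius_px`` are duplicate observations of one physical cell;
    of each pair, the member with fewer detected transcripts is removed
    (tie: the one from the higher-numbered FOV, then the larger cell_id).
    Pairs are resolved in ascending (distance, cell_id, cell_id) order, so
    the retained set is independent of input row order.

    Returns retained cell_ids.
    """
    df = cells.reset_index(drop=True)
    if len(df) == 0:
        return []
    xy = df[["x_global", "y_global"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = []
    for i, j in tree.query_pairs(match_radius_px, output_type="set"):
        if df.loc[i, "fov"] != df.loc[j, "fov"]:
            d = float(np.hypot(*(xy[i] - xy[j])))
            a, b = sorted([df.loc[i, "cell_id"], df.loc[j, "cell_id"]])
            pairs.append((d, a, b))
    pairs.sort()

    n_tx = dict(zip(df["cell_id"], df["n_transcripts"]))
    fov = dict(zip(df["cell_id"], df["fov"]))
    removed: set[str] = set()
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        if n_tx[a] < n_tx[b]:
            removed.add(a)
        elif n_tx[b] < n_tx[a]:
            removed.add(b)
        elif fov[a] != fov[b]:
            removed.add(a if fov[a] > fov[b] else b)
        else:
            removed.add(max(a, b))
    return [c for c in df["cell_id"] if c not in removed]


def neighbor_smooth(
    m: CellGeneMatrix, k: int, alpha: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """Blend each cell's profile with its k spatially nearest cells.

    x_i' = (1 − alpha)·x_i + alpha·mean(k nearest neighbours' profiles);
    alpha = 0 is the identity.  Off by default in the pipeline: the
    weighting is an optional enhancement, not part of the core counts.

    Returns (cells, dense real-valued matrix).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    n = len(m.cells)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    dense = m.counts.toarray().astype(float)
    if alpha == 0.0:
        return m.cells.copy(), dense
    xy = m.cells[["x_global", "y_global"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k + 1)  # includes self at position 0
    neigh_mean = dense[idx[:, 1:]].mean(axis=1)
    return m.cells.copy(), (1.0 - alpha) * dense + alpha * neigh_mean


def write_matrix_market(m: CellGeneMatrix, outdir) -> None:
    """matrix.mtx + cells.tsv / genes.tsv sidecars."""
    import os

    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, "matrix.mtx"), m.counts)
    m.cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)
    pd.Series(m.genes, name="gene_id").to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False
    )


def read_matrix_market(indir) -> CellGeneMatrix:
    import os

    counts = sp.csr_matrix(mmread(os.path.join(indir, "matrix.mtx")))
    cells = pd.read_csv(os.path.join(indir, "cells.tsv"), sep="\t")
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")["gene_id"].tolist()
    return CellGeneMatrix(cells=cells, genes=genes, counts=counts)
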