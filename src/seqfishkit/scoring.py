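"""Cell-type expression scoring for disease-associated gene sets.

Given a labelled cell × gene expression matrix, the score of gene g in
cell type t is the product of two quantities computed per (type, gene):

    F[t, g] — fraction of type-t cells with non-zero expression of g,
    M[t, g] — mean expression of g over all type-t cells,
    S = F ⊙ M  (elementwise).

Genes are pre-filtered to those expressed in at least 20% of the cells of
at least one type (inclusive).  Gene-list (disease) scores are the mean of
S over the list's genes, per type.  Marker significance is a two-sided
Wilcoxon rank-sum test of each type against all other cells, with
Benjamini–Hochberg correction across every (type, gene) test in the batch.

Expression values may be raw or normalised counts; the scoring is defined
for any non-negative matrix, and which transform the caller applied is
recorded by the caller, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScoreMatrix",
    "filter_genes",
    "expression_score",
    "aggregate_list",
    "marker_test",
    "read_gene_lists",
]


@dataclass
class ScoreMatrix:
    """Cell-type × gene score S with its factors F (fraction) and M (mean)."""

    S: pd.DataFrame
    F: pd.DataFrame
    M: pd.DataFrame


def _as_frame(matrix, genes=None, cell_index=None) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix.toarray() if hasattr(matrix, "toarray") else matrix, dtype=float)
    return pd.DataFrame(arr, columns=genes, index=cell_index)


def _check_labels(df: pd.DataFrame, labels: Sequence) -> pd.Series:
    labels = pd.Series(list(labels), index=df.index, name="cell_type")
    counts = labels.value_counts()
    if (counts < 1).any():
        raise ValueError("every used label needs at least one cell")
    return labels


def filter_genes(
    matrix, labels: Sequence, min_frac: float = 0.20, genes=None
) -> list:
    """Genes expressed (> 0) in ≥ ``min_frac`` of the cells of ≥ 1 type.

    The threshold is inclusive: a gene hitting exactly ``min_frac`` in one
    type is retained.
    """
    df = _as_frame(matrix, genes)
    labels = _check_labels(df, labels)
    frac = (df > 0).groupby(labels, observed=True).mean()
    keep = (frac >= min_frac).any(axis=0)
    return [g for g in df.columns if keep[g]]


def expression_score(matrix, labels: Sequence, genes=None) -> ScoreMatrix:
    """Compute F (fraction expressing), M (mean expression) and S = F ⊙ M.

    Both factors are cell-type × gene, so the product is elementwise; a
    true matrix product is dimensionally impossible here.
    """
    df = _as_frame(matrix, genes)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    labels = _check_labels(df, labels)
    grouped = df.groupby(labels, observed=True)
    F = (df > 0).groupby(labels, observed=True).mean()
    M = grouped.mean()
    return ScoreMatrix(S=F * M, F=F, M=M)


def aggregate_list(
    s: ScoreMatrix, gene_lists: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Mean score of each gene list per cell type.

    Genes absent from the score matrix are excluded from the mean and
    reported in the second return value; a list with an empty intersection
    raises.
    """
    agg = {}
    missing: dict[str, list[str]] = {}
    for name, gl in gene_lists.items():
        present = [g for g in dict.fromkeys(gl) if g in s.S.columns]
        absent = [g for g in dict.fromkeys(gl) if g not in s.S.columns]
        if not present:
            raise ValueError(f"gene list {name!r} has no genes in the score matrix")
        agg[name] = s.S[present].mean(axis=1)
        if absent:
            missing[name] = absent
    return pd.DataFrame(agg), missing


def marker_test(matrix, labels: Sequence, genes=None) -> pd.DataFrame:
    """Per-(type, gene) two-sided rank-sum test of type vs all other cells.

    Returns a tidy frame (cell_type, gene, statistic, p, p_adj) with
    Benjamini–Hochberg adjustment across all tests performed in this call
    — that whole batch is the multiple-testing family.  Completely tied
    samples (no separation possible) get p = 1.
    """
    df = _as_frame(matrix, genes)
    labels = _check_labels(df, labels)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    rows = []
    for t in types:
        in_t = (labels == t).to_numpy()
        for g in df.columns:
            x = df.loc[in_t, g].to_numpy()
            y = df.loc[~in_t, g].to_numpy()
            if np.ptp(np.concatenate([x, y])) == 0:
                stat, p = float(len(x) * len(y)) / 2.0, 1.0
            else:
                stat, p = mannwhitneyu(x, y, alternative="two-sided")
            rows.append((t, g, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["cell_type", "gene", "statistic", "p"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def read_gene_lists(path) -> dict[str, list[str]]:
    """Two-column TSV (disease, gene) → disease → gene list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["disease", "gene"], comment="#")
    return {d: sub["gene"].tolist() for d, sub in df.groupby("disease", sort=True)}
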