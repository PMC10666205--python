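"""Map genes to pathways and order each pathway's genes by mutual rank
correlation.

Within a pathway the g x g Spearman matrix is collapsed to one aggregate
coefficient per gene (the geometric mean of that gene's absolute
correlations with every pathway member, self included), and the genes are
re-indexed in non-increasing aggregate order. Adjacent input positions then
carry similar genes, which is what lets a small 1-D convolution pick up
local structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, PathwayCollection, ValidationError

#: smallest absolute correlation entering the log-domain product; keeps one
#: exact zero from annihilating every other gene's contribution
RHO_FLOOR = 1e-12

#: minimum spatial length a branch input needs to survive two halving pools
MIN_SPATIAL_LENGTH = 4


@dataclass
class OrderedPathway:
    """A pathway matched against an expression matrix, genes in aggregate-
    correlation order, optionally right-padded with silent columns."""

    name: str
    genes: list[str]              # matched gene symbols, in correlation order
    gene_order: np.ndarray        # permutation applied to the matched columns
    row_scores: np.ndarray        # aggregate coefficients, non-increasing
    column_indices: np.ndarray    # ordered columns' indices into the expression matrix
    n_padded: int = 0             # zero columns appended on the right

    @property
    def width(self) -> int:
        return len(self.genes) + self.n_padded


@dataclass
class PathwayTensorSet:
    """Per-pathway expression blocks sharing one sample axis (CNN inputs)."""

    pathways: list[OrderedPathway]
    blocks: list[np.ndarray]
    sample_ids: list[str]
    dropped_pathways: list[tuple[str, str]] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [pw.name for pw in self.pathways]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __len__(self) -> int:
        return len(self.pathways)


def spearman_matrix(block: np.ndarray) -> np.ndarray:
    """Spearman rank-correlation matrix of a samples x g block.

    Ties get average ranks. A zero-variance column, whose rank correlation
    is undefined, correlates 0 with every other column and 1 with itself.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2:
        raise ValueError("block must be 2-D (samples x genes)")
    n, g = block.shape
    if n < 2:
        raise ValidationError("Spearman correlation needs at least 2 samples")
    if g == 1:
        return np.ones((1, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(block, axis=0).statistic
    if g == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.atleast_2d(np.asarray(rho, dtype=np.float64))
    rho[~np.isfinite(rho)] = 0.0  # zero-variance columns
    np.fill_diagonal(rho, 1.0)
    return rho


def row_aggregate(corr: np.ndarray, aggregate: str = "geometric") -> np.ndarray:
    """Collapse a correlation matrix row-wise to one coefficient per gene.

    ``geometric`` (default): geometric mean of the row's absolute
    correlations, computed in log domain with each |rho| floored at
    ``RHO_FLOOR``. ``arithmetic``: plain mean of absolute correlations.
    Both are monotone summaries of how strongly a gene co-varies with the
    rest of its pathway.
    """
    corr = np.asarray(corr, dtype=np.float64)
    g = corr.shape[0]
    if corr.shape != (g, g):
        raise ValueError("correlation matrix must be square")
    absr = np.abs(corr)
    if aggregate == "geometric":
        return np.exp(np.log(np.maximum(absr, RHO_FLOOR)).mean(axis=1))
    if aggregate == "arithmetic":
        return absr.mean(axis=1)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def order_genes(
    block: np.ndarray, name: str = "", aggregate: str = "geometric"
) -> OrderedPathway:
    """Compute the correlation-based gene permutation for one block.

    Scores are sorted in non-increasing order; ties keep the original
    column order (stable sort), so duplicated genes stay adjacent.
    """
    block = np.asarray(block, dtype=np.float64)
    scores = row_aggregate(spearman_matrix(block), aggregate=aggregate)
    order = np.argsort(-scores, kind="stable")
    return OrderedPathway(
        name=name,
        genes=[str(j) for j in order],
        gene_order=order,
        row_scores=scores[order],
        column_indices=order.copy(),
    )


def match_pathway_genes(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    min_genes: int = 5,
) -> PathwayTensorSet:
    """Select, per pathway, the expression columns for its member genes.

    Pathways matching fewer than ``min_genes`` expression columns are
    dropped with reason ``"too_few_genes"``. Blocks are unordered (gene
    list order); a gene shared by two pathways appears in both blocks.
    """
    gene_idx = expr.gene_index()
    kept: list[OrderedPathway] = []
    blocks: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for pw in pathways:
        cols = [gene_idx[g] for g in pw.genes if g in gene_idx]
        if len(cols) < min_genes:
            dropped.append((pw.name, "too_few_genes"))
            continue
        cols_arr = np.array(cols, dtype=np.int64)
        kept.append(
            OrderedPathway(
                name=pw.name,
                genes=[expr.gene_ids[c] for c in cols],
                gene_order=np.arange(len(cols)),
                row_scores=np.full(len(cols), np.nan),
                column_indices=cols_arr,
            )
        )
        blocks.append(expr.values[:, cols_arr])
    if not kept:
        raise ValidationError(
            "no pathway matched at least "
            f"{min_genes} genes of the expression matrix"
        )
    return PathwayTensorSet(kept, blocks, list(expr.sample_ids), dropped)


def build_pathway_tensors(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    min_genes: int = 5,
    aggregate: str = "geometric",
    min_length: int = MIN_SPATIAL_LENGTH,
) -> PathwayTensorSet:
    """Match, order and pad: the full preprocessing pipeline in front of the
    CNN ensemble.

    Blocks narrower than ``min_length`` after matching are right-padded with
    zero columns (recorded in ``n_padded``) rather than dropped.
    """
    tset = match_pathway_genes(expr, pathways, min_genes=min_genes)
    ordered_pws: list[OrderedPathway] = []
    ordered_blocks: list[np.ndarray] = []
    for pw, block in zip(tset.pathways, tset.blocks):
        op = order_genes(block, name=pw.name, aggregate=aggregate)
        order = op.gene_order
        new_block = block[:, order]
        n_pad = max(0, min_length - new_block.shape[1])
        if n_pad:
            new_block = np.hstack([new_block, np.zeros((new_block.shape[0], n_pad))])
        ordered_pws.append(
            OrderedPathway(
                name=pw.name,
                genes=[pw.genes[j] for j in order],
                gene_order=order,
                row_scores=op.row_scores,
                column_indices=pw.column_indices[order],
                n_padded=n_pad,
            )
        )
        ordered_blocks.append(new_block)
    return PathwayTensorSet(
        ordered_pws, ordered_blocks, tset.sample_ids, tset.dropped_pathways
    )


def blocks_for_new_data(
    tset_pathways: list[OrderedPathway], values: np.ndarray
) -> list[np.ndarray]:
    """Re-create ordered (and padded) blocks for new samples using the gene
    order learned at fit time. ``values`` must have the fit-time gene axis."""
    blocks = []
    for pw in tset_pathways:
        block = values[:, pw.column_indices]
        if pw.n_padded:
            block = np.hstack([block, np.zeros((block.shape[0], pw.n_padded))])
        blocks.append(block)
    return blocks


def overlap_summary(pathways: PathwayCollection) -> pd.DataFrame:
    """Pairwise shared-gene counts: k(k-1)/2 rows of
    (pathway_a, pathway_b, shared_genes)."""
    names = pathways.names
    if len(names) < 2:
        raise ValidationError("overlap summary needs at least 2 pathways")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append((a, b, len(pathways.overlap(a, b))))
    return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "shared_genes"])
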