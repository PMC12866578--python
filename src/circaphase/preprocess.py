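"""Expression-matrix normalization and cycling-gene selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cosinor import cosinor_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneRanking",
    "znormalize",
    "select_seed_genes",
    "rank_genes_by_rhythmicity",
]


class SeedGeneError(KeyError):
    """Raised when a seed-gene list shares no identifiers with the matrix."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional true collection times.

    ``data`` carries gene ids on the index and sample ids on the columns;
    ``true_times`` (hours) is only available for timed or synthetic data and
    is used for evaluation, never for phase inference.
    """

    data: pd.DataFrame
    true_times: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.true_times is not None:
            self.true_times = np.asarray(self.true_times, dtype=float)
            if len(self.true_times) != self.data.shape[1]:
                raise ValueError("true_times length != number of samples")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[gene_ids], self.true_times)


@dataclass
class GeneRanking:
    gene_ids: list[str]
    p_values: np.ndarray
    selected: np.ndarray  # boolean mask, aligned with gene_ids

    @property
    def selected_ids(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]


def znormalize(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Z-score each gene row to mean 0 and (sample) standard deviation 1.

    Constant rows carry no ordering information and cannot be scaled; they
    are dropped with a logged warning rather than aborting the run.
    """
    values = matrix.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("znormalize: dropped %d constant gene rows", n_dropped)
    values = values[keep]
    sd = sd[keep][:, None]
    mean = values.mean(axis=1, keepdims=True)
    out = pd.DataFrame(
        (values - mean) / sd,
        index=matrix.data.index[keep],
        columns=matrix.data.columns,
    )
    return ExpressionMatrix(out, matrix.true_times)


def select_seed_genes(matrix: ExpressionMatrix, seed_list) -> ExpressionMatrix:
    """Restrict the matrix to a precomputed list of likely-cycling genes.

    Identifiers are matched case-sensitively after whitespace stripping;
    matrix row order is preserved.
    """
    seeds = {str(s).strip() for s in seed_list if str(s).strip()}
    if not seeds:
        raise SeedGeneError("seed list is empty")
    mask = [str(g).strip() in seeds for g in matrix.data.index]
    n_hit = sum(mask)
    if n_hit == 0:
        raise SeedGeneError(
            f"no overlap between {len(seeds)} seed ids "
            f"(e.g. {sorted(seeds)[:3]}) and {matrix.n_genes} matrix gene ids "
            f"(e.g. {matrix.gene_ids[:3]})"
        )
    logger.info(
        "select_seed_genes: %d of %d seed ids found in matrix", n_hit, len(seeds)
    )
    return ExpressionMatrix(matrix.data.loc[mask], matrix.true_times)


def rank_genes_by_rhythmicity(
    matrix: ExpressionMatrix,
    pseudo_times: np.ndarray,
    top_k: int = 1000,
    period: float = 24.0,
) -> GeneRanking:
    """Rank genes by the zero-amplitude cosinor F-test at the given times.

    ``pseudo_times`` are hours per sample — true collection times when known,
    otherwise pre-sort angles converted to hours.  The ``top_k`` smallest
    p-values are marked selected, ties broken by input gene order.
    """
    pseudo_times = np.asarray(pseudo_times, dtype=float)
    if len(pseudo_times) != matrix.n_samples:
        raise ValueError("pseudo_times length != number of samples")
    p = cosinor_pvalues(matrix.values, pseudo_times, period=period)
    if top_k >= matrix.n_genes:
        if top_k > matrix.n_genes:
            logger.warning(
                "rank_genes_by_rhythmicity: top_k=%d > %d genes; selecting all",
                top_k,
                matrix.n_genes,
            )
        selected = np.ones(matrix.n_genes, dtype=bool)
    else:
        order = np.argsort(p, kind="stable")
        selected = np.zeros(matrix.n_genes, dtype=bool)
        selected[order[:top_k]] = True
    return GeneRanking(matrix.gene_ids, p, selected)
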