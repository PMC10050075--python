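"""Phenotype preprocessing: library-size scaling, gene filtering,
covariate residualization with PC-count selection, and the rank-based
inverse-normal transform.

The pipeline order is fixed: raw counts -> library-size normalization
-> residualization on covariates (sex, technical PCs) -> rank-normal
transform. Domain calling and all association tests run on the
rank-normalised matrix.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .containers import QuantificationMatrix

logger = logging.getLogger(__name__)


def library_size_normalize(counts: QuantificationMatrix) -> QuantificationMatrix:
    """Scale each sample column to the mean library size.

    After scaling, every column sums to the mean of the original column
    totals, removing per-sample sequencing-depth differences.
    """
    v = counts.values
    if v.size and v.min() < 0:
        raise ValueError("library-size normalization requires non-negative counts")
    totals = v.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {[counts.samples[i] for i in zero]}")
    return counts.with_values(v * (totals.mean() / totals))


def filter_expressed_genes(
    expr: QuantificationMatrix, max_null_fraction: float = 0.10
) -> QuantificationMatrix:
    """Drop genes whose fraction of zero quantifications exceeds the cap.

    A gene is kept when its zero fraction is <= ``max_null_fraction``
    (strictly more than the cap is removed).
    """
    null_frac = (expr.values == 0).mean(axis=1)
    keep = null_frac <= max_null_fraction
    logger.info("filter_expressed_genes: kept %d / %d genes", int(keep.sum()), len(keep))
    return expr.subset_ids(expr.ids[keep])


def residualize(
    matrix: QuantificationMatrix, covariates: np.ndarray | None
) -> QuantificationMatrix:
    """Replace each phenotype by its OLS residuals on the covariates.

    An intercept is always included, so with no covariates the output
    is the per-phenotype centred matrix. Residuals are orthogonal to
    every covariate column. Rank-deficient covariate matrices are
    rejected with the collinear columns listed.
    """
    n = matrix.n_samples
    if covariates is None or np.size(covariates) == 0:
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != n:
            raise ValueError("covariates must have one row per sample")
        if covariates.shape[1] >= n:
            raise ValueError("need k < n_samples covariates")
        design = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j - 1)  # covariate index (0-based, sans intercept)
            else:
                kept = cand
        raise ValueError(f"rank-deficient covariates; collinear columns {bad}")
    # projection residual: Y - X (X'X)^-1 X' Y, applied to phenotypes-as-columns
    coef, *_ = np.linalg.lstsq(design, matrix.values.T, rcond=None)
    resid = matrix.values.T - design @ coef
    return matrix.with_values(resid.T)


def rank_normal(matrix: QuantificationMatrix) -> QuantificationMatrix:
    """Per-phenotype rank-based inverse-normal transform.

    Each row is mapped to ``Phi^-1((rank - 0.5) / n)`` with ties given
    their average rank, so quantifications match a standard normal up
    to the rank grid. The transform is invariant to monotone changes
    of the input and idempotent up to ties.
    """
    v = matrix.values
    n = matrix.n_samples
    out = np.empty_like(v, dtype=float)
    const = np.flatnonzero(v.std(axis=1) == 0)
    if len(const):
        raise ValueError(
            f"constant phenotype row(s) cannot be rank-normalised: "
            f"{list(matrix.ids[const][:5])}"
        )
    ranks = stats.rankdata(v, axis=1, method="average")
    out = stats.norm.ppf((ranks - 0.5) / n)
    return matrix.with_values(out)


def compute_pcs(matrix: QuantificationMatrix, n_pcs: int) -> np.ndarray:
    """Principal-component sample coordinates of a phenotype matrix.

    Samples are the observations; rows are centred first. Returns an
    (n_samples, n_pcs) array.
    """
    from sklearn.decomposition import PCA

    x = matrix.values.T  # samples x phenotypes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    return PCA(n_components=n_pcs, svd_solver="randomized", random_state=0).fit_transform(
        x - x.mean(axis=0)
    )


def select_n_pcs(
    matrix: QuantificationMatrix,
    genotypes,
    grid: list[int],
    cis_window: int = 1_000_000,
    fdr: float = 0.05,
    n_perm: int = 200,
    extra_covariates: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[int, list[tuple[int, int]]]:
    """Pick the PC count that maximises the cis-QTL yield.

    The matrix is progressively corrected with each candidate number of
    leading PCs (computed once on the uncorrected matrix), rank-
    normalised and scanned for QTLs; the grid value with the most
    significant phenotypes wins, ties going to the smallest value.
    Returns ``(best, [(n_pcs, yield), ...])``.
    """
    from .association import map_cis

    if not grid:
        raise ValueError("empty PC grid")
    for g in grid:
        if g >= matrix.n_samples:
            raise ValueError(f"grid value {g} >= n_samples {matrix.n_samples}")
    pcs = compute_pcs(matrix, max(grid))
    table = []
    for g in sorted(grid):
        cov = pcs[:, :g]
        if extra_covariates is not None:
            cov = np.column_stack([extra_covariates, cov])
        corrected = rank_normal(residualize(matrix, cov))
        res = map_cis(
            corrected, genotypes, window_bp=cis_window, n_perm=n_perm,
            fdr=fdr, seed=seed,
        )
        n_hits = int(res["significant"].sum()) if len(res) else 0
        table.append((g, n_hits))
        logger.info("select_n_pcs: %d PCs -> %d QTLs", g, n_hits)
    best = max(table, key=lambda t: (t[1], -t[0]))[0]
    return best, table
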