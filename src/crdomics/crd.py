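"""Cis-regulatory-domain calling from population correlation structure.

Pipeline per chromosome:

1. :func:`correlation_map` — Pearson correlation between phenotypes
   within a sliding window of 250 phenotypes (index distance), on the
   corrected, rank-normalised matrix. Pairs beyond the window are
   untested and contribute nothing to any correlation summary.
2. :func:`build_tree` — agglomerative (average-linkage) clustering on
   the distance ``1 - |r|`` (untested pairs at distance 1), yielding a
   binary tree over the chromosome's phenotypes.
3. :func:`call_crds` — root-down traversal emitting the first internal
   node on each path that satisfies the domain criteria; emitted nodes
   are not descended into, so CRDs from one tree are disjoint.

Domain criteria for an internal node:

i.   High internal correlation: the mean absolute correlation over the
     node's tested pairs is at least ``factor`` (default 2) times the
     chromosome-wide mean over all tested pairs.
ii.  Well-defined boundaries: the mean absolute correlation over node
     pairs involving the node's genomically first or last member is at
     least ``factor`` times the analogous chromosome-level value
     (pairs involving the chromosome's first or last phenotype).
iii. At least two members with non-overlapping genomic intervals, so a
     domain always spans at least two distinct regulatory regions.

Two refinements make the criteria robust to sampling noise, which is
essential at population sample sizes where even independent phenotypes
show correlations of order ``1/sqrt(n)``:

* Noise floor: pair correlations that are not significantly non-zero
  (two-sided t-test, Bonferroni-corrected over the chromosome's tested
  pairs at ``pair_alpha``) are counted as zero in all criterion sums,
  so a node must hold genuine correlation mass to qualify — on a
  fully independent matrix no domain is ever called.
* Cohesion: the node's two subtrees must themselves be correlated —
  the mean masked ``|r|`` over cross-subtree pairs must clear the same
  ``factor x baseline`` bar. This is equivalent to cutting the tree at
  a data-driven correlation height and prevents two unrelated distant
  blocks that happen to merge from being reported as one domain.

Methylation domains additionally pass through a two-component Gaussian
mixture on log10(size): the small-domain component (probes within one
regulatory region) is removed by thresholding at its 0.95 quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .containers import CRD, QuantificationMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 250


@dataclass
class CorrelationMap:
    """Banded Pearson correlations for one chromosome.

    ``band[d-1, i]`` is the correlation between phenotypes ``i`` and
    ``i + d`` (index distance d <= window); entries beyond the
    chromosome end are NaN.
    """

    chrom: str
    ids: np.ndarray
    start: np.ndarray
    end: np.ndarray
    window: int
    band: np.ndarray           # (window, n) with NaN padding
    n_samples: int

    @property
    def n_peaks(self) -> int:
        return len(self.ids)

    def r(self, i: int, j: int) -> float:
        """Correlation of a tested pair; NaN when untested."""
        if i == j:
            return 1.0
        i, j = min(i, j), max(i, j)
        d = j - i
        if d > self.window:
            return float("nan")
        return float(self.band[d - 1, i])

    def dense_abs(self) -> np.ndarray:
        """Dense |r| matrix with NaN at untested pairs and the diagonal."""
        n = self.n_peaks
        m = np.full((n, n), np.nan)
        for d in range(1, min(self.window, n - 1) + 1):
            v = np.abs(self.band[d - 1, : n - d])
            idx = np.arange(n - d)
            m[idx, idx + d] = v
            m[idx + d, idx] = v
        return m

    def significance_threshold(self, alpha: float) -> float:
        """|r| above which a pair is Bonferroni-significant at ``alpha``."""
        n = self.n_peaks
        n_pairs = int(
            sum(n - d for d in range(1, min(self.window, n - 1) + 1))
        )
        if n_pairs == 0 or self.n_samples < 4:
            return 0.0
        t_crit = stats.t.isf(alpha / (2 * n_pairs), df=self.n_samples - 2)
        return float(t_crit / np.sqrt(self.n_samples - 2 + t_crit**2))


def correlation_map(
    matrix: QuantificationMatrix, window: int = DEFAULT_WINDOW
) -> dict[str, CorrelationMap]:
    """Per-chromosome banded correlation maps of a phenotype matrix."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation maps")
    out: dict[str, CorrelationMap] = {}
    for chrom in matrix.chromosomes():
        sub = matrix.subset_chrom(chrom)
        n = sub.n_phenotypes
        x = sub.values
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan  # constant rows yield NaN correlations
        z = (x - mu) / sd / np.sqrt(x.shape[1])
        band = np.full((window, n), np.nan)
        for d in range(1, min(window, n - 1) + 1):
            band[d - 1, : n - d] = np.einsum("ij,ij->i", z[:-d], z[d:])
        np.clip(band, -1.0, 1.0, out=band)
        out[chrom] = CorrelationMap(
            chrom=chrom, ids=sub.ids, start=sub.start, end=sub.end,
            window=window, band=band, n_samples=matrix.n_samples,
        )
    return out


@dataclass
class DendroTree:
    """Binary agglomeration tree over one chromosome's phenotypes.

    ``linkage_matrix`` follows the scipy convention: row k merges nodes
    ``Z[k,0]`` and ``Z[k,1]`` (ids < n are leaves) at height
    ``Z[k,2]`` into node ``n + k``.
    """

    chrom: str
    n_leaves: int
    linkage_matrix: np.ndarray
    _members: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_internal(self) -> int:
        return len(self.linkage_matrix)

    @property
    def root(self) -> int:
        return self.n_leaves + self.n_internal - 1

    def children(self, node: int) -> tuple[int, int]:
        k = node - self.n_leaves
        return int(self.linkage_matrix[k, 0]), int(self.linkage_matrix[k, 1])

    def height(self, node: int) -> float:
        return float(self.linkage_matrix[node - self.n_leaves, 2])

    def members(self, node: int) -> np.ndarray:
        """Sorted leaf indices under ``node`` (memoised)."""
        if node < self.n_leaves:
            return np.array([node])
        if node not in self._members:
            # resolve bottom-up so deep trees don't recurse
            for k in range(self.n_internal):
                nid = self.n_leaves + k
                if nid in self._members:
                    continue
                a, b = self.children(nid)
                ma = self._members[a] if a >= self.n_leaves else np.array([a])
                mb = self._members[b] if b >= self.n_leaves else np.array([b])
                self._members[nid] = np.sort(np.concatenate([ma, mb]))
        return self._members[node]

    def internal_nodes(self) -> list[int]:
        return list(range(self.n_leaves, self.n_leaves + self.n_internal))


def build_tree(cmap: CorrelationMap, signed: bool = False) -> DendroTree:
    """Average-linkage tree on correlation distance.

    Distance is ``1 - |r|`` (or ``1 - r`` with ``signed=True``);
    untested pairs sit at distance 1. Constant phenotypes (NaN
    correlations) are treated as uncorrelated.
    """
    n = cmap.n_peaks
    if n < 2:
        logger.warning("chromosome %s has %d phenotype(s); empty tree", cmap.chrom, n)
        return DendroTree(cmap.chrom, n, np.empty((0, 4)))
    dense = np.ones((n, n))
    for d in range(1, min(cmap.window, n - 1) + 1):
        v = cmap.band[d - 1, : n - d]
        dist = 1.0 - (v if signed else np.abs(v))
        dist = np.where(np.isnan(dist), 1.0, dist)
        idx = np.arange(n - d)
        dense[idx, idx + d] = dist
        dense[idx + d, idx] = dist
    np.fill_diagonal(dense, 0.0)
    condensed = dense[np.triu_indices(n, k=1)]
    z = linkage(np.clip(condensed, 0.0, None), method="average")
    return DendroTree(cmap.chrom, n, z)


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture on log10 domain size (bp)."""

    mu_small: float
    sigma_small: float
    mu_large: float
    sigma_large: float
    weight_small: float
    converged: bool
    log_likelihood: float

    @property
    def size_threshold_bp(self) -> float:
        # 0.95 quantile of the small-domain component
        return float(10 ** (self.mu_small + 1.6449 * self.sigma_small))


def _node_criteria(
    masked: np.ndarray,
    members: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    baseline_all: float,
    baseline_ends: float,
    factor: float,
    left: np.ndarray | None,
    right: np.ndarray | None,
    require_cohesion: bool,
) -> bool:
    """Evaluate domain criteria i-iii (+ cohesion) for one member set.

    ``masked`` is the dense |r| matrix with untested pairs NaN and
    sub-threshold pairs zeroed.
    """
    sub = masked[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    vals = sub[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return False
    mean_all = float(vals.mean())
    if not (mean_all > 0 and mean_all >= factor * baseline_all):
        return False

    first = members[np.argmin(starts[members])]
    last = members[np.argmax(starts[members])]
    v1 = masked[first, members[members != first]]
    v2 = masked[last, members[(members != last) & (members != first)]]
    edge_vals = np.concatenate([v1, v2])
    edge_vals = edge_vals[~np.isnan(edge_vals)]
    if len(edge_vals) == 0:
        return False
    mean_edge = float(edge_vals.mean())
    if not (mean_edge > 0 and mean_edge >= factor * baseline_ends):
        return False

    # criterion iii: some pair of member intervals does not overlap
    if not (starts[members].max() >= ends[members].min()):
        return False

    if require_cohesion and left is not None and right is not None:
        cross = masked[np.ix_(left, right)]
        cross = cross[~np.isnan(cross)]
        if len(cross) == 0:
            return False
        mean_cross = float(cross.mean())
        if not (mean_cross > 0 and mean_cross >= factor * baseline_all):
            return False
    return True


def _chromosome_baselines(masked: np.ndarray) -> tuple[float, float]:
    n = masked.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = masked[iu]
    vals = vals[~np.isnan(vals)]
    baseline_all = float(vals.mean()) if len(vals) else 0.0
    # pairs involving the chromosome's first or last phenotype, each once
    edge = np.concatenate([masked[0, 1:], masked[n - 1, 1 : n - 1]])
    edge = edge[~np.isnan(edge)]
    baseline_ends = float(edge.mean()) if len(edge) else 0.0
    return baseline_all, baseline_ends


def call_crds(
    tree: DendroTree,
    cmap: CorrelationMap,
    factor: float = 2.0,
    pair_alpha: float = 0.01,
    require_cohesion: bool = True,
    crd_class: str = "hCRD",
    id_prefix: str | None = None,
) -> list[CRD]:
    """Call CRDs on one chromosome by root-down tree traversal.

    Starting from the root, the first internal node on each path that
    satisfies all criteria is emitted as a CRD and not descended into.
    ``pair_alpha`` sets the Bonferroni level of the pair-significance
    noise floor (``None`` disables masking); ``require_cohesion``
    additionally demands that the node's two subtrees be correlated
    with each other.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if tree.chrom != cmap.chrom:
        raise ValueError("tree and correlation map are from different chromosomes")
    if tree.n_leaves < 2:
        return []
    masked = cmap.dense_abs()
    if pair_alpha is not None:
        thr = cmap.significance_threshold(pair_alpha)
        with np.errstate(invalid="ignore"):
            masked[masked < thr] = 0.0
    baseline_all, baseline_ends = _chromosome_baselines(masked)

    starts, ends = cmap.start, cmap.end
    hits: list[np.ndarray] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node < tree.n_leaves:
            continue
        members = tree.members(node)
        a, b = tree.children(node)
        left = tree.members(a)
        right = tree.members(b)
        if _node_criteria(
            masked, members, starts, ends, baseline_all, baseline_ends,
            factor, left, right, require_cohesion,
        ):
            hits.append(members)
        else:
            stack.extend([a, b])

    hits.sort(key=lambda m: int(starts[m].min()))
    prefix = id_prefix or f"crd_{cmap.chrom}"
    crds: list[CRD] = []
    raw = cmap.dense_abs()
    for k, members in enumerate(hits):
        sub = raw[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        crds.append(
            CRD(
                crd_id=f"{prefix}_{k:04d}",
                chrom=cmap.chrom,
                start=int(starts[members].min()),
                end=int(ends[members].max()),
                members=[str(cmap.ids[i]) for i in members],
                mean_internal_abs_r=float(vals.mean()) if len(vals) else float("nan"),
                crd_class=crd_class,
            )
        )
    return crds


def call_crds_genomewide(
    matrix: QuantificationMatrix,
    window: int = DEFAULT_WINDOW,
    factor: float = 2.0,
    pair_alpha: float = 0.01,
    require_cohesion: bool = True,
    crd_class: str = "hCRD",
) -> list[CRD]:
    """Convenience wrapper: correlation map + tree + calling, all chromosomes."""
    cmaps = correlation_map(matrix, window=window)
    crds: list[CRD] = []
    for chrom, cmap in cmaps.items():
        if cmap.n_peaks < 2:
            continue
        tree = build_tree(cmap)
        crds.extend(
            call_crds(
                tree, cmap, factor=factor, pair_alpha=pair_alpha,
                require_cohesion=require_cohesion, crd_class=crd_class,
            )
        )
    return crds


def fit_size_mixture(lengths_bp: np.ndarray, random_state: int = 0) -> MixtureFit:
    """Fit the two-component Gaussian mixture to log10 domain sizes.

    EM runs to a log-likelihood tolerance of 1e-6 or 500 iterations.
    Degenerate inputs (effectively a single size) fall back to a
    one-component description with ``converged=False``.
    """
    lengths_bp = np.asarray(lengths_bp, dtype=float)
    if len(lengths_bp) < 20:
        raise ValueError("need at least 20 domain sizes to fit the mixture")
    if np.any(lengths_bp <= 0):
        raise ValueError("domain sizes must be positive")
    x = np.log10(lengths_bp)[:, None]
    if np.ptp(x) < 1e-9:
        logger.warning("all domain sizes identical; single-component fallback")
        mu = float(x.mean())
        return MixtureFit(mu, 0.0, mu, 0.0, 1.0, False, float("nan"))
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=2, covariance_type="full", tol=1e-6, max_iter=500,
        n_init=5, random_state=random_state,
    ).fit(x)
    mus = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(mus)
    mu_s, mu_l = mus[order]
    sd_s, sd_l = sigmas[order]
    w_s = float(weights[order][0])
    ll = float(gm.score(x) * len(x))
    if min(sd_s, sd_l) < 1e-6:
        logger.warning("degenerate mixture component (sigma -> 0); fallback")
        mu = float(x.mean())
        return MixtureFit(mu, float(x.std()), mu, float(x.std()), 1.0, False, ll)
    return MixtureFit(float(mu_s), float(sd_s), float(mu_l), float(sd_l),
                      w_s, bool(gm.converged_), ll)


def size_filter_mcrds(
    crds: list[CRD], fit: MixtureFit, fallback_threshold_bp: float | None = None
) -> list[CRD]:
    """Keep methylation CRDs whose span strictly exceeds the size threshold.

    The threshold is the 0.95 quantile of the small-domain component;
    domains at or below it are promoter-scale probe clusters, not
    multi-region domains. A span exactly at the threshold is removed.
    """
    if not fit.converged:
        if fallback_threshold_bp is None:
            raise ValueError("mixture fit did not converge and no fallback threshold given")
        threshold = fallback_threshold_bp
    else:
        threshold = fit.size_threshold_bp
    return [c for c in crds if c.span > threshold]
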