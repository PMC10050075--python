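"""Cis association engine: CRD activity, windowed linear-regression
scans, permutation adjustment, FDR control and conditional analysis.

The same machinery serves CRD-gene mapping, CRD-QTL mapping, eQTL
mapping and gene co-expression. For each phenotype (a CRD activity
vector or a gene) the engine

1. enumerates candidate features (gene TSS or variants) within a
   +/- 1 Mb window of the phenotype's boundaries,
2. fits a simple linear regression per feature and keeps the best
   nominal p (smallest; ties to the smallest genomic position),
3. calibrates that best p against ``n_perm`` phenotype permutations
   (empirical adjusted p with add-one smoothing, so the resolution is
   1/(n_perm+1)),
4. controls FDR across phenotypes with Storey q-values, and
5. optionally runs a forward-backward conditional scan for multiple
   independent signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CRD, ActivityMatrix, GenotypeMatrix, QuantificationMatrix

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "phenotype_id", "feature_id", "slope", "nominal_p", "adjusted_p",
    "q_value", "significant", "rank", "n_features",
]


def crd_activity(matrix: QuantificationMatrix, crds: list[CRD]) -> ActivityMatrix:
    """Per-individual CRD activity: unweighted mean of member rows."""
    index = {str(i): k for k, i in enumerate(matrix.ids)}
    rows, ids, chroms, starts, ends = [], [], [], [], []
    for crd in crds:
        try:
            idx = [index[m] for m in crd.members]
        except KeyError as exc:
            raise KeyError(f"CRD {crd.crd_id}: member {exc.args[0]} missing from matrix")
        rows.append(matrix.values[idx].mean(axis=0))
        ids.append(crd.crd_id)
        chroms.append(crd.chrom)
        starts.append(crd.start)
        ends.append(crd.end)
    values = np.vstack(rows) if rows else np.empty((0, matrix.n_samples))
    return ActivityMatrix(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64),
        values, matrix.samples,
    )


@dataclass
class CisFeatures:
    """Candidate features for a cis scan: ids, positions, value rows."""

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray        # 1-based point position (variant pos or TSS)
    values: np.ndarray     # features x samples

    @classmethod
    def from_genotypes(cls, geno: GenotypeMatrix) -> "CisFeatures":
        return cls(geno.ids, geno.chrom, geno.pos, geno.dosages)

    @classmethod
    def from_expression(
        cls, expr: QuantificationMatrix, tss: pd.DataFrame | None = None
    ) -> "CisFeatures":
        """Genes as features, anchored at their TSS.

        Without an explicit TSS table the gene interval start is used
        (converted to a 1-based point).
        """
        if tss is None:
            pos = expr.start + 1
            return cls(expr.ids, expr.chrom, np.asarray(pos), expr.values)
        t = tss.set_index("gene_id")
        keep = [i for i, g in enumerate(expr.ids) if str(g) in t.index]
        ids = expr.ids[keep]
        return cls(
            ids,
            t.loc[list(map(str, ids)), "chrom"].to_numpy(dtype=object),
            t.loc[list(map(str, ids)), "tss"].to_numpy(dtype=np.int64),
            expr.values[keep],
        )

    def in_window(self, chrom: str, start: int, end: int, window_bp: int) -> "CisFeatures":
        """Features whose position falls within [start-window, end+window].

        ``start``/``end`` are the 0-based half-open anchor boundaries;
        positions are 1-based, so the inclusive position window is
        [start+1-window, end+window].
        """
        mask = (
            (self.chrom == chrom)
            & (self.pos >= start + 1 - window_bp)
            & (self.pos <= end + window_bp)
        )
        return CisFeatures(self.ids[mask], self.chrom[mask], self.pos[mask],
                           self.values[mask])

    @property
    def n_features(self) -> int:
        return len(self.ids)


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = values.std(axis=1)
    mu = values.mean(axis=1, keepdims=True)
    z = np.zeros_like(values, dtype=float)
    ok = sd > 0
    z[ok] = (values[ok] - mu[ok]) / sd[ok, None]
    return z, sd


@dataclass
class CisHit:
    feature_id: str
    feature_index: int
    slope: float
    r: float
    nominal_p: float
    n_features: int


def cis_scan(phenotype: np.ndarray, features: CisFeatures) -> CisHit | None:
    """Best single-feature linear association within the window.

    Returns None (an untested phenotype) when the window holds no
    testable feature. Zero-variance features are skipped with a
    warning. Ties on p go to the smallest genomic position.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if features.n_features == 0:
        return None
    zf, sd_f = _standardize_rows(features.values)
    ok = sd_f > 0
    if not ok.any():
        return None
    if (~ok).any():
        logger.warning("cis_scan: skipped %d zero-variance features", int((~ok).sum()))
    sd_y = y.std()
    if sd_y == 0:
        return None
    zy = (y - y.mean()) / sd_y
    r = zf @ zy / n
    r[~ok] = 0.0
    absr = np.abs(r)
    best_abs = absr[ok].max()
    cand = np.flatnonzero(ok & (absr >= best_abs - 1e-15))
    best = cand[np.argmin(features.pos[cand])]
    rb = float(np.clip(r[best], -0.9999999999, 0.9999999999))
    t = rb * np.sqrt(n - 2) / np.sqrt(1 - rb**2)
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    slope = rb * sd_y / sd_f[best]
    return CisHit(str(features.ids[best]), int(best), float(slope), rb, p,
                  int(ok.sum()))


def make_permutations(n_samples: int, n_perm: int, seed: int) -> np.ndarray:
    """Permutation index matrix (n_perm x n_samples), reusable across phenotypes."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n_samples) for _ in range(n_perm)])


def permutation_adjust(
    phenotype: np.ndarray,
    features: CisFeatures,
    n_perm: int = 1000,
    seed: int = 0,
    perm_indices: np.ndarray | None = None,
) -> float:
    """Empirical adjusted p for the best association in the window.

    The phenotype is shuffled across samples; the adjusted p is
    ``(1 + #{permutations whose best nominal p <= observed}) /
    (1 + n_perm)``. Because every feature is tested at the same df,
    comparing best |r| is equivalent to comparing best p.
    """
    if perm_indices is None:
        if n_perm < 100:
            logger.warning("n_perm=%d gives adjusted-p resolution %.3g",
                           n_perm, 1 / (n_perm + 1))
        perm_indices = make_permutations(len(phenotype), n_perm, seed)
    n_perm = len(perm_indices)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    zf, sd_f = _standardize_rows(features.values)
    zf = zf[sd_f > 0]
    if len(zf) == 0 or y.std() == 0:
        return float("nan")
    zy = (y - y.mean()) / y.std()
    obs = np.abs(zf @ zy / n).max()
    perm_best = np.abs(zy[perm_indices] @ zf.T / n).max(axis=1)
    hits = int((perm_best >= obs - 1e-15).sum())
    return (1 + hits) / (1 + n_perm)


def storey_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 with a cubic smoother over the lambda grid.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on
    a 0.05..0.95 grid, smoothed with a cubic polynomial and read off
    at the largest lambda. Small inputs (< 50 p-values) fall back to
    the conservative pi0 = 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m < 50:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    if pi0 <= 0:
        pi0 = float(max(pi0_l.min(), 1.0 / m))
    return min(pi0, 1.0)


def fdr_qvalue(
    pvals: np.ndarray, method: str = "storey", level: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Q-values and significance calls across a family of tests.

    ``storey`` scales Benjamini-Hochberg by the estimated null
    proportion pi0; ``bh`` is plain step-up (pi0 = 1).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool), 1.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown FDR method {method!r}")
    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(p, method="fdr_bh")
        return q, q <= level, 1.0
    pi0 = storey_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= level, pi0


def significance_threshold(adjusted_p: np.ndarray, q: np.ndarray, level: float) -> float:
    """Adjusted-p cut-off matching a q-value level (for conditional scans).

    Interpolates between the largest significant and smallest
    non-significant adjusted p-values.
    """
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    sig = q <= level
    if not sig.any():
        return 0.0
    lo = adjusted_p[sig].max()
    rest = adjusted_p[~sig & np.isfinite(adjusted_p)]
    if len(rest) == 0:
        return float(lo)
    hi = rest.min()
    return float((lo + hi) / 2) if hi > lo else float(lo)


def conditional_scan(
    phenotype: np.ndarray,
    features: CisFeatures,
    adjusted_p_threshold: float,
    perm_indices: np.ndarray,
    max_signals: int = 10,
) -> list[CisHit]:
    """Forward-backward scan for multiple independent cis signals.

    Forward: repeatedly residualize the phenotype on the selected
    features and add the best remaining feature while its permutation-
    adjusted p passes the per-phenotype threshold. Backward: re-test
    each selected feature conditioning on all the others and drop
    failures. Ranks follow forward order.
    """
    y = np.asarray(phenotype, dtype=float)
    selected: list[CisHit] = []
    for _ in range(max_signals):
        y_res = _residualize_on(y, features, [h.feature_index for h in selected])
        if y_res is None:
            break
        hit = cis_scan(y_res, features)
        if hit is None:
            break
        adj = permutation_adjust(y_res, features, perm_indices=perm_indices)
        if not np.isfinite(adj) or adj > adjusted_p_threshold:
            break
        if hit.feature_index in [h.feature_index for h in selected]:
            break  # collinearity guard: same feature re-selected
        selected.append(hit)
    if len(selected) <= 1:
        return selected
    kept: list[CisHit] = []
    for i, hit in enumerate(selected):
        others = [h.feature_index for j, h in enumerate(selected) if j != i]
        y_res = _residualize_on(y, features, others)
        if y_res is None:
            continue
        sub = CisFeatures(
            features.ids[[hit.feature_index]], features.chrom[[hit.feature_index]],
            features.pos[[hit.feature_index]], features.values[[hit.feature_index]],
        )
        adj = permutation_adjust(y_res, sub, perm_indices=perm_indices)
        if np.isfinite(adj) and adj <= adjusted_p_threshold:
            kept.append(hit)
        else:
            logger.info("conditional_scan: dropped %s in backward pass", hit.feature_id)
    return kept


def _residualize_on(
    y: np.ndarray, features: CisFeatures, indices: list[int]
) -> np.ndarray | None:
    design = np.column_stack(
        [np.ones(len(y))] + [features.values[i] for i in indices]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("conditional_scan: collinear selected features")
        design = design[:, : np.linalg.matrix_rank(design)]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    res = y - design @ coef
    if res.std() < 1e-12:
        return None
    return res


def map_cis(
    phenotypes: QuantificationMatrix | ActivityMatrix,
    features: CisFeatures | GenotypeMatrix,
    window_bp: int = 1_000_000,
    n_perm: int = 1000,
    fdr: float = 0.05,
    fdr_method: str = "storey",
    conditional: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cis mapping: scan, permutation adjustment, FDR, conditionals.

    Returns one row per phenotype (rank 0) plus one row per additional
    independent signal (rank >= 1). Untested phenotypes (no feature in
    the window) carry NaN statistics and are excluded from the FDR
    family. Deterministic for a fixed seed.
    """
    if isinstance(features, GenotypeMatrix):
        features = CisFeatures.from_genotypes(features)
    perm_indices = make_permutations(phenotypes.n_samples if hasattr(phenotypes, "n_samples")
                                     else phenotypes.values.shape[1], n_perm, seed)
    rows = []
    windowed: list[CisFeatures | None] = []
    for i in range(len(phenotypes.ids)):
        win = features.in_window(
            str(phenotypes.chrom[i]), int(phenotypes.start[i]),
            int(phenotypes.end[i]), window_bp,
        )
        windowed.append(win)
        hit = cis_scan(phenotypes.values[i], win)
        if hit is None:
            rows.append([str(phenotypes.ids[i]), None, np.nan, np.nan, np.nan, 0])
            continue
        adj = permutation_adjust(phenotypes.values[i], win, perm_indices=perm_indices)
        rows.append([str(phenotypes.ids[i]), hit.feature_id, hit.slope,
                     hit.nominal_p, adj, hit.n_features])
    df = pd.DataFrame(rows, columns=["phenotype_id", "feature_id", "slope",
                                     "nominal_p", "adjusted_p", "n_features"])
    tested = df["adjusted_p"].notna()
    q = np.full(len(df), np.nan)
    sig = np.zeros(len(df), dtype=bool)
    pi0 = 1.0
    if tested.any():
        q_t, sig_t, pi0 = fdr_qvalue(df.loc[tested, "adjusted_p"].to_numpy(),
                                     method=fdr_method, level=fdr)
        q[tested.to_numpy()] = q_t
        sig[tested.to_numpy()] = sig_t
    df["q_value"] = q
    df["significant"] = sig
    df["rank"] = 0

    if conditional and sig.any():
        thr = significance_threshold(
            df.loc[tested, "adjusted_p"].to_numpy(), q[tested.to_numpy()], fdr
        )
        extra = []
        for i in np.flatnonzero(sig):
            hits = conditional_scan(
                phenotypes.values[i], windowed[i], thr, perm_indices
            )
            for rank, h in enumerate(hits):
                if rank == 0:
                    continue  # primary already reported
                extra.append({
                    "phenotype_id": str(phenotypes.ids[i]), "feature_id": h.feature_id,
                    "slope": h.slope, "nominal_p": h.nominal_p,
                    "adjusted_p": np.nan, "n_features": h.n_features,
                    "q_value": np.nan, "significant": True, "rank": rank,
                })
        if extra:
            df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df.reset_index(drop=True)


def coexpression_pairs(
    expr: QuantificationMatrix,
    max_distance_bp: int = 1_000_000,
    fdr: float = 0.01,
    tss: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlation of expression for same-chromosome gene pairs.

    Pairs with TSS distance <= ``max_distance_bp`` are tested with a
    Pearson correlation t-test; Storey q-values across all pairs;
    significance at q <= ``fdr`` (1% by default).
    """
    feats = CisFeatures.from_expression(expr, tss)
    n = expr.n_samples
    z, sd = _standardize_rows(feats.values)
    rows = []
    for chrom in np.unique(feats.chrom.astype(str)):
        idx = np.flatnonzero(feats.chrom == chrom)
        idx = idx[np.argsort(feats.pos[idx], kind="stable")]
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                dist = int(abs(feats.pos[j] - feats.pos[i]))
                if dist > max_distance_bp:
                    continue
                if sd[i] == 0 or sd[j] == 0:
                    continue
                r = float(np.clip(z[i] @ z[j] / n, -0.9999999999, 0.9999999999))
                t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
                p = float(2 * stats.t.sf(abs(t), df=n - 2))
                rows.append([str(feats.ids[i]), str(feats.ids[j]), r, p, dist])
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "distance"])
    if len(df):
        q, sig, _ = fdr_qvalue(df["p"].to_numpy(), method="storey", level=fdr)
        df["q"] = q
        df["significant"] = sig
    else:
        df["q"] = []
        df["significant"] = []
    return df


def same_crd_enrichment(
    pairs: pd.DataFrame,
    crd_gene: pd.DataFrame,
    bins: np.ndarray,
) -> pd.DataFrame:
    """Fraction and odds ratio of co-expressed pairs sharing a CRD.

    ``pairs`` is the co-expression table (all tested pairs, with a
    ``significant`` flag); ``crd_gene`` a significant CRD-gene
    association table. Per distance bin the 2x2 contingency of
    (co-expressed x same-CRD) yields an odds ratio (Haldane 0.5
    correction when a cell is zero).
    """
    bins = np.asarray(bins)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be increasing")
    sig_assoc = crd_gene[crd_gene["significant"] & (crd_gene["rank"] == 0)]
    gene_to_crds: dict[str, set[str]] = {}
    for _, rec in sig_assoc.iterrows():
        # phenotype/feature orientation: one of the two ids is the gene
        gene_to_crds.setdefault(str(rec["feature_id"]), set()).add(str(rec["phenotype_id"]))
    same = np.array([
        bool(gene_to_crds.get(str(a), set()) & gene_to_crds.get(str(b), set()))
        for a, b in zip(pairs["gene_a"], pairs["gene_b"])
    ]) if len(pairs) else np.array([], dtype=bool)
    coex = pairs["significant"].to_numpy(dtype=bool) if len(pairs) else np.array([], dtype=bool)
    dist = pairs["distance"].to_numpy() if len(pairs) else np.array([])
    out = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        in_bin = (dist >= lo) & (dist < hi)
        n_coex = int((in_bin & coex).sum())
        if n_coex == 0:
            out.append({"bin_lo": lo, "bin_hi": hi, "n_pairs": 0,
                        "fraction_same_crd": np.nan, "odds_ratio": np.nan})
            continue
        a = int((in_bin & coex & same).sum())        # co-expressed, same CRD
        b = n_coex - a                                # co-expressed, different
        c = int((in_bin & ~coex & same).sum())
        d = int((in_bin & ~coex).sum()) - c
        if min(a, b, c, d) == 0:
            a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a2, b2, c2, d2 = a, b, c, d
        out.append({
            "bin_lo": lo, "bin_hi": hi, "n_pairs": n_coex,
            "fraction_same_crd": a / n_coex,
            "odds_ratio": (a2 * d2) / (b2 * c2),
        })
    return pd.DataFrame(out)
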