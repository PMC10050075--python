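"""External-evidence statistics: PCHi-C support curves, TFBS Fisher
enrichment, local LD, GWAS overlap and the genomic inflation factor.

These consume externally computed tables (CHiCAGO-style interaction
scores, TFBS interval sets, GWAS summary statistics); nothing here
re-derives those scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import fdr_qvalue
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # ~0.454936


def _overlaps(frag_start, frag_end, start: int, end: int) -> np.ndarray:
    """Any-overlap (>= 1 bp) of half-open intervals, vectorised."""
    return (np.asarray(frag_start) < end) & (start < np.asarray(frag_end))


def pchic_support(
    pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]],
    interactions: pd.DataFrame,
    score_min: float = 5.0,
    min_distance_bp: int = 20_000,
    bins: np.ndarray | None = None,
    aggregate: str = "any",
    score_col: str | None = None,
) -> pd.DataFrame:
    """Fraction of interval pairs supported by promoter-capture Hi-C.

    A pair (A, B) is supported when an interaction whose fragments
    overlap A and B (either orientation) has score >= ``score_min``
    (``aggregate='any'``) or when the mean score over all matching
    interactions reaches it (``aggregate='mean'``, used for
    co-expressed gene pairs). Pairs separated by less than
    ``min_distance_bp`` are excluded: at short range genomic-distance
    noise dominates the capture signal. Returns per-bin counts and
    fractions.
    """
    if aggregate not in ("any", "mean"):
        raise ValueError("aggregate must be 'any' or 'mean'")
    if bins is None:
        bins = np.array([min_distance_bp, 50_000, 100_000, 200_000, 500_000,
                         1_000_000, 10_000_000])
    bins = np.asarray(bins)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing")
    score_col = score_col or interactions.columns[6]
    ia = interactions
    scores = ia[score_col].to_numpy(dtype=float)

    dists, supported = [], []
    for (ca, sa, ea), (cb, sb, eb) in pairs:
        if ca != cb:
            raise ValueError("PCHi-C support is defined for same-chromosome pairs")
        dist = max(sb - ea, sa - eb, 0)
        if dist < min_distance_bp:
            continue
        on_chrom = (ia["chromA"].astype(str) == ca) & (ia["chromB"].astype(str) == cb)
        fwd = on_chrom & _overlaps(ia["startA"], ia["endA"], sa, ea) & _overlaps(
            ia["startB"], ia["endB"], sb, eb
        )
        rev = on_chrom & _overlaps(ia["startA"], ia["endA"], sb, eb) & _overlaps(
            ia["startB"], ia["endB"], sa, ea
        )
        match = (fwd | rev).to_numpy()
        if aggregate == "any":
            ok = bool(match.any() and scores[match].max() >= score_min)
        else:
            ok = bool(match.any() and scores[match].mean() >= score_min)
        dists.append(dist)
        supported.append(ok)
    dists = np.asarray(dists)
    supported = np.asarray(supported, dtype=bool)
    out = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        in_bin = (dists >= lo) & (dists < hi)
        n = int(in_bin.sum())
        out.append({
            "bin_lo": int(lo), "bin_hi": int(hi), "n_pairs": n,
            "n_supported": int(supported[in_bin].sum()),
            "fraction": float(supported[in_bin].mean()) if n else np.nan,
        })
    return pd.DataFrame(out)


def rank_tfbs_by_crd_overlap(
    tfbs_sets: dict[str, pd.DataFrame],
    peaks_in_crds: pd.DataFrame,
    top_k: int = 50,
) -> list[str]:
    """The ``top_k`` TFBS sets overlapping the most CRD peaks.

    ``peaks_in_crds`` and each TFBS table need chrom/start/end columns
    (0-based half-open).
    """
    counts = []
    for name, df in tfbs_sets.items():
        if len(df) == 0:
            logger.warning("empty TFBS set %s skipped", name)
            continue
        n = 0
        for chrom in peaks_in_crds["chrom"].astype(str).unique():
            pk = peaks_in_crds[peaks_in_crds["chrom"].astype(str) == chrom]
            tf = df[df["chrom"].astype(str) == chrom]
            if len(tf) == 0:
                continue
            ts = tf["start"].to_numpy()
            te = tf["end"].to_numpy()
            for s, e in zip(pk["start"], pk["end"]):
                if np.any((ts < e) & (s < te)):
                    n += 1
        counts.append((name, n))
    counts.sort(key=lambda t: (-t[1], t[0]))
    return [name for name, _ in counts[:top_k]]


def tfbs_enrichment(
    significant_qtls: set[str],
    background_qtls: set[str],
    tfbs_sets: dict[str, pd.DataFrame],
    variant_positions: pd.DataFrame,
    peaks_in_crds: pd.DataFrame | None = None,
    top_k: int = 50,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Fisher's exact enrichment of significant QTLs in TFBS intervals.

    The background is the remaining tested (lead) QTL universe. When
    ``peaks_in_crds`` is given, TFBS sets are first ranked by overlap
    with CRD peaks and only the ``top_k`` most represented are tested.
    Odds ratios use the cross-product with a Haldane 0.5 correction
    when a cell is zero; q-values at 1% FDR by default.
    """
    vp = variant_positions.set_index("variant_id")
    background_only = set(background_qtls) - set(significant_qtls)
    if peaks_in_crds is not None:
        names = rank_tfbs_by_crd_overlap(tfbs_sets, peaks_in_crds, top_k)
    else:
        names = [n for n, df in sorted(tfbs_sets.items()) if len(df)][:top_k]
    rows = []
    for name in names:
        df = tfbs_sets[name]
        if len(df) == 0:
            continue

        def in_tfbs(variants: set[str]) -> int:
            n = 0
            for v in variants:
                if v not in vp.index:
                    continue
                chrom = str(vp.loc[v, "chrom"])
                pos0 = int(vp.loc[v, "pos"]) - 1  # 1-based -> 0-based point
                tf = df[df["chrom"].astype(str) == chrom]
                if len(tf) and np.any((tf["start"].to_numpy() <= pos0)
                                      & (pos0 < tf["end"].to_numpy())):
                    n += 1
            return n

        a = in_tfbs(significant_qtls)
        b = len(significant_qtls) - a
        c = in_tfbs(background_only)
        d = len(background_only) - c
        _, p = stats.fisher_exact([[a, b], [c, d]])
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({"tfbs": name, "n11": a, "n10": b, "n01": c, "n00": d,
                     "odds_ratio": float(orr), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        q, sig, _ = fdr_qvalue(out["p"].to_numpy(), method="bh", level=fdr)
        out["q"] = q
        out["significant"] = sig
    return out


def ld_matrix(genotypes: GenotypeMatrix, window_bp: int = 500_000) -> pd.DataFrame:
    """Pairwise dosage-correlation r^2 within a positional window.

    Zero-variance variants are skipped (logged). Pairs farther apart
    than ``window_bp`` are absent from the table.
    """
    if genotypes.n_variants < 2:
        raise ValueError("need at least 2 variants for LD")
    sd = genotypes.dosages.std(axis=1)
    skipped = int((sd == 0).sum())
    if skipped:
        logger.info("ld_matrix: skipped %d zero-variance variants", skipped)
    n = genotypes.dosages.shape[1]
    z = np.zeros_like(genotypes.dosages)
    ok = sd > 0
    z[ok] = (genotypes.dosages[ok] - genotypes.dosages[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    rows = []
    for chrom in np.unique(genotypes.chrom.astype(str)):
        idx = np.flatnonzero((genotypes.chrom == chrom) & ok)
        pos = genotypes.pos[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] > window_bp:
                    break  # positions are sorted within chromosome
                r = float(z[idx[a]] @ z[idx[b]] / n)
                rows.append([str(genotypes.ids[idx[a]]), str(genotypes.ids[idx[b]]),
                             min(r * r, 1.0)])
    return pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])


def ld_proxies(ld: pd.DataFrame, variant: str, r2_min: float) -> set[str]:
    """Variants in LD (r^2 > r2_min) with ``variant``, either orientation."""
    a = ld[(ld["variant_a"] == variant) & (ld["r2"] > r2_min)]["variant_b"]
    b = ld[(ld["variant_b"] == variant) & (ld["r2"] > r2_min)]["variant_a"]
    return set(a) | set(b)


def gwas_overlap(
    lead_qtls: set[str],
    gwas: pd.DataFrame,
    ld: pd.DataFrame,
    r2_min: float = 0.9,
    gwas_p_max: float = 1e-5,
) -> pd.DataFrame:
    """QTLs overlapping a GWAS signal directly or through an LD proxy.

    A lead QTL overlaps when it, or any variant with r^2 > ``r2_min``
    to it, has GWAS p < ``gwas_p_max``. One row per (qtl, proxy) hit;
    invariant to GWAS row order and LD pair orientation.
    """
    gw = gwas.set_index(gwas.columns[0])[gwas.columns[1]]
    rows = []
    for qtl in sorted(lead_qtls):
        candidates = {qtl} | ld_proxies(ld, qtl, r2_min)
        for v in sorted(candidates):
            if v in gw.index and float(gw.loc[v]) < gwas_p_max:
                rows.append({"qtl": qtl, "proxy": v, "gwas_p": float(gw.loc[v])})
    return pd.DataFrame(rows, columns=["qtl", "proxy", "gwas_p"])


def inflation_lambda(pvals: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ-plot coordinates.

    p-values are transformed to chi-square(1 df) statistics; lambda is
    the observed median over the null median (~0.4549). Returns
    (lambda, QQ table of -log10 expected vs observed).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("inflation_lambda of empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    order = np.argsort(p)
    m = len(p)
    qq = pd.DataFrame({
        "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
        "observed": -np.log10(p[order]),
    })
    return lam, qq
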