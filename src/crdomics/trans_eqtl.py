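"""Trans-eQTL discovery through the trans CRD network.

Instead of testing every variant against every distant gene, candidate
(variant, gene) pairs are nominated by chaining already-significant
associations:

* scenario 1: variant --(CRD-QTL, cis)--> CRD_A --(trans)--> CRD_B
  --(CRD-gene, cis)--> gene
* scenario 2: variant --(eQTL, cis)--> gene1 --(gene-CRD, cis)-->
  CRD_A --(trans)--> CRD_B --(CRD-gene, cis)--> gene2

Each nominated pair (variant and gene on different chromosomes by
construction of the trans layer) is then tested directly by linear
regression of expression on dosage, with Storey FDR across the tested
candidates. The search-space reduction relative to all cross-
chromosome pairs is the point of the construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import fdr_qvalue
from .containers import GenotypeMatrix, QuantificationMatrix
from .integrate import ld_proxies

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ["variant_id", "gene_id", "scenario", "chain"]


def _sig_pairs(table: pd.DataFrame) -> pd.DataFrame:
    if "significant" in table.columns:
        return table[table["significant"]]
    return table


def enumerate_candidates(
    crd_qtls: pd.DataFrame | None,
    eqtls: pd.DataFrame | None,
    crd_gene: pd.DataFrame,
    trans_edges: pd.DataFrame,
    scenario: int,
    gene_crd: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join significant association layers into untested candidates.

    Tables follow the association-record convention: ``phenotype_id``
    is the CRD (for CRD-QTL and CRD-gene layers) or the gene (for
    eQTLs), ``feature_id`` the variant or gene at the other end.
    ``gene_crd`` (scenario 2's gene-to-CRD layer) defaults to the
    CRD-gene table read in the opposite direction. Duplicate
    (variant, gene) pairs are collapsed; all nominating chains are
    kept in the ``chain`` column.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    edges = _sig_pairs(trans_edges)
    cg = _sig_pairs(crd_gene)
    crd_to_genes: dict[str, list[str]] = {}
    for _, rec in cg.iterrows():
        crd_to_genes.setdefault(str(rec["phenotype_id"]), []).append(str(rec["feature_id"]))

    rows = []
    if scenario == 1:
        if crd_qtls is None:
            raise ValueError("scenario 1 needs the CRD-QTL table")
        cq = _sig_pairs(crd_qtls)
        crd_to_variant = dict(zip(cq["phenotype_id"].astype(str),
                                  cq["feature_id"].astype(str)))
        for _, e in edges.iterrows():
            for crd_a, crd_b in ((str(e["crd_a"]), str(e["crd_b"])),
                                 (str(e["crd_b"]), str(e["crd_a"]))):
                v = crd_to_variant.get(crd_a)
                if v is None:
                    continue
                for g in crd_to_genes.get(crd_b, []):
                    rows.append([v, g, 1, f"{crd_a}>{crd_b}"])
    else:
        if eqtls is None:
            raise ValueError("scenario 2 needs the eQTL table")
        eq = _sig_pairs(eqtls)
        gene_to_variant = dict(zip(eq["phenotype_id"].astype(str),
                                   eq["feature_id"].astype(str)))
        gc = _sig_pairs(gene_crd) if gene_crd is not None else cg
        gene_to_crds: dict[str, list[str]] = {}
        if gene_crd is not None:
            for _, rec in gc.iterrows():
                gene_to_crds.setdefault(str(rec["phenotype_id"]), []).append(
                    str(rec["feature_id"]))
        else:
            for _, rec in gc.iterrows():
                gene_to_crds.setdefault(str(rec["feature_id"]), []).append(
                    str(rec["phenotype_id"]))
        edge_map: dict[str, list[str]] = {}
        for _, e in edges.iterrows():
            edge_map.setdefault(str(e["crd_a"]), []).append(str(e["crd_b"]))
            edge_map.setdefault(str(e["crd_b"]), []).append(str(e["crd_a"]))
        for g1, v in gene_to_variant.items():
            for crd_a in gene_to_crds.get(g1, []):
                for crd_b in edge_map.get(crd_a, []):
                    for g2 in crd_to_genes.get(crd_b, []):
                        if g2 == g1:
                            continue
                        rows.append([v, g2, 2, f"{g1}>{crd_a}>{crd_b}"])
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if len(df) == 0:
        return df
    df = (
        df.groupby(["variant_id", "gene_id", "scenario"], as_index=False)
        .agg(chain=("chain", lambda s: ";".join(sorted(set(s)))))
    )
    return df.sort_values(["variant_id", "gene_id"]).reset_index(drop=True)


def test_candidates(
    candidates: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: QuantificationMatrix,
    fdr: float = 0.05,
    fdr_method: str = "storey",
    require_cross_chromosome: bool = True,
) -> pd.DataFrame:
    """Direct regression test of each nominated (variant, gene) pair.

    Each pair is tested once regardless of how many chains nominated
    it; FDR is controlled across the tested candidates of the given
    table (per scenario, matching how counts are reported upstream).
    Pairs are never added beyond the candidate set.
    """
    if len(candidates) == 0:
        return candidates.assign(p=[], q=[], significant=[])
    if list(genotypes.samples) != list(expression.samples):
        raise ValueError("genotypes and expression must share sample order")
    n = genotypes.n_samples
    vid_index = {str(v): i for i, v in enumerate(genotypes.ids)}
    gid_index = {str(g): i for i, g in enumerate(expression.ids)}
    orphans = [v for v in candidates["variant_id"].unique() if v not in vid_index]
    orphans += [g for g in candidates["gene_id"].unique() if g not in gid_index]
    if orphans:
        raise KeyError(f"candidate ids missing from inputs: {orphans[:5]}")
    rows = []
    for _, rec in candidates.iterrows():
        vi = vid_index[str(rec["variant_id"])]
        gi = gid_index[str(rec["gene_id"])]
        if require_cross_chromosome and str(genotypes.chrom[vi]) == str(expression.chrom[gi]):
            continue
        x = genotypes.dosages[vi]
        y = expression.values[gi]
        if x.std() == 0:
            logger.info("dropping zero-variance dosage %s", rec["variant_id"])
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = float(np.clip(r, -0.9999999999, 0.9999999999))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append({**rec.to_dict(), "r": r, "p": p})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    q, sig, _ = fdr_qvalue(out["p"].to_numpy(), method=fdr_method, level=fdr)
    out["q"] = q
    out["significant"] = sig
    return out.reset_index(drop=True)


def overlap_external(
    hits: pd.DataFrame,
    external: pd.DataFrame,
    ld: pd.DataFrame,
    r2_min: float = 0.9,
) -> pd.DataFrame:
    """Overlap discovered trans-eQTLs with an external (variant, gene) table.

    A hit overlaps when the external table lists the same gene with
    the same variant or with any variant in LD (r^2 > ``r2_min``).
    """
    ext_by_gene: dict[str, set[str]] = {}
    vcol, gcol = external.columns[0], external.columns[1]
    for _, rec in external.iterrows():
        ext_by_gene.setdefault(str(rec[gcol]), set()).add(str(rec[vcol]))
    rows = []
    for _, rec in hits.iterrows():
        gene = str(rec["gene_id"])
        variant = str(rec["variant_id"])
        ext_variants = ext_by_gene.get(gene, set())
        if not ext_variants:
            continue
        if variant in ext_variants:
            rows.append({"variant_id": variant, "gene_id": gene,
                         "external_variant": variant, "via": "identity"})
            continue
        proxies = ld_proxies(ld, variant, r2_min)
        hit_proxies = sorted(proxies & ext_variants)
        if hit_proxies:
            rows.append({"variant_id": variant, "gene_id": gene,
                         "external_variant": hit_proxies[0], "via": "ld_proxy"})
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "external_variant", "via"])
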