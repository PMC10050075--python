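"""Inter-chromosomal CRD-CRD networks and Trans Regulatory Hubs.

All pairs of CRDs on distinct autosomal chromosomes are tested for
correlated activity; edges surviving a 1% FDR cut form an undirected
graph whose communities (greedy modularity maximisation) are the
Trans Regulatory Hubs (TRHs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import fdr_qvalue
from .containers import ActivityMatrix

logger = logging.getLogger(__name__)

DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass
class TRH:
    """One trans regulatory hub: a community of trans-linked CRDs."""

    trh_id: str
    members: list[str]
    n_edges: int

    @property
    def size(self) -> int:
        return len(self.members)


def trans_scan(
    activities: ActivityMatrix,
    autosomes: tuple[str, ...] | None = DEFAULT_AUTOSOMES,
) -> pd.DataFrame:
    """Correlation tests for every inter-chromosomal CRD pair.

    Same-chromosome pairs are never tested. ``autosomes`` restricts
    the scan to an allowlist of chromosome names (None keeps all).
    The number of tests equals the sum of nA*nB over chromosome pairs.
    """
    n = len(activities.samples)
    if n < 10:
        logger.warning("trans_scan with %d samples: correlations are unstable", n)
    if autosomes is not None:
        keep = np.isin(activities.chrom.astype(str), autosomes)
    else:
        keep = np.ones(len(activities.ids), dtype=bool)
    ids = activities.ids[keep]
    chrom = activities.chrom[keep].astype(str)
    values = activities.values[keep]
    sd = values.std(axis=1)
    ok = sd > 0
    z = np.zeros_like(values)
    z[ok] = (values[ok] - values[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    rmat = z @ z.T / n
    rows = []
    order = np.argsort(ids.astype(str), kind="stable")
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            if chrom[i] == chrom[j] or not (ok[i] and ok[j]):
                continue
            r = float(np.clip(rmat[i, j], -0.9999999999, 0.9999999999))
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
            rows.append([str(ids[i]), str(ids[j]), r, p])
    return pd.DataFrame(rows, columns=["crd_a", "crd_b", "r", "p"])


def trans_significant(pvals: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Storey-FDR cut on a trans scan; edges stored once with a < b."""
    if len(pvals) == 0:
        return pvals.assign(q=[], significant=[])
    df = pvals.copy()
    a = df[["crd_a", "crd_b"]].min(axis=1)
    b = df[["crd_a", "crd_b"]].max(axis=1)
    df["crd_a"], df["crd_b"] = a, b
    df = df.drop_duplicates(subset=["crd_a", "crd_b"], keep="first")
    q, sig, _ = fdr_qvalue(df["p"].to_numpy(), method="storey", level=fdr)
    df["q"] = q
    df["significant"] = sig
    return df[df["significant"]].reset_index(drop=True)


def detect_trhs(edges: pd.DataFrame) -> list[TRH]:
    """Greedy-modularity communities of the significant-edge graph.

    The graph is unweighted (edge weights are kept in the table for an
    optional weighted mode but not used here); communities of size one
    are not reported as hubs.
    """
    import networkx as nx

    if len(edges) == 0:
        return []
    g = nx.Graph()
    g.add_edges_from(zip(edges["crd_a"].astype(str), edges["crd_b"].astype(str)))
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    trhs: list[TRH] = []
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
    k = 0
    for members in comms:
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        trhs.append(TRH(f"TRH{k:03d}", list(members), sub.number_of_edges()))
        k += 1
    return trhs


def network_summary(edges: pd.DataFrame, trhs: list[TRH]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node degree table and per-TRH size table."""
    from collections import Counter

    deg: Counter = Counter()
    for a, b in zip(edges.get("crd_a", []), edges.get("crd_b", [])):
        deg[str(a)] += 1
        deg[str(b)] += 1
    degree_df = pd.DataFrame(
        sorted(deg.items()), columns=["crd_id", "degree"]
    )
    trh_df = pd.DataFrame(
        [{"trh_id": t.trh_id, "size": t.size, "n_edges": t.n_edges} for t in trhs]
    )
    return degree_df, trh_df


def trh_membership_table(trhs: list[TRH]) -> pd.DataFrame:
    rows = [{"trh_id": t.trh_id, "crd_id": m} for t in trhs for m in t.members]
    return pd.DataFrame(rows, columns=["trh_id", "crd_id"])
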