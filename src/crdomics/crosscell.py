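"""Cell-type comparison: CRD sharing, fixed-peak-set replication and
Storey's pi1 replication statistic.

Sharing uses the 50% membership rule: a query CRD is shared with a
reference cell type when at least half of its member phenotypes also
belong to some CRD in the reference map. Membership is by consensus
phenotype id (peaks are called on a cross-cell consensus set); the
rule is directional, so both query->reference and reference->query are
reported by the caller when needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import crd_activity, storey_pi0
from .containers import CRD, ActivityMatrix, QuantificationMatrix

logger = logging.getLogger(__name__)


@dataclass
class SharingReport:
    query_cell: str
    reference_cell: str
    crd_class: str
    n_query_crds: int
    n_shared: int

    @property
    def fraction(self) -> float:
        return self.n_shared / self.n_query_crds


def crd_sharing(
    query_crds: list[CRD],
    ref_crds: list[CRD],
    min_fraction: float = 0.5,
    query_cell: str = "query",
    reference_cell: str = "reference",
) -> SharingReport:
    """Fraction of query CRDs shared with the reference map.

    A query CRD counts as shared when the fraction of its members that
    belong to any reference CRD is >= ``min_fraction`` (boundary
    inclusive: 2 of 4 members at the default 50% is shared).
    """
    if not query_crds:
        raise ValueError("empty query CRD list: sharing fraction undefined")
    ref_members: set[str] = set()
    for c in ref_crds:
        ref_members.update(c.members)
    n_shared = 0
    for c in query_crds:
        inside = sum(1 for m in c.members if m in ref_members)
        if inside / c.n_members >= min_fraction:
            n_shared += 1
    classes = {c.crd_class for c in query_crds}
    return SharingReport(
        query_cell=query_cell, reference_cell=reference_cell,
        crd_class=classes.pop() if len(classes) == 1 else "mixed",
        n_query_crds=len(query_crds), n_shared=n_shared,
    )


def fixed_peakset_activity(
    crds_ref: list[CRD], matrix_other_cell: QuantificationMatrix
) -> ActivityMatrix:
    """Activity of reference-defined member sets on another cell's data.

    Keeping the peak sets fixed across cell types lets associations be
    re-tested like-for-like; missing members raise with their ids.
    """
    known = set(map(str, matrix_other_cell.ids))
    missing = {c.crd_id: [m for m in c.members if m not in known] for c in crds_ref}
    missing = {k: v for k, v in missing.items() if v}
    if missing:
        raise KeyError(f"members not quantified in target matrix: {missing}")
    return crd_activity(matrix_other_cell, crds_ref)


def association_sharing(ref_assoc: pd.DataFrame, query_assoc: pd.DataFrame) -> float:
    """Fraction of reference-significant pairs also significant in query.

    Both tables must come from the same candidate universe at the same
    FDR level; pairs are (phenotype_id, feature_id).
    """
    def sig_pairs(df: pd.DataFrame) -> set[tuple[str, str]]:
        sel = df[df["significant"]]
        return set(zip(sel["phenotype_id"].astype(str), sel["feature_id"].astype(str)))

    ref = sig_pairs(ref_assoc)
    if not ref:
        raise ValueError("no significant associations in the reference cell")
    return len(ref & sig_pairs(query_assoc)) / len(ref)


def pi1(replication_pvals: np.ndarray) -> float:
    """Storey's estimated true-positive proportion among replications.

    ``pi1 = 1 - pi0`` over the p-values of reference-significant
    associations re-tested in the query cell, clipped to [0, 1].
    Below 20 p-values the estimate is unstable (warned, still
    computed; the pi0 estimator itself falls back to 1 under 50).
    """
    p = np.asarray(replication_pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("pi1 of an empty p-value list")
    if len(p) < 20:
        logger.warning("pi1 on %d p-values is unstable", len(p))
    return float(np.clip(1.0 - storey_pi0(p), 0.0, 1.0))
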