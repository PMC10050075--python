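"""Core in-memory containers shared across the pipeline.

Coordinate conventions
----------------------
All genomic intervals (peaks, CpG probes, genes, CRDs, fragments) are
0-based half-open, the BED convention. Variant positions are 1-based,
the VCF convention. Conversions happen only inside the readers/writers
in :mod:`crdomics.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_CLASSES = ("peak", "cpg", "gene")


class CoordinateError(ValueError):
    """Malformed or inconsistent genomic coordinates."""


@dataclass
class QuantificationMatrix:
    """Molecular phenotype quantifications: phenotypes x samples.

    Rows are ChIP-seq peaks, CpG probes or genes; columns are individuals.
    Rows are kept sorted by (chrom, start) within each chromosome; CpG
    probes are stored as width-1 intervals so downstream domain calling
    is agnostic to the phenotype class.
    """

    ids: np.ndarray          # str, shape (p,)
    chrom: np.ndarray        # str, shape (p,)
    start: np.ndarray        # int, 0-based, shape (p,)
    end: np.ndarray          # int, half-open, shape (p,)
    values: np.ndarray       # float, shape (p, n)
    samples: list[str]
    phenotype_class: str = "peak"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = list(self.samples)
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(f"unknown phenotype class {self.phenotype_class!r}")
        p = len(self.ids)
        if not (len(self.chrom) == len(self.start) == len(self.end) == p):
            raise ValueError("coordinate arrays disagree in length")
        if self.values.shape != (p, len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != ({p}, {len(self.samples)})"
            )
        if len(set(self.ids)) != p:
            dupes = pd.Series(self.ids).value_counts()
            dupes = list(dupes[dupes > 1].index[:5])
            raise ValueError(f"duplicate phenotype ids: {dupes}")
        if np.any(self.end <= self.start):
            bad = self.ids[self.end <= self.start][:5]
            raise CoordinateError(f"end <= start for {list(bad)}")
        self._sort()

    def _sort(self) -> None:
        order = np.lexsort((self.start, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            logger.warning("phenotype rows out of order; re-sorting by (chrom, start)")
            self.ids = self.ids[order]
            self.chrom = self.chrom[order]
            self.start = self.start[order]
            self.end = self.end[order]
            self.values = self.values[order]

    @property
    def n_phenotypes(self) -> int:
        return len(self.ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset_chrom(self, chrom: str) -> "QuantificationMatrix":
        mask = self.chrom == chrom
        return QuantificationMatrix(
            self.ids[mask], self.chrom[mask], self.start[mask], self.end[mask],
            self.values[mask], self.samples, self.phenotype_class,
        )

    def subset_ids(self, keep: np.ndarray) -> "QuantificationMatrix":
        keep_set = set(map(str, keep))
        mask = np.array([str(i) in keep_set for i in self.ids])
        return QuantificationMatrix(
            self.ids[mask], self.chrom[mask], self.start[mask], self.end[mask],
            self.values[mask], self.samples, self.phenotype_class,
        )

    def with_values(self, values: np.ndarray) -> "QuantificationMatrix":
        return replace(self, values=np.asarray(values, dtype=float))

    def row(self, phenotype_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.ids == phenotype_id)
        if len(idx) == 0:
            raise KeyError(phenotype_id)
        return self.values[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.samples)
        df.insert(0, "end", self.end)
        df.insert(0, "start", self.start)
        df.insert(0, "chrom", self.chrom)
        return df


@dataclass
class GenotypeMatrix:
    """Genotype dosages: variants x samples, values in [0, 2]."""

    ids: np.ndarray          # variant ids
    chrom: np.ndarray
    pos: np.ndarray          # int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray      # float, shape (v, n)
    samples: list[str]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = list(self.samples)
        if self.dosages.shape != (len(self.ids), len(self.samples)):
            raise ValueError("dosage shape inconsistent with ids/samples")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages outside [0, 2]")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise CoordinateError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=1) / 2.0
        return np.minimum(f, 1.0 - f)

    def row(self, variant_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.ids == variant_id)
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[idx[0]]


@dataclass
class CRD:
    """A called cis-regulatory domain.

    ``start``/``end`` span the min start / max end of the member
    phenotypes; ``mean_internal_abs_r`` summarises within-domain
    correlation over the pairs present in the correlation map.
    """

    crd_id: str
    chrom: str
    start: int
    end: int
    members: list[str]
    mean_internal_abs_r: float
    crd_class: str = "hCRD"   # hCRD or mCRD

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ActivityMatrix:
    """Per-CRD activity: each row is the mean of the member phenotype rows."""

    ids: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = list(self.samples)

    @property
    def n_crds(self) -> int:
        return len(self.ids)

    def row(self, crd_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.ids == crd_id)
        if len(idx) == 0:
            raise KeyError(crd_id)
        return self.values[idx[0]]


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside a simulated population."""

    block_members: dict[str, list[str]]       # block id -> peak ids
    block_qtls: dict[str, str]                # block id -> variant id
    gene_blocks: pd.DataFrame                 # gene_id, block_id, cis_effect
    trans_links: pd.DataFrame                 # block_a, block_b, coupling
    trh_labels: dict[str, int] = field(default_factory=dict)
    cpg_domains: pd.DataFrame | None = None   # domain_id, chrom, start, end, size_bp
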