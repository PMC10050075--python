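"""Readers and writers for the tabular formats the pipeline consumes.

Formats
-------
* Phenotype matrices: tab-separated ``#chr start end id <sample...>``
  (a BED-like dialect; coordinates 0-based half-open).
* Genotypes: VCF 4.x (GT or DS) or a dosage table with the same column
  layout as the phenotype BED (``#chr pos id ref alt <sample...>``).
* CRDs: BED6+ dialect with member-id list.
* TSS: 4-column TSV (gene_id, chrom, tss [1-based], strand).
* Interactions: TSV with two fragment triplets plus one or more score
  columns.

All text I/O is gzip-transparent (pandas infers compression from the
file name).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CRD, CoordinateError, GenotypeMatrix, QuantificationMatrix

logger = logging.getLogger(__name__)

_PHENO_COLS = ["#chr", "start", "end", "id"]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_phenotype_bed(path, phenotype_class: str = "peak") -> QuantificationMatrix:
    """Read a BED-like phenotype quantification matrix.

    The header row carries the sample ids after the four coordinate
    columns. Rows out of genomic order are re-sorted with a warning
    (the container enforces the invariant).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected chrom,start,end,id + >=1 sample column")
    first4 = list(df.columns[:4])
    if [c.lstrip("#").lower() for c in first4] != ["chr", "start", "end", "id"]:
        raise ValueError(f"{path}: unexpected header {first4}; need {_PHENO_COLS}")
    for col in df.columns[1:3]:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise CoordinateError(f"{path}: malformed coordinate in column {col}, line {line}")
    samples = list(df.columns[4:])
    return QuantificationMatrix(
        ids=df.iloc[:, 3].to_numpy(dtype=object),
        chrom=df.iloc[:, 0].to_numpy(dtype=object),
        start=df.iloc[:, 1].to_numpy(),
        end=df.iloc[:, 2].to_numpy(),
        values=df[samples].to_numpy(dtype=float),
        samples=samples,
        phenotype_class=phenotype_class,
    )


def write_phenotype_bed(matrix: QuantificationMatrix, path) -> None:
    coords = pd.DataFrame(
        {
            "#chr": matrix.chrom,
            "start": matrix.start,
            "end": matrix.end,
            "id": matrix.ids,
        }
    )
    values = pd.DataFrame(matrix.values, columns=matrix.samples)
    pd.concat([coords, values], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT or DS fields) or a dosage TSV.

    GT calls are converted to alt-allele dosage; missing calls are
    mean-imputed per variant (the downstream regression engine needs
    complete dosages) with the imputed count logged. Multiallelic VCF
    records are skipped with a warning.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path)
    return _read_dosage_table(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_imputed = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multiallelic record %s:%d", rec.CHROM, rec.POS)
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            gt = np.asarray(rec.gt_types, dtype=float)
            hom_alt = gt == 2
            unknown = gt == 3
            dose = gt.copy()
            dose[hom_alt] = 2.0
            dose[unknown] = np.nan
        miss = np.isnan(dose)
        if miss.any():
            if miss.all():
                logger.warning("skipping all-missing record %s:%d", rec.CHROM, rec.POS)
                continue
            dose[miss] = dose[~miss].mean()
            n_imputed += int(miss.sum())
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0]}"
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dose)
    if n_imputed:
        logger.info("mean-imputed %d missing genotype calls", n_imputed)
    if not ids:
        raise ValueError(f"{path}: no usable biallelic records")
    return GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosages=np.vstack(rows),
        samples=samples,
    )


def _read_dosage_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    expected = ["chr", "pos", "id", "ref", "alt"]
    got = [c.lstrip("#").lower() for c in df.columns[:5]]
    if got != expected:
        raise ValueError(f"{path}: dosage table needs columns {expected}, got {got}")
    samples = list(df.columns[5:])
    if not samples:
        raise ValueError(f"{path}: dosage table has no sample columns")
    return GenotypeMatrix(
        ids=df.iloc[:, 2].to_numpy(dtype=object),
        chrom=df.iloc[:, 0].to_numpy(dtype=object),
        pos=df.iloc[:, 1].to_numpy(),
        ref=df.iloc[:, 3].to_numpy(dtype=object),
        alt=df.iloc[:, 4].to_numpy(dtype=object),
        dosages=df[samples].to_numpy(dtype=float),
        samples=samples,
    )


def write_dosage_table(geno: GenotypeMatrix, path) -> None:
    coords = pd.DataFrame(
        {"#chr": geno.chrom, "pos": geno.pos, "id": geno.ids,
         "ref": geno.ref, "alt": geno.alt}
    )
    values = pd.DataFrame(geno.dosages, columns=geno.samples)
    pd.concat([coords, values], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


_CRD_HEADER = "#chr\tstart\tend\tcrd_id\tn_peaks\tmean_internal_abs_r\tclass\tmembers"


def write_crds(crds: list[CRD], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(_CRD_HEADER + "\n")
        for c in crds:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.crd_id}\t{c.n_members}\t"
                f"{c.mean_internal_abs_r:.17g}\t{c.crd_class}\t{','.join(c.members)}\n"
            )


def read_crds(path, matrix: QuantificationMatrix | None = None) -> list[CRD]:
    """Read a CRD BED file; with ``matrix`` given, member ids are validated."""
    known = set(map(str, matrix.ids)) if matrix is not None else None
    crds: list[CRD] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _CRD_HEADER:
            raise ValueError(f"{path}: unexpected CRD header {header!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            members = f[7].split(",") if f[7] else []
            if known is not None:
                orphans = [m for m in members if m not in known]
                if orphans:
                    raise ValueError(f"{path}: unknown member ids {orphans[:5]} in {f[3]}")
            crds.append(
                CRD(crd_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                    members=members, mean_internal_abs_r=float(f[5]), crd_class=f[6])
            )
    return crds


def read_tss(path) -> pd.DataFrame:
    """Gene TSS annotation: gene_id, chrom, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"gene_id", "chrom", "tss", "strand"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: TSS table needs columns {sorted(need)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id entries")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand must be + or -")
    return df


def write_tss(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    """Fragment-pair interaction scores (CHiCAGO-style).

    Columns: chromA,startA,endA,chromB,startB,endB then one or more
    score columns (one per cell type, or a single ``score``).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 3: str})
    need = ["chromA", "startA", "endA", "chromB", "startB", "endB"]
    got = [c.lstrip("#") for c in df.columns[:6]]
    if got != need:
        raise ValueError(f"{path}: interaction table needs columns {need}, got {got}")
    score_cols = df.columns[6:]
    if len(score_cols) == 0:
        raise ValueError(f"{path}: interaction table has no score column")
    if (df[score_cols].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative interaction scores")
    return df


def write_interactions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
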