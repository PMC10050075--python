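"""Config-driven end-to-end runs on synthetic or on-disk data.

A run is a plain staged execution (no DAG engine): each enabled stage
reads the artifacts of earlier stages from the output directory and
writes its own as TSV. Stage seeds are derived from the master seed
with a fixed per-stage offset, so toggling one stage never perturbs
another's randomness, and a rerun with the same config is
bit-identical (outputs carry no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, crd, io, normalize, simulate, trans
from .containers import ActivityMatrix, GenotypeMatrix, QuantificationMatrix

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "normalize", "call_crds", "activity",
    "map_cis_genes", "map_cis_qtls", "map_trans", "detect_trhs",
    "connectivity",
]

# artifact each stage needs -> stage that provides it
_REQUIRES = {
    "normalize": ["peaks.bed"],
    "call_crds": ["peaks.norm.bed"],
    "activity": ["crds.bed", "peaks.norm.bed"],
    "map_cis_genes": ["activity.bed", "genes.bed"],
    "map_cis_qtls": ["activity.bed", "genotypes.tsv"],
    "map_trans": ["activity.bed"],
    "detect_trhs": ["trans_edges.tsv"],
    "connectivity": ["crd_gene.tsv", "crds.bed", "genes.bed"],
}

_STAGE_SEED_OFFSET = {s: 101 + 13 * k for k, s in enumerate(STAGES)}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) * 1009 + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def subsample(obj, n: int, seed: int):
    """Uniform sample of ``n`` columns without replacement, seeded.

    The selection depends only on (seed, n_samples), so matrices and
    genotypes sharing a sample panel are co-subsampled consistently
    when given the same seed. ``n`` equal to the full panel returns
    the object unchanged (original order preserved).
    """
    total = len(obj.samples)
    if n > total:
        raise ValueError(f"cannot subsample {n} of {total} samples")
    if n == total:
        return obj
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    samples = [obj.samples[i] for i in idx]
    if isinstance(obj, GenotypeMatrix):
        return replace(obj, dosages=obj.dosages[:, idx], samples=samples)
    return replace(obj, values=obj.values[:, idx], samples=samples)


def connectivity_report(
    crd_gene: pd.DataFrame, crds: list, genes: QuantificationMatrix
) -> pd.DataFrame:
    """Fractions of CRDs (genes) with >=1 and >=2 associated genes (CRDs).

    Counts independent signals: conditional ranks count as extra
    associations of the same CRD.
    """
    sig = crd_gene[crd_gene["significant"]] if len(crd_gene) else crd_gene
    crd_counts: dict[str, set[str]] = {}
    gene_counts: dict[str, set[str]] = {}
    for _, rec in sig.iterrows():
        crd_counts.setdefault(str(rec["phenotype_id"]), set()).add(str(rec["feature_id"]))
        gene_counts.setdefault(str(rec["feature_id"]), set()).add(str(rec["phenotype_id"]))
    n_crds = len(crds)
    n_genes = genes.n_phenotypes
    rows = [
        {"entity": "crd", "at_least": 1,
         "fraction": sum(1 for s in crd_counts.values() if len(s) >= 1) / n_crds if n_crds else 0.0},
        {"entity": "crd", "at_least": 2,
         "fraction": sum(1 for s in crd_counts.values() if len(s) >= 2) / n_crds if n_crds else 0.0},
        {"entity": "gene", "at_least": 1,
         "fraction": sum(1 for s in gene_counts.values() if len(s) >= 1) / n_genes if n_genes else 0.0},
        {"entity": "gene", "at_least": 2,
         "fraction": sum(1 for s in gene_counts.values() if len(s) >= 2) / n_genes if n_genes else 0.0},
    ]
    return pd.DataFrame(rows)


def _default_sim_config(sim_cfg: dict, seed: int) -> simulate.SimulationConfig:
    rng = np.random.default_rng(seed)
    n_blocks = int(sim_cfg.get("n_blocks", 10))
    blocks = [
        (int(rng.integers(sim_cfg.get("min_block", 8), sim_cfg.get("max_block", 20) + 1)),
         float(sim_cfg.get("within_r", 0.7)))
        for _ in range(n_blocks)
    ]
    qtl_frac = float(sim_cfg.get("qtl_fraction", 0.6))
    n_qtl = int(round(qtl_frac * n_blocks))
    qtls = [(int(b), float(sim_cfg.get("qtl_h2", 0.2)))
            for b in rng.choice(n_blocks, size=n_qtl, replace=False)]
    genes = [(b, float(sim_cfg.get("gene_effect", 0.25))) for b in range(n_blocks)]
    genes += [(None, 0.0)] * int(sim_cfg.get("n_null_genes", n_blocks))
    blocks_per_chrom = int(sim_cfg.get("blocks_per_chrom", 2))
    trans_pairs = []
    coupling = float(sim_cfg.get("trans_coupling", 0.6))
    for k in range(int(sim_cfg.get("n_trans_links", 0))):
        a = (2 * k) % n_blocks
        b = (2 * k + blocks_per_chrom) % n_blocks  # guaranteed different chromosome
        if a // blocks_per_chrom != b // blocks_per_chrom:
            trans_pairs.append((a, b, coupling))
    return simulate.SimulationConfig(
        n_samples=int(sim_cfg.get("n_samples", 300)),
        blocks=blocks,
        blocks_per_chrom=blocks_per_chrom,
        background_peaks_per_chrom=int(sim_cfg.get("background_peaks_per_chrom", 40)),
        background_r=float(sim_cfg.get("background_r", 0.0)),
        qtls=qtls,
        genes=genes,
        trans=trans_pairs,
        seed=seed,
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the enabled stages in order; returns the artifact directory.

    Missing upstream artifacts for an enabled stage are detected
    before execution (dry-run validation) and raise immediately.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = config
    out = Path(out_dir or cfg.get("out_dir", "crdomics_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    stages = [s for s in STAGES if s in stages]

    # dry-run dependency validation
    will_exist = {p.name for p in out.iterdir()} if out.exists() else set()
    provides = {
        "simulate": ["peaks.bed", "genotypes.tsv", "genes.bed", "truth_blocks.tsv"],
        "normalize": ["peaks.norm.bed"],
        "call_crds": ["crds.bed"],
        "activity": ["activity.bed"],
        "map_cis_genes": ["crd_gene.tsv"],
        "map_cis_qtls": ["crd_qtl.tsv"],
        "map_trans": ["trans_edges.tsv"],
        "detect_trhs": ["trhs.tsv"],
        "connectivity": ["connectivity.tsv"],
    }
    planned = set(will_exist)
    for s in stages:
        missing = [a for a in _REQUIRES.get(s, []) if a not in planned]
        if missing:
            raise FileNotFoundError(f"stage {s!r} requires missing artifact(s) {missing}")
        planned.update(provides[s])

    meta = {"config_hash": _config_hash(cfg), "seed": seed, "stages": stages}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    assoc_cfg = cfg.get("association", {})
    n_perm = int(assoc_cfg.get("n_perm", 200))
    window_bp = int(assoc_cfg.get("window_bp", 1_000_000))
    fdr = float(assoc_cfg.get("fdr", 0.05))
    crd_cfg = cfg.get("crd", {})

    if "simulate" in stages:
        sim = _default_sim_config(cfg.get("simulate", {}), stage_seed(seed, "simulate"))
        peaks, geno, genes, cpgs, truth = simulate.simulate_population(sim)
        io.write_phenotype_bed(peaks, out / "peaks.bed")
        io.write_dosage_table(geno, out / "genotypes.tsv")
        io.write_phenotype_bed(genes, out / "genes.bed")
        if cpgs is not None:
            io.write_phenotype_bed(cpgs, out / "cpgs.bed")
        rows = [{"block_id": b, "peak_id": p} for b, ms in truth.block_members.items()
                for p in ms]
        pd.DataFrame(rows).to_csv(out / "truth_blocks.tsv", sep="\t", index=False)
        truth.gene_blocks.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        truth.trans_links.to_csv(out / "truth_trans.tsv", sep="\t", index=False)

    if "normalize" in stages:
        peaks = io.read_phenotype_bed(out / "peaks.bed")
        n_pcs = int(cfg.get("normalize", {}).get("n_pcs", 0))
        cov = normalize.compute_pcs(peaks, n_pcs) if n_pcs > 0 else None
        normed = normalize.rank_normal(normalize.residualize(peaks, cov))
        io.write_phenotype_bed(normed, out / "peaks.norm.bed")

    if "call_crds" in stages:
        normed = io.read_phenotype_bed(out / "peaks.norm.bed")
        crds = crd.call_crds_genomewide(
            normed,
            window=int(crd_cfg.get("window", crd.DEFAULT_WINDOW)),
            factor=float(crd_cfg.get("factor", 2.0)),
            pair_alpha=crd_cfg.get("pair_alpha", 0.01),
        )
        io.write_crds(crds, out / "crds.bed")

    if "activity" in stages:
        normed = io.read_phenotype_bed(out / "peaks.norm.bed")
        crds = io.read_crds(out / "crds.bed", normed)
        act = association.crd_activity(normed, crds)
        io.write_phenotype_bed(
            QuantificationMatrix(act.ids, act.chrom, act.start, act.end,
                                 act.values, act.samples, "peak"),
            out / "activity.bed",
        )

    def _load_activity() -> ActivityMatrix:
        m = io.read_phenotype_bed(out / "activity.bed")
        return ActivityMatrix(m.ids, m.chrom, m.start, m.end, m.values, m.samples)

    if "map_cis_genes" in stages:
        act = _load_activity()
        genes = io.read_phenotype_bed(out / "genes.bed", "gene")
        feats = association.CisFeatures.from_expression(genes)
        res = association.map_cis(act, feats, window_bp=window_bp, n_perm=n_perm,
                                  fdr=fdr, seed=stage_seed(seed, "map_cis_genes"))
        res.to_csv(out / "crd_gene.tsv", sep="\t", index=False)

    if "map_cis_qtls" in stages:
        act = _load_activity()
        geno = io.read_genotypes(out / "genotypes.tsv")
        res = association.map_cis(act, geno, window_bp=window_bp, n_perm=n_perm,
                                  fdr=fdr, seed=stage_seed(seed, "map_cis_qtls"))
        res.to_csv(out / "crd_qtl.tsv", sep="\t", index=False)

    if "map_trans" in stages:
        act = _load_activity()
        scan = trans.trans_scan(act, autosomes=None)
        scan.to_csv(out / "trans_scan.tsv", sep="\t", index=False)
        edges = trans.trans_significant(scan, fdr=float(cfg.get("trans", {}).get("fdr", 0.01)))
        edges.to_csv(out / "trans_edges.tsv", sep="\t", index=False)

    if "detect_trhs" in stages:
        edges = pd.read_csv(out / "trans_edges.tsv", sep="\t")
        trhs = trans.detect_trhs(edges)
        trans.trh_membership_table(trhs).to_csv(out / "trhs.tsv", sep="\t", index=False)

    if "connectivity" in stages:
        crd_gene = pd.read_csv(out / "crd_gene.tsv", sep="\t")
        normed = io.read_phenotype_bed(out / "peaks.norm.bed")
        crds = io.read_crds(out / "crds.bed", normed)
        genes = io.read_phenotype_bed(out / "genes.bed", "gene")
        connectivity_report(crd_gene, crds, genes).to_csv(
            out / "connectivity.tsv", sep="\t", index=False
        )

    return out
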