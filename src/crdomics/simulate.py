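"""Synthetic population multi-omics with planted regulatory structure.

The generator emits the same objects the real pipeline consumes — peak,
gene and CpG quantification matrices plus genotype dosages — together
with a :class:`~crdomics.containers.TruthTable` recording what was
planted, so every downstream stage (domain calling, QTL mapping, trans
networks, trans-eQTL chaining) can be scored against ground truth.

Statistical model
-----------------
* Each planted block of peaks shares a latent Gaussian factor; a peak
  value is ``a*B + b*g + c*eps`` with weights chosen so the expected
  within-block pairwise correlation equals the target ``r`` and the
  cross-block correlation equals ``background_r``.
* A planted QTL contributes ``sqrt(h2) * z`` to the block factor, where
  ``z`` is the standardised dosage and ``h2`` the configured fraction of
  block-activity variance.
* A trans link ``(A, B, c)`` propagates block A's full factor
  (including its genetic component) into block B:
  ``g_B = c g_A + sqrt(1-c^2) e_B``, giving correlation ``c`` between
  the block factors and letting a QTL of block A reach block B and its
  target genes — the causal topology trans-eQTL chaining assumes.
* Genes driven by a block receive ``sqrt(v)`` of the block factor.
* CpG probes are grouped into methylation domains whose genomic sizes
  are drawn from a two-component Gaussian mixture on log10(bp),
  emulating the bimodal size distribution of methylation domains
  (small promoter-scale domains around 300 bp, large domains around
  40 kb).

Genotypes are binomial(2, f) with f uniform in the MAF range; there is
no LD by default, and :func:`simulate_ld_genotypes` provides a simple
block-LD generator for proxy-lookup tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, QuantificationMatrix, TruthTable

PEAK_WIDTH = 500


@dataclass
class SimulationConfig:
    """Parameters of one simulated population.

    ``blocks`` lists ``(n_peaks, within_r)`` per planted block; blocks
    are laid out ``blocks_per_chrom`` to a synthetic chromosome with
    ``background_peaks_per_chrom`` uncorrelated peaks interleaved
    between and around them, so the correlation landscape resembles a
    real chromosome: islands of high correlation in a sea of noise.
    """

    n_samples: int = 200
    blocks: list[tuple[int, float]] = field(default_factory=list)
    blocks_per_chrom: int = 2
    background_peaks_per_chrom: int = 40
    background_r: float = 0.0
    qtls: list[tuple[int, float]] = field(default_factory=list)       # (block, h2)
    genes: list[tuple[int | None, float]] = field(default_factory=list)  # (block|None, v)
    trans: list[tuple[int, int, float]] = field(default_factory=list)  # (a, b, coupling)
    n_cpg_domains: int = 0
    cpgs_per_domain: int = 6
    cpg_within_r: float = 0.7
    methyl_size_mix: tuple[float, float, float, float, float] = (2.48, 0.25, 4.60, 0.25, 0.5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    background_variants_per_chrom: int = 10
    peak_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for b, (k, r) in enumerate(self.blocks):
            if not -1.0 < r < 1.0:
                raise ValueError(f"block {b}: correlation target {r} outside (-1, 1)")
            if k >= 2 and r < -1.0 / (k - 1):
                raise ValueError(f"block {b}: r={r} implies a non-PSD covariance for {k} peaks")
            if r < self.background_r:
                raise ValueError(f"block {b}: within-block r below background_r")
        for b, h2 in self.qtls:
            if not 0.0 <= h2 < 1.0:
                raise ValueError(f"QTL variance fraction {h2} outside [0, 1)")
            self._check_block(b)
        for g, (b, v) in enumerate(self.genes):
            if not 0.0 <= v < 1.0:
                raise ValueError(f"gene {g}: cis effect {v} outside [0, 1)")
            if b is not None:
                self._check_block(b)
        coupling_sum = np.zeros(len(self.blocks))
        for a, b, c in self.trans:
            self._check_block(a)
            self._check_block(b)
            if a == b:
                raise ValueError(f"trans link ({a}, {b}) couples a block to itself")
            if not 0.0 <= c < 1.0:
                raise ValueError(f"trans coupling {c} outside [0, 1)")
            coupling_sum[b] += c * c  # b is the target of the directed link
        if (coupling_sum >= 1.0).any():
            bad = int(np.argmax(coupling_sum >= 1.0))
            raise ValueError(f"block {bad}: incoming couplings imply variance >= 1 (non-PSD)")
        mu_s, sd_s, mu_l, sd_l, w = self.methyl_size_mix
        if sd_s <= 0 or sd_l <= 0 or not 0.0 < w < 1.0:
            raise ValueError("invalid methylation size mixture")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("MAF range must satisfy 0 < lo <= hi <= 0.5")

    def _check_block(self, b: int) -> None:
        if not 0 <= b < len(self.blocks):
            raise ValueError(f"block index {b} out of range")

    @property
    def n_chromosomes(self) -> int:
        n = max(1, -(-len(self.blocks) // self.blocks_per_chrom))
        return n

    def block_chrom(self, b: int) -> str:
        return str(1 + b // self.blocks_per_chrom)


def _block_layout(config: SimulationConfig):
    """Assign peaks to chromosomes: background runs flank each block."""
    rows = []  # (chrom, start, end, block_index or -1)
    n_chrom = config.n_chromosomes
    for ci in range(n_chrom):
        chrom = str(ci + 1)
        block_ids = [
            b for b in range(len(config.blocks)) if config.block_chrom(b) == chrom
        ]
        n_slots = len(block_ids) + 1
        bg_per_slot = [
            config.background_peaks_per_chrom // n_slots
            + (1 if s < config.background_peaks_per_chrom % n_slots else 0)
            for s in range(n_slots)
        ]
        pos = 0
        for s in range(n_slots):
            for _ in range(bg_per_slot[s]):
                rows.append((chrom, pos, pos + PEAK_WIDTH, -1))
                pos += config.peak_spacing
            if s < len(block_ids):
                b = block_ids[s]
                for _ in range(config.blocks[b][0]):
                    rows.append((chrom, pos, pos + PEAK_WIDTH, b))
                    pos += config.peak_spacing
    return rows


def simulate_population(
    config: SimulationConfig,
) -> tuple[QuantificationMatrix, GenotypeMatrix, QuantificationMatrix,
           QuantificationMatrix | None, TruthTable]:
    """Generate (peaks, genotypes, genes, cpgs, truth) for one population.

    Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    n_blocks = len(config.blocks)

    # --- latent structure -------------------------------------------------
    shared_bg = rng.standard_normal(n) if config.background_r > 0 else np.zeros(n)
    idio = rng.standard_normal((n_blocks, n))
    qtl_by_block = {b: h2 for b, h2 in config.qtls}

    # genotypes: one tag variant per QTL'd block + background variants
    geno = _simulate_genotypes(config, rng)
    z_std = (geno.dosages - geno.dosages.mean(axis=1, keepdims=True)) / geno.dosages.std(
        axis=1, keepdims=True
    )
    qtl_variant_of_block: dict[int, int] = {}
    for vi, vid in enumerate(geno.ids):
        if str(vid).startswith("qtl_b"):
            qtl_variant_of_block[int(str(vid).split("qtl_b")[1])] = vi

    factors = np.zeros((n_blocks, n))  # full block factor incl. genetics
    for blk in range(n_blocks):
        h2 = qtl_by_block.get(blk, 0.0)
        g = idio[blk]
        if h2 > 0:
            z = z_std[qtl_variant_of_block[blk]]
            g = np.sqrt(h2) * z + np.sqrt(1.0 - h2) * g
        factors[blk] = g
    # directed trans propagation: the source's full factor (genetics
    # included) feeds the target, in the order the links are listed
    incoming: dict[int, list[tuple[int, float]]] = {}
    for a, b, c in config.trans:
        incoming.setdefault(b, []).append((a, c))
    for b, links in incoming.items():
        total_c2 = sum(c * c for _, c in links)
        g = np.sqrt(1.0 - total_c2) * factors[b]
        for a, c in links:
            g = g + c * factors[a]
        factors[b] = g

    # --- peaks ------------------------------------------------------------
    layout = _block_layout(config)
    p = len(layout)
    a_bg = np.sqrt(config.background_r)
    values = np.empty((p, n))
    ids, chroms, starts, ends = [], [], [], []
    block_members: dict[str, list[str]] = {f"B{b}": [] for b in range(n_blocks)}
    for i, (chrom, s, e, blk) in enumerate(layout):
        pid = f"pk_{chrom}_{i:05d}"
        ids.append(pid)
        chroms.append(chrom)
        starts.append(s)
        ends.append(e)
        eps = rng.standard_normal(n)
        if blk >= 0:
            r = config.blocks[blk][1]
            values[i] = (
                a_bg * shared_bg
                + np.sqrt(max(r - config.background_r, 0.0)) * factors[blk]
                + np.sqrt(1.0 - r) * eps
            )
            block_members[f"B{blk}"].append(pid)
        else:
            values[i] = a_bg * shared_bg + np.sqrt(1.0 - config.background_r) * eps
    peaks = QuantificationMatrix(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(starts), np.array(ends), values, samples, "peak",
    )

    # --- genes ------------------------------------------------------------
    genes = _simulate_genes(config, rng, factors, samples, peaks, block_members)
    gene_rows = []
    for gi, (blk, v) in enumerate(config.genes):
        gene_rows.append({"gene_id": f"g_{gi:04d}", "block_id": f"B{blk}" if blk is not None else "",
                          "cis_effect": v})
    gene_blocks = pd.DataFrame(gene_rows, columns=["gene_id", "block_id", "cis_effect"])

    # --- methylation ------------------------------------------------------
    cpgs, cpg_domains = _simulate_cpgs(config, rng, samples)

    trans_links = pd.DataFrame(
        [{"block_a": f"B{a}", "block_b": f"B{b}", "coupling": c} for a, b, c in config.trans],
        columns=["block_a", "block_b", "coupling"],
    )
    trh_labels = _coupling_communities(config)
    truth = TruthTable(
        block_members=block_members,
        block_qtls={f"B{b}": f"qtl_b{b}" for b, _ in config.qtls},
        gene_blocks=gene_blocks,
        trans_links=trans_links,
        trh_labels=trh_labels,
        cpg_domains=cpg_domains,
    )
    return peaks, geno, genes, cpgs, truth


def _simulate_genotypes(config: SimulationConfig, rng) -> GenotypeMatrix:
    lo, hi = config.maf_range
    rows, ids, chroms, poss = [], [], [], []
    layout = _block_layout(config)
    spans: dict[int, tuple[str, int, int]] = {}
    for chrom, s, e, blk in layout:
        if blk >= 0:
            c0, s0, e0 = spans.get(blk, (chrom, s, e))
            spans[blk] = (chrom, min(s0, s), max(e0, e))
    chrom_extent: dict[str, int] = {}
    for chrom, s, e, _ in layout:
        chrom_extent[chrom] = max(chrom_extent.get(chrom, 0), e)

    def draw(n_samples: int) -> np.ndarray:
        # reject monomorphic draws so dosages are always testable
        while True:
            f = rng.uniform(lo, hi)
            d = rng.binomial(2, f, size=n_samples).astype(float)
            if d.std() > 0:
                return d

    qtl_blocks = [b for b, _ in config.qtls]
    for b in qtl_blocks:
        chrom, s, e = spans[b]
        ids.append(f"qtl_b{b}")
        chroms.append(chrom)
        poss.append((s + e) // 2 + 1)
        rows.append(draw(config.n_samples))
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        extent = chrom_extent.get(chrom, 10 * config.peak_spacing)
        for k in range(config.background_variants_per_chrom):
            pos = int((k + 0.5) / config.background_variants_per_chrom * extent) + 1
            ids.append(f"var_{chrom}_{k:04d}")
            chroms.append(chrom)
            poss.append(pos)
            rows.append(draw(config.n_samples))
    order = np.lexsort((np.array(poss), np.array(chroms, dtype=object).astype(str)))
    # nudge position collisions apart so the VCF-style invariant holds
    poss = np.array(poss)[order]
    chroms_a = np.array(chroms, dtype=object)[order]
    for i in range(1, len(poss)):
        if chroms_a[i] == chroms_a[i - 1] and poss[i] <= poss[i - 1]:
            poss[i] = poss[i - 1] + 1
    ids_a = np.array(ids, dtype=object)[order]
    dos = np.vstack(rows)[order]
    return GenotypeMatrix(
        ids=ids_a, chrom=chroms_a, pos=poss,
        ref=np.array(["A"] * len(ids_a), dtype=object),
        alt=np.array(["G"] * len(ids_a), dtype=object),
        dosages=dos, samples=[f"S{i:04d}" for i in range(config.n_samples)],
    )


def _simulate_genes(config, rng, factors, samples, peaks, block_members):
    n = config.n_samples
    rows, ids, chroms, starts, ends = [], [], [], [], []
    for gi, (blk, v) in enumerate(config.genes):
        noise = rng.standard_normal(n)
        if blk is not None and v > 0:
            expr = np.sqrt(v) * factors[blk] + np.sqrt(1.0 - v) * noise
        else:
            expr = noise
        if blk is not None:
            members = block_members[f"B{blk}"]
            idx = np.flatnonzero(np.isin(peaks.ids, members))
            chrom = str(peaks.chrom[idx[0]])
            tss0 = int(peaks.end[idx].max()) + 50_000 + 1_000 * gi
        else:
            chrom = str(1 + gi % config.n_chromosomes)
            tss0 = 5_000_000 + 10_000 * gi
        ids.append(f"g_{gi:04d}")
        chroms.append(chrom)
        starts.append(tss0)
        ends.append(tss0 + 1_000)
        rows.append(expr)
    if not rows:
        rows = np.empty((0, n))
    ids_a = np.array(ids, dtype=object)
    chroms_a = np.array(chroms, dtype=object)
    starts_a = np.array(starts, dtype=np.int64)
    ends_a = np.array(ends, dtype=np.int64)
    values_a = np.asarray(rows, dtype=float).reshape(len(ids), n)
    order = np.lexsort((starts_a, chroms_a.astype(str)))
    return QuantificationMatrix(
        ids_a[order], chroms_a[order], starts_a[order], ends_a[order],
        values_a[order], samples, "gene",
    )


def _simulate_cpgs(config, rng, samples):
    if config.n_cpg_domains == 0:
        return None, None
    mu_s, sd_s, mu_l, sd_l, w = config.methyl_size_mix
    n = config.n_samples
    ids, chroms, starts, ends, rows, dom_rows = [], [], [], [], [], []
    pos = 50_000_000  # far from the peak region of each chromosome
    for d in range(config.n_cpg_domains):
        chrom = str(1 + d % config.n_chromosomes)
        small = rng.random() < w
        size = int(round(10 ** rng.normal(mu_s if small else mu_l, sd_s if small else sd_l)))
        size = max(size, config.cpgs_per_domain)
        g = rng.standard_normal(n)
        offsets = np.sort(
            rng.choice(size, size=min(config.cpgs_per_domain, size), replace=False)
        )
        for j, off in enumerate(offsets):
            cid = f"cpg_d{d:04d}_{j}"
            ids.append(cid)
            chroms.append(chrom)
            starts.append(pos + int(off))
            ends.append(pos + int(off) + 1)
            eps = rng.standard_normal(n)
            r = config.cpg_within_r
            rows.append(np.sqrt(r) * g + np.sqrt(1 - r) * eps)
        dom_rows.append({"domain_id": f"D{d}", "chrom": chrom, "start": pos,
                         "end": pos + size, "size_bp": size})
        pos += size + 100_000
    cpgs = QuantificationMatrix(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(starts), np.array(ends), np.vstack(rows), samples, "cpg",
    )
    return cpgs, pd.DataFrame(dom_rows)


def _coupling_communities(config: SimulationConfig) -> dict[str, int]:
    import networkx as nx

    g = nx.Graph()
    for a, b, _ in config.trans:
        g.add_edge(f"B{a}", f"B{b}")
    labels: dict[str, int] = {}
    for k, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        for node in comp:
            labels[node] = k
    return labels


def simulate_interactions(
    truth: TruthTable,
    peaks: QuantificationMatrix,
    genes: QuantificationMatrix,
    enrichment: float = 10.0,
    noise_rate: float = 0.05,
    n_random_pairs: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Fragment-pair score table enriched at planted gene-block links.

    A fragment pair spanning a planted gene-block link receives a score
    >= 5 with probability ``min(1, enrichment * noise_rate)``; random
    same-chromosome pairs with probability ``noise_rate``.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []

    def frag(chrom, start, end):
        return str(chrom), int(start), int(end)

    spans = planted_block_spans(truth, peaks)
    for _, rec in truth.gene_blocks.iterrows():
        if not rec["block_id"]:
            continue
        gi = np.flatnonzero(genes.ids == rec["gene_id"])
        if len(gi) == 0:
            continue
        gi = gi[0]
        chrom, bs, be = spans[rec["block_id"]]
        supported = rng.random() < min(1.0, enrichment * noise_rate)
        score = rng.uniform(5.0, 15.0) if supported else rng.uniform(0.0, 5.0)
        fa = frag(genes.chrom[gi], genes.start[gi], genes.end[gi])
        fb = frag(chrom, bs, be)
        rows.append((*fa, *fb, score))
    for _ in range(n_random_pairs):
        chrom = str(rng.choice(peaks.chromosomes()))
        idx = np.flatnonzero(peaks.chrom == chrom)
        i, j = rng.choice(idx, size=2, replace=False)
        supported = rng.random() < noise_rate
        score = rng.uniform(5.0, 15.0) if supported else rng.uniform(0.0, 5.0)
        rows.append((chrom, int(peaks.start[i]), int(peaks.end[i]),
                     chrom, int(peaks.start[j]), int(peaks.end[j]), score))
    return pd.DataFrame(
        rows, columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "score"]
    )


def planted_block_spans(
    truth: TruthTable, peaks: QuantificationMatrix
) -> dict[str, tuple[str, int, int]]:
    """Genomic span (chrom, start, end) of each planted block."""
    spans = {}
    for block_id, members in truth.block_members.items():
        idx = np.flatnonzero(np.isin(peaks.ids, members))
        if len(idx) == 0:
            continue
        spans[block_id] = (
            str(peaks.chrom[idx[0]]), int(peaks.start[idx].min()), int(peaks.end[idx].max())
        )
    return spans


def simulate_gwas(
    genotypes: GenotypeMatrix,
    causal: list[str],
    seed: int = 0,
    effect: float = 0.2,
) -> pd.DataFrame:
    """Single-trait GWAS summary statistics over the given genotypes.

    A latent trait receives ``effect`` (on the correlation scale) from
    each standardised causal dosage; every variant is then tested
    against the trait, so LD proxies of causal variants pick up signal
    through their dosage correlation and all other variants yield
    uniform p-values.
    """
    from scipy import stats

    causal_set = set(causal)
    missing = causal_set - set(map(str, genotypes.ids))
    if missing:
        raise ValueError(f"causal variants absent from genotypes: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    y = rng.standard_normal(n)
    sd = genotypes.dosages.std(axis=1)
    ok = sd > 0
    z = np.zeros_like(genotypes.dosages)
    z[ok] = (genotypes.dosages[ok] - genotypes.dosages[ok].mean(axis=1, keepdims=True)) / sd[
        ok, None
    ]
    # beta chosen so a single causal variant has corr(y, z) = effect
    beta = effect / np.sqrt(max(1e-12, 1.0 - effect**2))
    for vid in causal:
        vi = int(np.flatnonzero(genotypes.ids == vid)[0])
        y = y + beta * z[vi]
    y = (y - y.mean()) / y.std()
    r = z @ y / n
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[~ok] = 1.0
    return pd.DataFrame({"variant_id": genotypes.ids, "p": p})


def simulate_ld_genotypes(
    n_variants: int,
    n_samples: int,
    block_size: int = 5,
    rho: float = 0.95,
    maf_range: tuple[float, float] = (0.1, 0.5),
    chrom: str = "1",
    spacing: int = 50_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Block-LD dosages via a latent-Gaussian threshold model.

    Variants within a block share AR(1)-correlated latents per
    haplotype, so neighbouring dosages are strongly correlated (r2
    close to ``rho**2`` for adjacent pairs), which is enough to
    exercise LD-proxy lookups.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_variants)
    from scipy import stats

    thresh = stats.norm.ppf(1 - freqs)
    dosages = np.zeros((n_variants, n_samples))
    for hap in range(2):
        latent = np.zeros((n_variants, n_samples))
        for v in range(n_variants):
            innov = rng.standard_normal(n_samples)
            if v % block_size == 0:
                latent[v] = innov
            else:
                latent[v] = rho * latent[v - 1] + np.sqrt(1 - rho**2) * innov
        dosages += (latent > thresh[:, None]).astype(float)
    return GenotypeMatrix(
        ids=np.array([f"ld_{i:04d}" for i in range(n_variants)], dtype=object),
        chrom=np.array([chrom] * n_variants, dtype=object),
        pos=np.arange(1, n_variants + 1) * spacing,
        ref=np.array(["A"] * n_variants, dtype=object),
        alt=np.array(["G"] * n_variants, dtype=object),
        dosages=dosages,
        samples=[f"S{i:04d}" for i in range(n_samples)],
    )
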