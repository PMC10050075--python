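# crdomics

Cis-regulatory domains (CRDs) from population epigenomes: domain
calling, activity quantification, cis and trans association mapping,
and trans-eQTL discovery through chromatin networks.

## The problem

Regulatory elements — enhancers and promoters marked by histone
modifications (H3K4me1, H3K27ac) or CpG methylation — do not act in
isolation. Across a population of individuals, nearby chromatin peaks
show coordinated activity: groups of peaks rise and fall together.
These groups, *cis-regulatory domains*, are the functional units this
package identifies and analyses. Starting from standard quantification
matrices (peaks/CpGs/genes × individuals) and genotype dosages, the
pipeline:

1. **calls CRDs** per chromosome by hierarchical clustering of
   inter-individual peak correlations and a criteria-based tree cut;
2. **quantifies CRD activity** as the per-individual mean of member
   peaks;
3. **maps cis associations** — CRD–gene links and CRD-QTLs within
   ±1 Mb — with permutation-based multiple-testing control
   (1000 phenotype shuffles per scan) and Storey FDR across
   phenotypes, plus a forward–backward conditional scan for multiple
   independent signals;
4. **builds trans networks** from all inter-chromosomal CRD pairs
   (1% FDR) and detects *Trans Regulatory Hubs* by greedy modularity;
5. **compares cell types** (50% membership sharing rule, fixed-peak-set
   replication, Storey's π₁);
6. **chains associations into trans-eQTL candidates**
   (variant → CRD → trans CRD → gene), testing only the nominated
   pairs — a reduction of the cross-chromosome search space by orders
   of magnitude;
7. **integrates external evidence**: promoter-capture Hi-C support
   fractions, TFBS Fisher enrichment, local LD (r²), GWAS overlap and
   the genomic inflation factor λ.

Everything is testable without controlled-access data: the
`simulate` module generates populations with planted blocks, QTLs,
cis genes, trans couplings and bimodal methylation-domain sizes, plus
the truth tables to score recovery.

## The core model

For phenotypes on one chromosome, Pearson correlations are computed
for all pairs within a 250-phenotype sliding window on the corrected,
rank-normalised matrix. Average-linkage clustering on d = 1 − |r|
yields a binary tree; a root-down traversal emits the first node
satisfying, with factor 2:

- **(i) high internal correlation** — mean |r| over within-node pairs
  ≥ 2 × the chromosome-wide mean;
- **(ii) well-defined boundaries** — mean |r| of pairs involving the
  node's genomically first or last peak ≥ 2 × the analogous
  chromosome-level value;
- **(iii) two regulatory regions** — at least two members with
  non-overlapping genomic intervals.

Pairs that are not significantly correlated (Bonferroni within
chromosome) contribute zero correlation mass to these sums, and the
node's two subtrees must themselves be correlated (a dendrogram cut at
a correlation height), so chance correlations never nominate domains —
a fully independent matrix yields zero CRDs. Methylation CRDs are
additionally size-filtered by a two-component Gaussian mixture on
log₁₀(bp): the small component (~300 bp, probes within one regulatory
region) is removed at its 0.95 quantile, keeping genuine multi-region
domains (~40 kb).

Associations are simple linear regressions; the best hit per phenotype
is calibrated as adjusted p = (1 + #{permutation best p ≤ observed}) /
(1 + N), and significance is controlled with Storey q-values
(π₀ from a cubic smoother over the λ grid 0.05…0.95).

## Worked example

```python
import crdomics as cx

cfg = cx.SimulationConfig(
    n_samples=300,
    blocks=[(12, 0.7), (10, 0.7), (15, 0.7), (9, 0.7)],
    blocks_per_chrom=2,
    background_peaks_per_chrom=40,
    qtls=[(0, 0.2), (2, 0.2)],          # QTLs explain 20% of activity variance
    genes=[(0, 0.25), (2, 0.25), (None, 0.0)],
    trans=[(0, 2, 0.6)],                # blocks 0 and 2 coupled at r = 0.6
    seed=7,
)
peaks, genotypes, genes, _, truth = cx.simulate_population(cfg)

normed = cx.rank_normal(peaks)
crds = cx.call_crds_genomewide(normed)
print(f"called {len(crds)} CRDs from {peaks.n_phenotypes} peaks")
for c in crds:
    print(f"  {c.crd_id}: chr{c.chrom}:{c.start}-{c.end}, "
          f"{c.n_members} peaks, mean |r| = {c.mean_internal_abs_r:.2f}")

activity = cx.crd_activity(normed, crds)
qtls = cx.map_cis(activity, genotypes, n_perm=1000, fdr=0.05, seed=1)
print(qtls[qtls.significant][["phenotype_id", "feature_id", "slope",
                              "adjusted_p", "q_value"]].to_string(index=False))

edges = cx.trans_significant(cx.trans_scan(activity, autosomes=None), fdr=0.01)
print(f"{len(edges)} trans edge(s):",
      [f"{a}~{b} (r={r:.2f})" for a, b, r in zip(edges.crd_a, edges.crd_b, edges.r)])
```

prints

```
called 4 CRDs from 126 peaks
  crd_1_0000: chr1:140000-250500, 12 peaks, mean |r| = 0.68
  crd_1_0001: chr1:390000-480500, 10 peaks, mean |r| = 0.67
  crd_2_0000: chr2:140000-280500, 15 peaks, mean |r| = 0.65
  crd_2_0001: chr2:420000-500500, 9 peaks, mean |r| = 0.71
phenotype_id feature_id    slope  adjusted_p  q_value
  crd_1_0000     qtl_b0 0.609369    0.000999 0.001998
  crd_2_0000     qtl_b2 0.902915    0.000999 0.001998
1 trans edge(s): ['crd_1_0000~crd_2_0000 (r=0.53)']
```

All four planted blocks are recovered with their exact member sets;
the two planted QTLs reach the permutation-resolution floor
(1/1001 ≈ 0.000999) and pass 5% FDR; the planted trans coupling is the
single 1% FDR inter-chromosomal edge, at its expected attenuated
correlation (0.6 at the latent level, ≈0.53 on measured activities).

A command-line interface mirrors the library
(`crdomics simulate|normalize|call-crds|map-cis|coexpress|map-trans|detect-trhs|run`);
`crdomics run --config run.yaml` executes the staged pipeline with
per-stage seeds and byte-reproducible outputs.

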