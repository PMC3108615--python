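# ridgescan

Detection of chromosomal domains of increased and decreased gene
expression — RIDGEs (Regions of IncreaseD Gene Expression) and
anti-RIDGEs — from gene-ordered transcriptome maps, for bulk expression
studies with a small tissue panel.

Eukaryotic genes cluster along chromosomes into highly expressed and
lowly expressed neighbourhoods, suggesting a layer of transcriptional
regulation operating at the level of the chromosomal domain rather than
the individual promoter. `ridgescan` implements the standard
moving-median mapping approach for finding such domains, designed around
a five-tissue bovine brain/pituitary panel (anterior pituitary, amygdala,
hippocampus, dorsal and ventral hypothalamus) but applicable to any
gene × tissue log-intensity matrix plus a gene annotation.

## Method

Given per-gene log2 expression values `x_g` and the gene order along each
chromosome:

1. **Transcriptome map** — at every gene position compute the moving
   median over a window of `w = 39` gene positions (the gene and 19
   flanking genes on either side); near chromosome ends the window
   half-width shrinks symmetrically (the behaviour of R's
   `runmed(..., endrule="med")`).
2. **Region calling** — with `m` the genome-wide median of the per-gene
   values, a position qualifies as RIDGE-like when its smoothed value
   exceeds `m·f_up` and as anti-RIDGE-like when it falls below
   `m/f_down`. Maximal runs of at least `k = 10` qualifying positions
   become regions; a region spans from the first qualifying gene's start
   to the last qualifying gene's end, and its member genes are all
   annotation genes overlapping that interval by ≥ 1 bp.
3. **Coverage calibration** — `f_up` and `f_down` are chosen on a grid so
   that regions of each kind cover ≈ 10% of the genome in bp, making the
   two region classes comparable and the method portable across platforms.
4. **Permutation null** — gene positions stay fixed while expression
   values are shuffled genome-wide; maps are rebuilt and regions
   re-called 10,000 times, yielding an empirical p-value
   `(#{null ≥ observed}+1)/(B+1)` for the observed region count.
5. **HK/TS classification** — a gene is *expressed* in a tissue when its
   value strictly exceeds τ, the 99.9% quantile of the negative-control
   intensities. Genes expressed in all tissues of the panel are
   housekeeping (HK), in exactly one tissue-specific (TS).
6. **Set enrichment** — whether HK (or TS) genes are over-represented
   among RIDGE genes is tested by drawing equally sized gene sets from
   the universe *without replacement* 10,000 times and comparing the
   observed percent overlap with the resampled distribution (a
   hypergeometric null).
7. **Region distribution** — a query gene list (e.g. positively selected
   genes) is tested for a non-random split across RIDGE / anti-RIDGE /
   intermediate territory with Fisher's exact test on the 2×3 table
   (plus a 2×2 anti-RIDGE-vs-rest collapse).
8. **Genomic features** — gene length, mean intron length, GC fraction,
   mean transcript length, mean exon count and mean exon length are
   compared between gene groups with the two-sided Wilcoxon rank-sum
   test.

A bundled simulator (`ridgescan.simulate`) generates annotated genomes
with planted RIDGE/anti-RIDGE domains, class-conditional gene structure
(planted-RIDGE genes shorter, more compact, higher GC) and a five-tissue
expression matrix with correlated profiles, so the entire pipeline is
testable without any external data.

## Worked example

```
ridgescan run-all --simulate --seed 7 --n-chrom 2 --genes-per-chrom 600 \
    --n-perm 200 --n-samp 1000 --outdir demo
```

prints (stderr):

```
RIDGEs: 2 (coverage 0.090); anti-RIDGEs: 2 (coverage 0.069)
```

and writes `demo/report.json` together with the simulated inputs
(`annotation.tsv`, `expression.tsv`, `controls.tsv`, `truth.json`), the
tissue-averaged map, the region calls (`regions.bed`, `regions.tsv`),
the permutation null, the HK/TS classification and enrichment results,
and the feature comparison table. Here the caller recovered the two
planted high-expression domains and the two planted low-expression
domains of the simulated two-chromosome genome at close to the 10%
coverage target; re-running the command reproduces `report.json`
byte-for-byte.

The same subcommands work stage by stage on real files (`map`, `call`,
`permtest`, `classify`, `enrich`, `seldist`, `features`, `correlate`);
see `ridgescan --help`.

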