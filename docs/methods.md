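# Methods

## Model and procedure

The pipeline treats a genome as, per chromosome, an ordered sequence of
gene positions (sorted by start, ties broken by end then gene id) and a
transcriptome map as the running median of per-gene log2 expression
values along that order. Window size is counted in gene positions, not
bp, so gene-dense and gene-poor regions are smoothed equally in gene
units. All internal coordinates are 1-based inclusive; exported interval
files are BED 0-based half-open.

**Smoothing end rule.** Interior positions take the median of the
`w`-window centred on them. Within `(w−1)/2` positions of either
chromosome end the half-width shrinks symmetrically:
`h_i = min(i, n−1−i, (w−1)/2)` (0-based), so the first and last
positions keep their raw values. This is self-consistent, parameter-free
and reduces to the interior definition; it coincides with
`runmed(endrule="med")` in R. A consequence worth knowing: near
chromosome ends the map is barely smoothed, so short spurious qualifying
runs can appear there under noisy data; they are genuine outputs of the
rule, not artifacts of this implementation.

**Thresholds.** Qualification is strict (`>`, `<`): a map equal to the
genomic median everywhere yields no regions. "Fold down" divides
(`m/f_down`), "fold up" multiplies (`m·f_up`); both are applied to the
same log-intensity scale as the map, matching common practice for this
map type. Because folds are re-calibrated to the coverage target, this
convention is a default, not a behavioural constraint.

**Calibration.** Coverage is measured in bp (a `unit="genes"` option
exists for sensitivity analysis). The grid is `f ∈ {1.05, 1.10, …, 3.0}`
(step 0.05); ties in `|coverage − target|` resolve to the larger, more
stringent fold. Coverage is monotone non-increasing in the fold, so the
grid scan is exact on the grid.

**Permutation null.** Positions are fixed; the genome-wide assignment of
expression values to positions is shuffled uniformly. The genomic median
is invariant under this shuffle (same value multiset) and is computed
once. The reported p-value uses the add-one correction
`(#{null ≥ obs}+1)/(B+1)`; the plain proportion is also reported.

**Classification.** The expression threshold τ is the linear-interpolation
quantile (numpy default) of the negative-control intensities at
q = 0.999. "Expressed" is strict (`> τ`). HK/TS labels are relative to
the supplied tissue panel: a gene called HK against five brain-dominated
tissues may not be housekeeping against a broader panel.

**Resampling enrichment.** Draws are without replacement, so the null of
the percent overlap is hypergeometric with s.d.
`100·√(p(1−p)/n · (N−n)/(N−1))` percentage points; the Monte-Carlo
engine is validated against this closed form in the tests. The reported
tail follows the observed direction of deviation.

**Fisher's exact test.** The 2×3 test conditions on all margins and sums
the probabilities of tables no more probable than the observed one (the
r×c convention of R's `fisher.test`), enumerated over the free cells of
the query row in log-space. Because the exact construction of the
contingency table for a published analysis is often ambiguous, the 2×2
collapse (anti-RIDGE vs rest) is always reported alongside the 2×3 test.

**Wilcoxon comparisons.** Exact null distribution when both groups have
≤ 20 values and no ties; otherwise the normal approximation with midrank
tie correction. "Mean intron length" pools the introns of all
transcripts of a gene (a per-transcript-mean variant is available);
exon count is averaged over transcripts and may be fractional. Raw
p-values, no multiplicity correction across the six features.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `window` | 39 | gene positions | moving-median window (gene + 19 each side) |
| `min_stretch` | 10 | gene positions | minimum qualifying run length |
| `coverage_target` | 0.10 | fraction of genome bp | calibration target per region kind |
| `fold_up` / `fold_down` | 1.25 / 1.45 | fold vs genomic median | pre-calibration defaults |
| `control_quantile` | 0.999 | — | negative-control quantile defining τ |
| `n_perm` / `n_samp` | 10,000 | replicates | permutation / resampling null sizes |
| `grid_step`, `fold_max` | 0.05, 3.0 | fold | calibration grid |

## Synthetic data

`generate_genome` plants one RIDGE-like and one anti-RIDGE-like gene
block per chromosome at random locations. Block gene counts are solved
from the class-conditional expected gene spans so each kind's expected
bp coverage equals the target; gamma-distributed intron lengths
(shape 2) and intergenic gaps (shape 4) keep the realized coverage
within a few percent (relative) of the target. Gene structure per class
(defaults): planted-RIDGE genes average 6 exons, 1.8 kb introns,
GC 0.52; background 8 exons, 3.2 kb introns, GC 0.47; planted-anti-RIDGE
8 exons, 5.2 kb introns, GC 0.42 — shorter/compact/GC-rich high-expression
genes, as repeatedly observed across vertebrates.

`generate_expression` builds
`x(g,t) = μ_bg + shift + class term + u_g + ε(g,t)` with
`shift = ±δ` inside planted blocks (δ default 1.5 log2 units),
`u_g ~ N(0, 0.8)` a shared per-gene effect inducing the high
between-tissue map correlations seen in real panels, and
`ε ~ N(0, σ_bg)` (σ default 0.4), clipped to [8, 15] (the intensity
scale of two-colour arrays). Class terms: HK +1.6 in every tissue; TS
+1.2 in its tissue, −2.0 elsewhere; silent −2.2; intermediate genes get
a per-gene baseline offset `U(−2.5, 0.5)` so the expressed-in-k-tissues
histogram spans 0…5 rather than piling at 5. HK genes are placed into
planted RIDGEs with probability 0.35 vs 0.18 elsewhere, recreating the
HK-over-representation phenomenon. Negative controls are
`N(8.7, 0.3)` (n = 2000), putting τ ≈ 9.6 — below the background mean,
as on a real array.

What the simulator does **not** emulate: probe-level noise and multiple
probes per gene, array batch/dye effects, inter-individual variance,
realistic chromosome-scale gene-density variation, sequence-level GC
(GC is a drawn number, not computed from sequence), and any correlation
structure beyond the single shared per-gene effect. Passing tests on
synthetic data therefore demonstrate correctness of the algorithms and
recoverability of planted structure under the stated noise model — not
performance on any particular real dataset.

## Problem sizes and numerical choices

Recovery and calibration properties are exercised on single-chromosome
genomes of 2,000 genes, which keeps planted blocks (≈ 300 / 145 genes)
comfortably larger than the 39-gene window; with blocks only marginally
wider than the window, edge blurring of the running median caps
achievable boundary accuracy, which is a property of the method, not of
the implementation. Permutation-power demonstrations use four planted
domains (4 × 500 genes) because a region *count* statistic needs several
true regions to stand out against chance runs. Null-calibration checks
use δ = 0 **and** uniform HK placement: planted HK enrichment alone
creates genuine spatial expression clustering, which the permutation
test correctly detects, so a true null must disable both.

Medians of even-sized windows (possible only at shrunken ends in oracle
tests) are the mean of the two central order statistics. Calibration
tie-breaks are deterministic (larger fold). The run-report JSON contains
only deterministic quantities — stage wall-times go to the stderr log —
so identical seeds give byte-identical reports.

## Known limitations

- Region extent is defined by the qualifying genes' spans; window
  midpoints or half-open window extents would give slightly different
  bp coverage for the same calls.
- Member genes use the any-overlap rule; full containment would give
  systematically smaller member lists.
- The permutation shuffles values globally, preserving the value
  multiset but not any chromosome-specific composition.
- With one chromosome and one planted region per kind, the count
  statistic is nearly powerless; use genomes with several expected
  regions when assessing significance.
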