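# richdom

Tools for calling **factor-rich chromatin domains** from ChIP-seq peaks and
signal — the "super-enhancer" (ROSE-style) rank-ordering geometry applied to
repressive factors such as EZH2/PRC2 and H3K27me3 — together with the
downstream analyses such a study needs: genomic annotation of peaks and
domains, Hi-C A/B-compartment overlap enrichment, expression-repression and
methylation-correlation statistics, ROC diagnostics, gene-set
over-representation, signature scoring, and CpG-island prediction. A
seed-reproducible synthetic-data generator with planted ground truth makes
every stage testable end-to-end without any external downloads.

## Who this is for

Computational epigenomics groups asking where a chromatin factor forms
*broad, high-signal domains* (rather than point-source peaks), whether those
domains sit in repressive B compartments, and whether the genes under them
are transcriptionally silenced.

## The core algorithm

Given peaks and binned ChIP/input signal:

1. **Stitch** — peaks on the same chromosome whose gap is at most a window
   *W* (default 4 kb) are merged transitively into candidate regions.
2. **Score** — each stitched region gets
   `S = (mean ChIP density − mean input density) × region length`,
   negative values clamped to 0.
3. **Rank-order cutoff** — sort scores ascending as a curve *y(x)*,
   x = 1…N. A line with slope `(max y − min y) / N` is anchored at each
   point in turn; the anchor leaving the fewest points strictly below the
   line is the cutoff (the point where the curve's slope reaches the
   diagonal — the "elbow"). Regions scoring strictly above the cutoff are
   **rich domains**.

Because all candidate lines share one slope, the optimum is the point with
minimal residual `y − slope·x`; the test suite verifies exact agreement with
the quadratic all-pairs search.

## Worked example

```python
from richdom import (SimulationConfig, simulate_dataset, read_narrowpeak,
                     read_bedgraph, call_rich_domains)

truth = simulate_dataset(SimulationConfig(seed=1), "data/")
peaks = read_narrowpeak("data/peaks.narrowPeak")
chip  = read_bedgraph("data/chip.bedGraph", bin_size=200)
inp   = read_bedgraph("data/input.bedGraph", bin_size=200)

regions, cutoff = call_rich_domains(peaks, chip, inp)
rich = [r for r in regions if r.is_rich]
print(len(regions), len(rich), round(cutoff.cutoff_value, 1))
```

prints

```
195 5 4001.1
```

195 stitched regions were formed from the peak set; the rank-ordered curve
puts the elbow at a score of ≈4 001, and exactly the 5 broad planted
domains (10× signal over background) score above it. Comparing against
`data/truth.json` gives precision and recall 1.0 at Jaccard ≥ 0.5.

The same dataset supports every downstream module — e.g. the one-sided
rank-sum test of domain-target genes against all other genes in the tumor
cohort:

```python
from richdom import read_expression, compare_domain_gene_expression
expr = read_expression("data/expr.tsv")
res = compare_domain_gene_expression(truth.target_genes, expr,
                                     samples=truth.tumor_samples)
print(f"{res.p_value:.2e}")   # 3.74e-12 : planted repression detected
```

Or from the shell:

```bash
richdom simulate --out-dir data --seed 1
richdom call-domains --peaks data/peaks.narrowPeak --chip data/chip.bedGraph \
        --input data/input.bedGraph --bin-size 200 --out domains.bed
richdom cpg-scan --fasta promoter.fa --out islands.bed
```

## Layout

- `richdom.genomic` — interval/peak/gene/track/expression data model; BED,
  narrowPeak, bedGraph, gene-table TSV, expression TSV, GMT readers/writers.
- `richdom.domains` — stitching, scoring, tangent-line cutoff, domain calls.
- `richdom.annotate` — promoter/exon/intron/distal annotation and summaries.
- `richdom.compartments` — eigenvector orientation, A/B assignment,
  permutation enrichment.
- `richdom.stats` — rank-sum, correlation, ROC/Youden, hypergeometric ORA
  with BH, cohort splitting, signature scoring.
- `richdom.cpg` — sliding-window CpG-island scanner.
- `richdom.simulate` — the synthetic-data generator and its truth manifest.

See `docs/methods.md` for the modeling assumptions, parameter defaults and
numerical conventions.
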