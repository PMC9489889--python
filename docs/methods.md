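# Methods

## Domain calling

The caller implements the rank-ordering geometry popularised for
super-enhancer detection, applied here to broad repressive factors
(EZH2/PRC2, H3K27me3). Three steps:

**Stitching.** Peaks are sorted per chromosome by start and merged whenever
`next.start − running_end ≤ stitch_window`. The default window is 4 kb —
tighter than the 12.5 kb typically used for enhancer stitching, reflecting
the denser peak spacing inside polycomb-type domains. Merging is transitive
and idempotent; enlarging the window can only reduce the number of regions.
Both properties are asserted in the test suite against a brute-force
union-find oracle.

**Scoring.** `score = (mean ChIP density − mean input density) × length`,
with the mean taken over the whole stitched span by default. A
`constituents` mode restricts the sum to the constituent peak intervals,
for workflows that prefer not to credit the stitched gaps; the whole-span
default matches how density is mapped over complete stitched regions in
the super-enhancer literature. Negative background-subtracted scores are
clamped to 0 **before** ranking, because the cutoff geometry below assumes
a non-negative ascending curve.

**Tangent-line cutoff.** With scores sorted ascending as `y` over
`x = 1..N`, a line of slope `m = (max − min)/N` is anchored at each point;
the anchor minimising the number of points *strictly below* the line wins,
ties resolved to the smallest index (the most conservative, lowest cutoff).
Since every candidate line has the same slope, point j is below the line
anchored at i iff `y_j − m·x_j < y_i − m·x_i`, so the optimum is simply the
argmin of the residual `y − m·x` — an O(N log N) reduction of the O(N²)
search, verified exactly against the quadratic oracle. Regions are rich iff
their score strictly exceeds the cutoff value; on a perfectly flat curve no
region is rich. Strict inequalities ("strictly below", "strictly above")
make flat segments unambiguous. A single stitched region cannot support a
cutoff (N ≥ 2 required); it is returned flagged not-rich with a warning.

## Annotation

Categories promoter > exon > intron > distal, by fixed priority over all
overlapping features. The promoter is the strand-oriented ±2 kb window
around the TSS — chosen to match the promoter definition used elsewhere in
the pipeline (methylation region of interest) rather than the ±3 kb default
of some annotation tools; it is configurable. Finer categories (UTRs,
downstream) are deliberately collapsed into these four. Nearest gene is by
absolute TSS distance, ties broken lexicographically by gene id; the signed
distance is 0 iff the interval contains the TSS and follows transcription
direction otherwise.

## Compartment enrichment

The Hi-C leading eigenvector has an arbitrary sign per chromosome; it is
oriented so that positive values correlate with gene-body density (A =
gene-rich, open). Chromosomes with zero-variance eigenvector are left
unflipped with a warning. Bins are labelled A (> 0), B (< 0) or unassigned
(exactly 0 — not forced into a class). Enrichment of a domain set in B is
bp-weighted (domains vary >10× in length, so counting domains would
mis-weight), with a null that re-places each domain uniformly at random on
its own chromosome, preserving its length and allowing overlaps. The
one-sided empirical p uses the add-one rule
`p = (1 + #{null ≥ observed}) / (1 + n_permutations)` and therefore can
never be 0; results are bit-reproducible for a fixed seed. A circular-shift
null (for spatial autocorrelation robustness) was considered and not
implemented; uniform placement is adequate at the scales exercised here and
is trivially seedable.

## Association statistics

- **Rank-sum** (Wilcoxon/Mann–Whitney): exact enumeration p when
  `n1·n2 ≤ 10 000` and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections (delegated to scipy;
  exact p verified against full enumeration for n ≤ 8 per side). The
  repression test is one-sided ("domain genes lower") by default, and is
  computed on per-gene means over a chosen sample cohort — restricting to
  the tumor cohort avoids diluting a tumor-specific shift.
- **Correlation**: Pearson on values, Spearman on midranks, least-squares
  slope/intercept; zero-variance inputs are an error naming the offending
  vector.
- **ROC**: AUC by direct concordant-pair counting (ties ½). The reported
  cutoff maximises Youden J = sensitivity + specificity − 1, with ties
  broken toward higher specificity; a sample is predicted positive when its
  score ≥ cutoff. AUC, sensitivity and specificity are invariant under
  strictly monotone transforms of the scores (tested).
- **Over-representation**: one-sided hypergeometric upper tail per gene set
  after intersecting each set with the universe, BH adjustment across sets.
- **Cohort split**: top-n vs bottom-n samples by driver-gene expression
  (default 20 per group), ties broken lexicographically by sample id so the
  split is deterministic.
- **Signature score**: per-sample mean of gene-wise z-scores (sample sd,
  ddof = 1). This is a generic stand-in for proprietary weighted signature
  scores; genes with zero variance across samples make the z ill-defined
  and raise rather than silently dropping.

## CpG-island scanning

Windows of 200 bp slide at step 1; a window passes when GC% > 50 **and**
Obs/Exp CpG > 0.6, both strict inequalities as is conventional for these
criteria. `Obs = #CG dinucleotides`, `Exp = (#C × #G)/length`, with N bases
excluded from all counts and windows exceeding 10 % N failing outright.
Islands are unions of overlapping/adjacent passing windows (not trimmed to
passing cores — matching the visual convention of the classic island
finders) retained at merged length ≥ 200 bp, reported disjoint and sorted
with statistics recomputed over the merged span. The union merge rule is a
declared choice; no claim of bit-compatibility with any particular tool is
made.

## Synthetic data

`simulate_dataset` writes a complete miniature study: genome, compartments,
peaks, tracks, genes, expression, methylation, labels, and a `truth.json`
sufficient to score any downstream run. Defaults (all configurable):

| parameter | default | why |
|---|---|---|
| genome | 3 × 5 Mb | desk-scale; large enough for ~150 compartment bins |
| track bins | 200 bp | sub-peak resolution at small memory |
| compartment bins | 100 kb | domains (≤ 60 kb) fit inside one bin |
| planted domains | 5 × U(20–60 kb) | broad-domain scale |
| domain signal | 10× background | strong, recoverable enrichment |
| background peaks | 200 × 300–1000 bp at 3× | ordinary point-source peaks |
| background noise | N(1, 0.3) clipped at 0 | flat input-like floor |
| P(domain in B) | 0.9 | domains preferentially repressive |
| P(background gene in B) | 0.2 | B compartments are gene-poor |
| repression Δ | −2 log2 units in tumor | clear silencing signal |
| cohort | 40 tumor / 20 normal | unbalanced, realistic scale |
| methylation coupling | Spearman −0.25 | via Gaussian copula |

Planted domains are tiled with constituent peaks of 500–1500 bp separated
by 0.5–3.5 kb gaps, so recovering a domain genuinely requires the stitching
step (≥ 3 peaks per domain). Background peaks carry a separate 3× signal:
they are real but narrow enrichments, so stitched clusters of them score
orders of magnitude below broad domains — the same contrast that separates
tens of thousands of peaks from a few hundred domains in real data.
Background genes avoid B bins with probability 0.8, giving the gene-density
contrast that the eigenvector orientation step relies on; domain-target
genes have their TSS planted inside domains regardless (silenced genes do
sit in B domains). The methylation–expression pair uses a Gaussian copula
at latent correlation `2·sin(π·ρ/6)`, which attains the target Spearman ρ
exactly in the large-n limit; both margins are monotone transforms, so the
rank correlation is preserved.

The generator is deterministic: identical configs (including seed) write
byte-identical files.

**Power note.** The compartment-enrichment study is run on a config with 20
planted domains on a 3 × 10 Mb genome (800 genes). With only 5 domains the
permutation test is intrinsically underpowered — the null standard
deviation of a 5-domain B-fraction on a half-B genome is ≈ 0.22, so even a
perfectly planted set cannot reliably reach p < 0.05. Twenty domains on a
proportionally larger genome keep domains a small fraction of the genome
(as in real data) while giving the test adequate power.

**What the generator does not emulate.** Read-level noise, fragment-size
effects, mappability and copy-number artifacts, correlated gene programs,
and realistic compartment spatial autocorrelation (bins are i.i.d.). Tests
passing on this generator demonstrate that the algorithms recover planted
structure of the stated kind and strength; they do not certify performance
on real ChIP-seq, where background is heavier-tailed and enrichment is less
uniform.

## Numerical conventions

Coordinates are 0-based half-open throughout; 1-based sources are converted
at the reader boundary. Chromosome names are taken verbatim, and combining
files whose naming styles share no names is an explicit error. bedGraph
records are resampled onto fixed bins by coverage-weighted mean with
uncovered bp contributing 0; overlapping records with different values are
rejected as contradictory. Signal means over intervals are length-weighted
and conserve the mean over disjoint unions exactly. All Monte-Carlo
procedures take explicit seeds and use numpy's PCG64 generator.
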