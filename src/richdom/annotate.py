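"""Genomic annotation of peaks and domains.

Assigns each interval to one of four categories — promoter, exon, intron,
distal — by a fixed priority (promoter > exon > intron > distal), and to
its nearest gene by TSS distance.  The promoter is a +/-2 kb window around
the TSS by default, oriented by gene strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic import GeneModel, GenomicInterval

__all__ = [
    "AnnotationConfig",
    "AnnotatedInterval",
    "promoter_interval",
    "annotate_interval",
    "annotation_summary",
]

CATEGORIES = ("promoter", "exon", "intron", "distal")


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000

    def __post_init__(self) -> None:
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter windows must be >= 0")


@dataclass(frozen=True)
class AnnotatedInterval:
    interval: GenomicInterval
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None  # signed, strand-aware; negative = upstream


def promoter_interval(gene: GeneModel, config: AnnotationConfig) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS."""
    t = gene.tss
    if gene.interval.strand == "+":
        start = t - config.promoter_upstream
        end = t + config.promoter_downstream
    else:
        start = t - config.promoter_downstream + 1
        end = t + config.promoter_upstream + 1
    return GenomicInterval(gene.interval.chrom, max(0, start), max(1, end), gene.interval.strand)


def _signed_tss_distance(interval: GenomicInterval, gene: GeneModel) -> int:
    """0 iff the interval contains the TSS; sign follows transcription."""
    t = gene.tss
    if interval.start <= t < interval.end:
        return 0
    if t < interval.start:
        d = interval.start - t  # interval right of TSS
    else:
        d = (interval.end - 1) - t  # negative: interval left of TSS
    return d if gene.interval.strand == "+" else -d


def annotate_interval(
    interval: GenomicInterval,
    genes: list[GeneModel],
    config: AnnotationConfig = AnnotationConfig(),
) -> AnnotatedInterval:
    """Assign the highest-priority category among overlapping features.

    Promoter beats exon beats intron; intervals overlapping nothing are
    distal.  The nearest gene is chosen by absolute TSS distance with
    lexicographic gene_id tie-break; on a chromosome without genes the
    category is distal and no nearest gene is reported.
    """
    chrom_genes = [g for g in genes if g.interval.chrom == interval.chrom]
    if not chrom_genes:
        return AnnotatedInterval(interval, "distal", None, None)

    is_promoter = is_exon = is_intron = False
    for g in chrom_genes:
        if interval.overlaps(promoter_interval(g, config)):
            is_promoter = True
        if interval.overlaps(g.interval):
            if any(interval.overlaps(ex) for ex in g.exons):
                is_exon = True
            else:
                is_intron = True
    if is_promoter:
        category = "promoter"
    elif is_exon:
        category = "exon"
    elif is_intron:
        category = "intron"
    else:
        category = "distal"

    nearest = min(
        chrom_genes,
        key=lambda g: (abs(_signed_tss_distance(interval, g)), g.gene_id),
    )
    return AnnotatedInterval(
        interval, category, nearest.gene_id, _signed_tss_distance(interval, nearest)
    )


def annotation_summary(
    intervals: list[GenomicInterval],
    genes: list[GeneModel],
    config: AnnotationConfig = AnnotationConfig(),
) -> dict[str, dict[str, float]]:
    """Category counts and fractions over a set of intervals.

    Fractions sum to 1; raises on empty input.
    """
    if not intervals:
        raise ValueError("annotation_summary requires >= 1 interval")
    counts = {c: 0 for c in CATEGORIES}
    for iv in intervals:
        counts[annotate_interval(iv, genes, config).category] += 1
    total = len(intervals)
    return {
        "counts": {c: float(counts[c]) for c in CATEGORIES},
        "fractions": {c: counts[c] / total for c in CATEGORIES},
    }
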