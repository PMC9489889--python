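"""Seed-reproducible synthetic datasets with planted ground truth.

The generator emulates the statistical structure of a polycomb-factor
ChIP-seq study: broad high-signal domains planted on a small genome and
tiled with constituent peaks (so the stitching step is genuinely
exercised), a flat input track, a Hi-C-style eigenvector with domains
preferentially in B bins, an expression matrix in which domain-promoter
genes are repressed in tumor samples, and a driver gene whose expression
anti-correlates with its promoter methylation at a target Spearman rho
via a Gaussian copula.  All outputs are pure functions of the config
(including its seed): the same config writes byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .genomic import (
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    write_bedgraph,
    write_genes_tsv,
    write_narrowpeak,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_methylation_expression",
    "simulate_expression_groups",
    "simulate_roc_cohort",
]

DRIVER_GENE = "EZH2"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults plant 5 broad domains with 10x signal over a ~N(1, 0.3)
    background on a 3 x 5 Mb genome, put domains in B compartments with
    probability 0.9, repress domain-target genes by 2 log2 units in the
    40 tumor samples, and couple driver expression to promoter
    methylation at Spearman rho = -0.25.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 5_000_000
    n_genes: int = 400
    n_background_peaks: int = 200
    n_planted_domains: int = 5
    domain_length_min: int = 20_000
    domain_length_max: int = 60_000
    background_signal_mean: float = 1.0
    background_signal_sd: float = 0.3
    domain_signal_multiplier: float = 10.0
    peak_signal_multiplier: float = 3.0  # ordinary point-source peaks
    b_compartment_fraction: float = 0.5
    p_domain_in_B: float = 0.9
    repression_delta: float = -2.0
    n_tumor: int = 40
    n_normal: int = 20
    driver_methylation_rho: float = -0.25
    expression_noise_sd: float = 1.0
    track_bin_size: int = 200
    eigen_bin_size: int = 100_000
    targets_per_domain: int = 8
    p_gene_in_B: float = 0.2  # B compartments are gene-poor

    def __post_init__(self) -> None:
        if self.domain_signal_multiplier <= 1:
            raise ValueError("domain_signal_multiplier must be > 1")
        if not (0 <= self.p_domain_in_B <= 1 and 0 <= self.b_compartment_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_genes",
            "n_background_peaks",
            "n_planted_domains",
            "n_tumor",
            "n_normal",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.domain_length_max > self.eigen_bin_size:
            raise ValueError("domains must fit inside one compartment bin")


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score any downstream run."""

    domains: list[GenomicInterval]
    target_genes: list[str]
    driver_gene: str
    tumor_samples: list[str]
    normal_samples: list[str]
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domains": [
                {"chrom": d.chrom, "start": d.start, "end": d.end} for d in self.domains
            ],
            "target_genes": self.target_genes,
            "driver_gene": self.driver_gene,
            "tumor_samples": self.tumor_samples,
            "normal_samples": self.normal_samples,
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            domains=[
                GenomicInterval(d["chrom"], d["start"], d["end"])
                for d in payload["domains"]
            ],
            target_genes=payload["target_genes"],
            driver_gene=payload["driver_gene"],
            tumor_samples=payload["tumor_samples"],
            normal_samples=payload["normal_samples"],
            config=SimulationConfig(**payload["config"]),
        )


def _chrom_names(cfg: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]


def _simulate_compartments(cfg: SimulationConfig, rng) -> dict[str, np.ndarray]:
    """Eigenvector per chromosome: B bins negative, A bins positive."""
    eigen = {}
    for chrom in _chrom_names(cfg):
        n_bins = cfg.chrom_length // cfg.eigen_bin_size
        is_b = rng.random(n_bins) < cfg.b_compartment_fraction
        mag = np.abs(rng.normal(1.0, 0.3, n_bins)) + 1e-3
        eigen[chrom] = np.where(is_b, -mag, mag)
    return eigen


def _place_domains(
    cfg: SimulationConfig, eigen: dict[str, np.ndarray], rng
) -> list[GenomicInterval]:
    """One planted domain per chosen compartment bin, mostly in B."""
    chroms = _chrom_names(cfg)
    used: dict[str, set[int]] = {c: set() for c in chroms}
    domains = []
    for i in range(cfg.n_planted_domains):
        chrom = chroms[i % len(chroms)]
        want_b = rng.random() < cfg.p_domain_in_B
        labels = eigen[chrom] < 0
        candidates = np.flatnonzero(labels == want_b)
        candidates = np.array([b for b in candidates if b not in used[chrom]])
        if candidates.size == 0:  # fall back to any free bin
            candidates = np.array(
                [b for b in range(len(eigen[chrom])) if b not in used[chrom]]
            )
        if candidates.size == 0:
            raise ValueError(f"cannot place domain {i}: no free compartment bin on {chrom}")
        b = int(rng.choice(candidates))
        used[chrom].add(b)
        length = int(rng.integers(cfg.domain_length_min, cfg.domain_length_max + 1))
        slack = cfg.eigen_bin_size - length
        start = b * cfg.eigen_bin_size + int(rng.integers(0, slack + 1))
        domains.append(GenomicInterval(chrom, start, start + length))
    return domains


def _tile_domain_peaks(domain: GenomicInterval, rng) -> list[Peak]:
    """Constituent peaks of 500-1500 bp separated by sub-stitch gaps."""
    peaks = []
    pos = domain.start
    while pos < domain.end - 500:
        length = int(rng.integers(500, 1501))
        end = min(pos + length, domain.end)
        peaks.append(
            Peak(GenomicInterval(domain.chrom, pos, end), name=f"dpk_{pos}", score=10.0)
        )
        pos = end + int(rng.integers(500, 3500))
    return peaks


def _place_background_peaks(
    cfg: SimulationConfig, domains: list[GenomicInterval], rng
) -> list[Peak]:
    """Random isolated peaks kept > stitch-range away from planted domains."""
    chroms = _chrom_names(cfg)
    margin = 5000
    peaks: list[Peak] = []
    attempts = 0
    while len(peaks) < cfg.n_background_peaks and attempts < cfg.n_background_peaks * 50:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(300, 1001))
        start = int(rng.integers(0, cfg.chrom_length - length))
        iv = GenomicInterval(chrom, start, start + length)
        near_domain = any(
            d.chrom == chrom and iv.start < d.end + margin and d.start - margin < iv.end
            for d in domains
        )
        if near_domain:
            continue
        peaks.append(Peak(iv, name=f"bpk_{len(peaks)}", score=2.0))
    if len(peaks) < cfg.n_background_peaks:
        raise ValueError("could not place all background peaks away from domains")
    return peaks


def _simulate_tracks(
    cfg: SimulationConfig,
    domains: list[GenomicInterval],
    bg_peaks: list[Peak],
    rng,
) -> tuple[SignalTrack, SignalTrack]:
    """ChIP and input tracks: shared noise model, enrichment in ChIP only."""
    bs = cfg.track_bin_size
    n_bins = cfg.chrom_length // bs
    mu, sd = cfg.background_signal_mean, cfg.background_signal_sd
    chip_vals, input_vals = {}, {}
    for chrom in _chrom_names(cfg):
        chip = np.clip(rng.normal(mu, sd, n_bins), 0, None)
        inp = np.clip(rng.normal(mu, sd, n_bins), 0, None)
        for mult, spans in (
            (cfg.peak_signal_multiplier, [p.interval for p in bg_peaks if p.interval.chrom == chrom]),
            (cfg.domain_signal_multiplier, [d for d in domains if d.chrom == chrom]),
        ):
            enriched = np.zeros(n_bins, bool)
            for region in spans:
                enriched[region.start // bs : -(-region.end // bs)] = True
            k = int(enriched.sum())
            if k:
                chip[enriched] = np.clip(rng.normal(mu * mult, sd * mult, k), 0, None)
        chip_vals[chrom] = chip
        input_vals[chrom] = inp
    return (
        SignalTrack(bs, chip_vals, units="chip"),
        SignalTrack(bs, input_vals, units="input"),
    )


def _place_genes(
    cfg: SimulationConfig,
    domains: list[GenomicInterval],
    eigen: dict[str, np.ndarray],
    rng,
) -> tuple[list[GeneModel], list[str]]:
    """Genes with TSS either planted inside a domain (targets) or well away.

    Background genes land in B compartment bins only with probability
    p_gene_in_B, reproducing the gene-poor character of B compartments
    that lets the eigenvector be oriented by gene density.
    """
    chroms = _chrom_names(cfg)
    genes: list[GeneModel] = []
    target_ids: list[str] = []
    gid = 0

    def make_gene(chrom: str, tss: int, strand: str) -> GeneModel:
        nonlocal gid
        length = int(rng.integers(5_000, 50_001))
        if strand == "+":
            start, end = tss, min(tss + length, cfg.chrom_length)
        else:
            start, end = max(0, tss - length + 1), tss + 1
        n_ex = int(rng.integers(2, 6))
        cuts = np.sort(rng.integers(start, end, 2 * n_ex))
        exons = tuple(
            GenomicInterval(chrom, int(s), int(e) + 1, strand)
            for s, e in zip(cuts[0::2], cuts[1::2])
            if int(e) + 1 <= end and int(s) >= start and int(s) < int(e) + 1
        )
        # keep exons disjoint: drop overlapping successors
        kept: list[GenomicInterval] = []
        for ex in exons:
            if not kept or ex.start >= kept[-1].end:
                kept.append(ex)
        gid += 1
        return GeneModel(f"gene_{gid:04d}", GenomicInterval(chrom, start, end, strand), tuple(kept))

    # domain-target genes: TSS uniform inside each planted domain
    for d in domains:
        for _ in range(cfg.targets_per_domain):
            tss = int(rng.integers(d.start, d.end))
            g = make_gene(d.chrom, tss, "+" if rng.random() < 0.5 else "-")
            genes.append(g)
            target_ids.append(g.gene_id)

    margin = 10_000
    while len(genes) < cfg.n_genes - 1:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        tss = int(rng.integers(margin, cfg.chrom_length - margin))
        if any(
            d.chrom == chrom and d.start - margin <= tss < d.end + margin for d in domains
        ):
            continue
        in_b = eigen[chrom][tss // cfg.eigen_bin_size] < 0
        if in_b and rng.random() > cfg.p_gene_in_B:
            continue
        genes.append(make_gene(chrom, tss, "+" if rng.random() < 0.5 else "-"))

    # the driver gene, away from domains on the first chromosome
    while True:
        tss = int(rng.integers(margin, cfg.chrom_length - margin))
        if not any(
            d.chrom == chroms[0] and d.start - margin <= tss < d.end + margin
            for d in domains
        ):
            break
    length = int(rng.integers(5_000, 50_001))
    driver = GeneModel(
        DRIVER_GENE,
        GenomicInterval(chroms[0], tss, min(tss + length, cfg.chrom_length), "+"),
    )
    genes.append(driver)
    return genes, target_ids


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent Gaussian correlation achieving a target Spearman rho."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_methylation_expression(
    n: int, rho: float, seed: int, expr_mean: float = 7.0, expr_sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (methylation beta, expression) values at target Spearman rho.

    A bivariate Gaussian copula is sampled at the latent correlation
    2 sin(pi rho / 6), which yields the requested Spearman correlation in
    the large-n limit; methylation is the Gaussian CDF of one coordinate
    (a value in (0, 1)), expression a location-scale transform of the
    other, both monotone so the rank correlation is preserved.
    """
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson_latent(rho)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    meth = sps.norm.cdf(z[:, 0])
    expr = expr_mean + expr_sd * z[:, 1]
    return meth, expr


def simulate_expression_groups(
    n_genes: int,
    n_targets: int,
    n_tumor: int,
    n_normal: int,
    delta: float,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal expression simulation for calibration studies.

    Returns (matrix of shape genes x samples, boolean target mask); the
    first n_tumor columns are tumor samples in which target genes are
    shifted by delta log2 units.  With delta = 0 this is an exact null.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(5.0, 1.5, n_genes)
    mat = baseline[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_tumor + n_normal))
    targets = np.zeros(n_genes, bool)
    targets[:n_targets] = True
    mat[targets, :n_tumor] += delta
    return np.clip(mat, 0, None), targets


def simulate_dataset(
    cfg: SimulationConfig, out_dir: str | Path
) -> SyntheticTruth:
    """Write the full synthetic dataset and its truth manifest.

    Files written to out_dir: genes.tsv, peaks.narrowPeak, chip.bedGraph,
    input.bedGraph, eigen.bedGraph, expr.tsv, meth.tsv, labels.tsv,
    truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    eigen = _simulate_compartments(cfg, rng)
    domains = _place_domains(cfg, eigen, rng)
    domain_peaks = [p for d in domains for p in _tile_domain_peaks(d, rng)]
    bg_peaks = _place_background_peaks(cfg, domains, rng)
    chip, inp = _simulate_tracks(cfg, domains, bg_peaks, rng)
    genes, target_ids = _place_genes(cfg, domains, eigen, rng)

    tumor = [f"tumor_{i + 1:03d}" for i in range(cfg.n_tumor)]
    normal = [f"normal_{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = tumor + normal
    n_s = len(samples)

    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(5.0, 1.5, len(gene_ids))
    expr = baseline[:, None] + rng.normal(0.0, cfg.expression_noise_sd, (len(gene_ids), n_s))
    target_set = set(target_ids)
    for i, g in enumerate(gene_ids):
        if g in target_set:
            expr[i, : cfg.n_tumor] += cfg.repression_delta

    # driver: coupled to promoter methylation across all samples; tumor
    # samples additionally overexpress the driver
    meth, driver_expr = simulate_methylation_expression(
        n_s,
        cfg.driver_methylation_rho,
        seed=int(rng.integers(0, 2**31 - 1)),
        expr_mean=7.0,
        expr_sd=1.0,
    )
    driver_expr = driver_expr.copy()
    driver_expr[: cfg.n_tumor] += 2.0
    expr[gene_ids.index(DRIVER_GENE)] = driver_expr
    expr = np.clip(expr, 0, None)

    write_genes_tsv(genes, out / "genes.tsv")
    write_narrowpeak(domain_peaks + bg_peaks, out / "peaks.narrowPeak")
    write_bedgraph(chip, out / "chip.bedGraph")
    write_bedgraph(inp, out / "input.bedGraph")
    write_bedgraph(
        SignalTrack(cfg.eigen_bin_size, eigen, units="eigenvector"),
        out / "eigen.bedGraph",
    )
    with open(out / "expr.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(samples) + "\n")
        for g, row in zip(gene_ids, expr):
            fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    with open(out / "meth.tsv", "w") as fh:
        fh.write("sample\tmethylation\n")
        for s, m in zip(samples, meth):
            fh.write(f"{s}\t{m:.6g}\n")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("sample\tlabel\n")
        for s in samples:
            fh.write(f"{s}\t{'tumor' if s in set(tumor) else 'normal'}\n")

    truth = SyntheticTruth(
        domains=domains,
        target_genes=sorted(target_ids),
        driver_gene=DRIVER_GENE,
        tumor_samples=tumor,
        normal_samples=normal,
        config=cfg,
    )
    truth.to_json(out / "truth.json")
    return truth


def simulate_roc_cohort(
    target_auc: float,
    n_pos: int = 500,
    n_neg: int = 500,
    seed: int = 0,
    mu: float = 7.0,
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class scores with a planted binormal shift hitting a target AUC.

    For equal-variance normal classes, AUC = Phi(delta / (sigma sqrt 2)),
    so delta = sigma sqrt(2) Phi^-1(AUC).  Requested AUC must lie in
    [0.5, 1): 0.5 is the exact null (delta 0), 1 is unreachable at any
    finite shift.
    """
    if not (0.5 <= target_auc < 1.0):
        raise ValueError(f"target AUC must lie in [0.5, 1), got {target_auc}")
    if n_pos < 5 or n_neg < 5:
        raise ValueError("class sizes must be >= 5")
    delta = sigma * np.sqrt(2.0) * sps.norm.ppf(target_auc)
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(mu + delta, sigma, n_pos), rng.normal(mu, sigma, n_neg)]
    )
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    return scores, labels
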