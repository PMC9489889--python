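"""Association statistics for expression, methylation and diagnostics.

Covers the downstream statistical questions of the pipeline: are genes
under rich domains transcriptionally repressed (rank-sum), does promoter
methylation anti-correlate with driver expression (Pearson/Spearman),
how well does driver expression separate tumor from normal (ROC with a
Youden-optimal cutoff), which gene sets are over-represented among hits
(hypergeometric with BH adjustment), cohort splitting by driver
expression, and mean-z signature scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genomic import ExpressionMatrix

__all__ = [
    "RankSumResult",
    "CorrelationResult",
    "RocResult",
    "OraResult",
    "OraSetResult",
    "GroupSplit",
    "rank_sum_test",
    "compare_domain_gene_expression",
    "correlate",
    "roc_analysis",
    "ora_fisher",
    "split_by_driver",
    "signature_score",
]

EXACT_MAX_PRODUCT = 10_000  # exact rank-sum enumeration up to n1*n2 of this


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    alternative: str  # two_sided / less / greater
    method: str  # exact / normal_approx
    n1: int
    n2: int
    median1: float | None = None
    median2: float | None = None


def rank_sum_test(
    x, y, alternative: str = "two_sided"
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration when n1*n2 <= 10,000 and the pooled sample has
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  `alternative="less"` tests whether x is stochastically
    smaller than y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = (x.size * y.size <= EXACT_MAX_PRODUCT) and not has_ties
    method = "exact" if exact_ok else "normal_approx"
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=alternative.replace("_", "-"),
        method="exact" if exact_ok else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        method=method,
        n1=int(x.size),
        n2=int(y.size),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
    )


def compare_domain_gene_expression(
    domain_genes, expr: ExpressionMatrix, background=None, samples=None
) -> RankSumResult:
    """Test whether domain-associated genes are expressed lower.

    Per-gene expression is the mean over samples (optionally restricted
    to a cohort, e.g. the tumor samples) of the log-scale matrix; the
    one-sided alternative is that domain genes are lower than the
    background (all other genes unless given explicitly).
    """
    domain_genes = [g for g in domain_genes if g in expr.data.index]
    if background is None:
        background = [g for g in expr.data.index if g not in set(domain_genes)]
    else:
        background = [g for g in background if g in expr.data.index]
    if len(domain_genes) < 3 or len(background) < 3:
        raise ValueError(
            f"need >= 3 genes per group, got {len(domain_genes)} domain / "
            f"{len(background)} background"
        )
    data = expr.data if samples is None else expr.data[list(samples)]
    means = data.mean(axis=1)
    return rank_sum_test(
        means.loc[domain_genes].to_numpy(),
        means.loc[background].to_numpy(),
        alternative="less",
    )


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    slope: float
    intercept: float
    n: int


def correlate(x_values, y_values) -> CorrelationResult:
    """Pearson, Spearman and least-squares line for paired values."""
    x = np.asarray(x_values, float)
    y = np.asarray(y_values, float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    for name, v in (("x", x), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    lr = sps.linregress(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(x.size),
    )


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


def roc_analysis(scores, labels) -> RocResult:
    """ROC curve, AUC by concordant-pair counting, Youden-optimal cutoff.

    AUC = P(score_pos > score_neg) + 0.5 P(tie), computed by direct pair
    enumeration.  A sample is predicted positive when score >= cutoff;
    the cutoff maximizing Youden J = sensitivity + specificity - 1 is
    reported, with ties broken toward higher specificity (i.e. the
    higher cutoff).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    diff = pos[:, None] - neg[None, :]
    auc = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)

    thresholds = np.unique(scores)[::-1]  # descending; predict pos when >= t
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    # first index in descending-threshold order = highest cutoff = max specificity
    best = int(np.argmax(j))
    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
    )


@dataclass(frozen=True)
class OraSetResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K (after intersecting with universe)
    n_hits: int  # n
    universe_size: int  # N
    odds_ratio: float
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class OraResult:
    results: tuple[OraSetResult, ...]  # sorted by raw p ascending

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


def ora_fisher(hit_genes, gene_sets: dict, universe) -> OraResult:
    """Over-representation by one-sided hypergeometric (Fisher exact) test.

    Each set is intersected with the universe before testing; p is the
    upper tail P(X >= k) for X ~ Hypergeom(N, K, n); BH adjustment is
    applied across all tested sets.
    """
    universe = set(universe)
    hits = set(hit_genes) & universe
    if not universe:
        raise ValueError("universe is empty")
    if not set(hit_genes):
        raise ValueError("hit list is empty")
    if not hits:
        raise ValueError("no hit genes lie in the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & hits)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        # sample odds ratio of the 2x2 table, inf when a margin is exhausted
        a, b, c, d = k, n - k, K - k, N - K - n + k
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else 0.0
        rows.append((name, k, K, n, N, odds, p))
    padj = multipletests([r[6] for r in rows], method="fdr_bh")[1]
    results = sorted(
        (
            OraSetResult(name, k, K, n, N, odds, p, float(pa))
            for (name, k, K, n, N, odds, p), pa in zip(rows, padj)
        ),
        key=lambda r: (r.p_value, r.set_name),
    )
    return OraResult(tuple(results))


@dataclass(frozen=True)
class GroupSplit:
    driver_gene: str
    high_samples: tuple[str, ...]
    low_samples: tuple[str, ...]
    n_per_group: int


def split_by_driver(
    expr: ExpressionMatrix, driver_gene: str, n_per_group: int = 20
) -> GroupSplit:
    """Top-n / bottom-n cohort split by driver-gene expression.

    Deterministic: samples are ordered by driver expression with
    lexicographic sample-id tie-break; the top n form the high group and
    the bottom n the low group.
    """
    if driver_gene not in expr.data.index:
        raise KeyError(f"driver gene {driver_gene!r} not in expression matrix")
    samples = expr.samples
    if len(samples) < 2 * n_per_group:
        raise ValueError(
            f"need >= {2 * n_per_group} samples for n_per_group={n_per_group}, "
            f"got {len(samples)}"
        )
    driver = expr.data.loc[driver_gene]
    order = sorted(samples, key=lambda s: (driver[s], s))
    return GroupSplit(
        driver_gene=driver_gene,
        high_samples=tuple(order[-n_per_group:]),
        low_samples=tuple(order[:n_per_group]),
        n_per_group=n_per_group,
    )


def signature_score(
    expr: ExpressionMatrix, gene_set, ddof: int = 1
) -> pd.Series:
    """Per-sample mean of gene-wise z-scores over a gene set.

    Each signature gene is z-scored across samples (sample sd, ddof=1 by
    default) and the z-scores averaged per sample.  Missing genes warn;
    a gene with zero variance across samples makes the z ill-defined and
    raises, naming the offenders.
    """
    if len(expr.samples) < 2:
        raise ValueError("need >= 2 samples to z-score")
    present = [g for g in gene_set if g in expr.data.index]
    missing = [g for g in gene_set if g not in expr.data.index]
    if not present:
        raise ValueError("signature entirely absent from expression matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from matrix: {missing[:5]}...",
            stacklevel=2,
        )
    sub = expr.data.loc[present]
    sd = sub.std(axis=1, ddof=ddof)
    zero_var = list(sd.index[sd == 0])
    if zero_var:
        raise ValueError(f"zero-variance signature genes: {zero_var[:5]}")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)
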