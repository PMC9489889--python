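import numpy as np
import pytest

from richdom.genomic import GenomicInterval, Peak
from richdom.simulate import SimulationConfig, simulate_dataset


SMALL_CONFIG = SimulationConfig(
    seed=11,
    n_chromosomes=2,
    chrom_length=1_000_000,
    n_genes=60,
    n_background_peaks=40,
    n_planted_domains=2,
    n_tumor=10,
    n_normal=6,
    targets_per_domain=5,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic dataset shared by read-only tests."""
    out = tmp_path_factory.mktemp("smallsim")
    truth = simulate_dataset(SMALL_CONFIG, out)
    return out, truth


def random_peaks(rng, n, chrom_span=100_000, n_chroms=2, max_len=2000):
    """Unsorted random peaks for oracle comparisons."""
    peaks = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_span))
        length = int(rng.integers(50, max_len))
        peaks.append(Peak(GenomicInterval(chrom, start, start + length), name=f"p{i}"))
    return peaks


def stitch_oracle(peaks, window):
    """Brute-force transitive-closure merge on the gap relation (union-find)."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= window:
                parent[find(i)] = find(j)

    groups = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    spans = sorted(
        (
            g[0].interval.chrom,
            min(p.interval.start for p in g),
            max(p.interval.end for p in g),
            len(g),
        )
        for g in groups.values()
    )
    return spans


def cutoff_oracle(scores):
    """Exhaustive points-below-line search over every candidate index."""
    y = np.sort(np.clip(np.asarray(scores, float), 0, None))
    n = y.size
    x = np.arange(1, n + 1)
    m = (y[-1] - y[0]) / n
    best_idx, best_count = None, None
    for i in range(n):
        line = y[i] + m * (x - x[i])
        count = int((y < line).sum())
        if best_count is None or count < best_count:
            best_idx, best_count = i, count
    return best_idx, best_count, float(y[best_idx])
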