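"""CpG-island prediction on promoter-scale sequences.

Classic sliding-window criteria: a window passes when its G+C percentage
and its observed/expected CpG ratio both strictly exceed their thresholds
(defaults 50 % and 0.6 over 200 bp windows at step 1); overlapping or
adjacent passing windows are merged by union and merged runs at least the
minimum island length are reported, with GC% and Obs/Exp recomputed over
the merged island.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CpGScanConfig",
    "CpGIsland",
    "gc_percent",
    "obs_exp_cpg",
    "cpg_island_scan",
]


@dataclass(frozen=True)
class CpGScanConfig:
    min_island_length: int = 200
    step: int = 1
    min_gc_percent: float = 50.0
    min_obs_exp: float = 0.6
    window_length: int | None = None  # defaults to min_island_length
    max_n_fraction: float = 0.1  # windows with more N than this fail

    def __post_init__(self) -> None:
        if self.min_island_length <= 0 or self.step < 1:
            raise ValueError("min_island_length must be > 0 and step >= 1")
        if self.min_gc_percent <= 0 or self.min_obs_exp <= 0:
            raise ValueError("thresholds must be > 0")

    @property
    def window(self) -> int:
        return self.window_length or self.min_island_length


@dataclass(frozen=True)
class CpGIsland:
    """An island in sequence-local 0-based half-open coordinates."""

    start: int
    end: int
    gc_percent: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(C, G, CpG, non-N length) for an upper-cased sequence."""
    s = seq.upper()
    c, g = s.count("C"), s.count("G")
    cg = s.count("CG")
    non_n = sum(s.count(b) for b in "ACGT")
    return c, g, cg, non_n


def gc_percent(seq: str) -> float:
    """100 * (C+G) / (A+C+G+T); N bases excluded from both sides."""
    c, g, _, non_n = _counts(seq)
    if non_n == 0:
        raise ValueError("sequence has no non-N bases")
    return 100.0 * (c + g) / non_n


def obs_exp_cpg(seq: str) -> float:
    """Observed CpG count over expected (C*G/length); 0 when expected is 0."""
    c, g, cg, non_n = _counts(seq)
    if non_n == 0:
        raise ValueError("sequence has no non-N bases")
    expected = c * g / non_n
    return cg / expected if expected > 0 else 0.0


def cpg_island_scan(seq: str, config: CpGScanConfig = CpGScanConfig()) -> list[CpGIsland]:
    """Slide a window over the sequence and merge passing windows.

    A window passes when GC% and Obs/Exp both strictly exceed their
    thresholds and its N fraction is at most max_n_fraction.  Islands are
    the unions of passing windows with merged length >= min_island_length,
    reported disjoint and sorted, with statistics recomputed per island.
    Case-insensitive; a sequence shorter than the window warns and
    returns no islands.
    """
    s = seq.upper()
    w = config.window
    n = len(s)
    if n < w:
        warnings.warn(f"sequence length {n} < window {w}; no scan performed", stacklevel=2)
        return []

    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = ~(is_c | is_g | (arr == ord("A")) | (arr == ord("T")))
    is_cpg = np.zeros(n, bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    starts = np.arange(0, n - w + 1, config.step)
    csC = np.concatenate([[0], np.cumsum(is_c)])
    csG = np.concatenate([[0], np.cumsum(is_g)])
    csN = np.concatenate([[0], np.cumsum(is_n)])
    csCpG = np.concatenate([[0], np.cumsum(is_cpg)])

    nC = csC[starts + w] - csC[starts]
    nG = csG[starts + w] - csG[starts]
    nN = csN[starts + w] - csN[starts]
    # CpG dinucleotides fully inside the window: positions start..start+w-2
    nCpG = csCpG[starts + w - 1] - csCpG[starts]

    non_n = w - nN
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(non_n > 0, 100.0 * (nC + nG) / np.maximum(non_n, 1), 0.0)
        expected = nC * nG / np.maximum(non_n, 1)
        oe = np.where(expected > 0, nCpG / np.maximum(expected, 1e-300), 0.0)
    passing = (
        (gc > config.min_gc_percent)
        & (oe > config.min_obs_exp)
        & (nN <= config.max_n_fraction * w)
        & (non_n > 0)
    )

    islands: list[CpGIsland] = []
    run_start: int | None = None
    run_end = 0
    for st, ok in zip(starts, passing):
        if not ok:
            continue
        if run_start is not None and st <= run_end:
            run_end = max(run_end, st + w)
        else:
            if run_start is not None:
                _emit(islands, s, run_start, run_end, config)
            run_start, run_end = int(st), int(st + w)
    if run_start is not None:
        _emit(islands, s, run_start, run_end, config)
    return islands


def _emit(islands: list[CpGIsland], s: str, start: int, end: int, config: CpGScanConfig) -> None:
    if end - start < config.min_island_length:
        return
    sub = s[start:end]
    islands.append(CpGIsland(start, end, gc_percent(sub), obs_exp_cpg(sub)))
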