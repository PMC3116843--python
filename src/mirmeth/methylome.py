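"""Methylated-region calling from MBD-enrichment read counts.

MBD pulldown enriches methylated DNA fragments; after sequencing and
mapping, methylated regions appear as local pileups of reads over a
genome-wide background.  This module tiles the genome into fixed
windows, models the background read count per window as Poisson with
rate ``lambda = total_reads * window_size / genome_size``, and calls a
window significant when its count reaches the smallest integer ``k*``
whose Poisson upper-tail probability falls below a Bonferroni-adjusted
level ``alpha / n_windows``.  Adjacent (or near-adjacent) significant
windows are merged into regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mirmeth.intervals import GenomicInterval

DEFAULT_WINDOW_SIZE = 500
DEFAULT_ALPHA = 0.01


@dataclass
class WindowCounts:
    """Per-window read counts for one sample over a tiled genome."""

    sample_id: str
    window_size: int
    counts: dict[GenomicInterval, int]
    total_reads: int
    genome_size: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.counts)


@dataclass
class MethylomeProfile:
    """Significant methylated regions called for one sample.

    ``regions`` maps each merged region to the maximum single-window
    read count supporting it (the BED score column on output).
    """

    sample_id: str
    threshold_reads: int
    regions: list[tuple[GenomicInterval, int]]
    lam: float = float("nan")
    alpha: float = DEFAULT_ALPHA
    chroms: frozenset[str] = frozenset()

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.regions]


def _n_windows(chrom_sizes: dict[str, int], window_size: int) -> int:
    return sum(-(-size // window_size) for size in chrom_sizes.values())


def count_reads_in_windows(
    reads: list[GenomicInterval],
    window_size: int,
    chrom_sizes: dict[str, int],
    sample_id: str = "sample",
) -> WindowCounts:
    """Tile each chromosome into ``window_size`` windows and count reads.

    Each read is assigned to exactly one window by its midpoint, so the
    window counts conserve the total read number.  A midpoint that falls
    exactly on a window boundary belongs to the right (higher-coordinate)
    window — with half-open windows ``[i*w, (i+1)*w)`` this is simply
    ``floor(midpoint / w)``.

    Raises :class:`ValueError` for reads outside the declared
    chromosome bounds, naming the offending locus.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counts: dict[GenomicInterval, int] = {}
    per_chrom: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n = -(-size // window_size)
        per_chrom[chrom] = np.zeros(n, dtype=np.int64)
    for read in reads:
        if read.chrom not in chrom_sizes:
            raise ValueError(
                f"read {read.chrom}:{read.start}-{read.end} on undeclared "
                f"chromosome {read.chrom!r}"
            )
        size = chrom_sizes[read.chrom]
        if read.end > size:
            raise ValueError(
                f"read {read.chrom}:{read.start}-{read.end} extends beyond "
                f"chromosome end ({size} bp)"
            )
        idx = int(read.midpoint // window_size)
        per_chrom[read.chrom][idx] += 1
    for chrom, size in chrom_sizes.items():
        arr = per_chrom[chrom]
        for i in range(arr.shape[0]):
            win = GenomicInterval(chrom, i * window_size, min((i + 1) * window_size, size))
            counts[win] = int(arr[i])
    return WindowCounts(
        sample_id=sample_id,
        window_size=window_size,
        counts=counts,
        total_reads=len(reads),
        genome_size=sum(chrom_sizes.values()),
        chrom_sizes=dict(chrom_sizes),
    )


def significance_threshold(
    total_reads: int,
    genome_size: int,
    window_size: int,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[int, float]:
    """Minimum read count per window indicating significant methylation.

    Background rate per window is ``lambda = total_reads * window_size /
    genome_size``; the threshold is the smallest ``k`` with
    ``P(Poisson(lambda) >= k) < alpha / n_windows`` (Bonferroni over all
    windows).  Returns ``(k_star, lambda)``.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if genome_size <= 0 or window_size <= 0:
        raise ValueError("degenerate genome: genome_size and window_size must be positive")
    n_windows = -(-genome_size // window_size)
    if n_windows == 0:
        raise ValueError("degenerate genome: zero windows")
    lam = total_reads * window_size / genome_size
    per_window_alpha = alpha / n_windows
    # P(X >= k) = sf(k - 1); walk k upward until the tail drops below level.
    k = 1
    while stats.poisson.sf(k - 1, lam) >= per_window_alpha:
        k += 1
    return k, lam


def call_regions(
    wc: WindowCounts,
    k_star: int,
    merge_gap: int = 0,
    lam: float = float("nan"),
    alpha: float = DEFAULT_ALPHA,
) -> MethylomeProfile:
    """Mark windows with count >= ``k_star`` and merge them into regions.

    Significant windows on the same chromosome separated by at most
    ``merge_gap`` bases are merged; ``merge_gap=0`` merges only
    book-ended (adjacent) windows.  Region order is deterministic:
    chromosomes sorted by name, regions by start.
    """
    if k_star < 1:
        raise ValueError("k_star must be >= 1")
    sig = sorted(
        (iv for iv, c in wc.counts.items() if c >= k_star),
        key=lambda iv: (iv.chrom, iv.start),
    )
    regions: list[tuple[GenomicInterval, int]] = []
    cur: GenomicInterval | None = None
    cur_max = 0
    for iv in sig:
        count = wc.counts[iv]
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= merge_gap:
            cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            cur_max = max(cur_max, count)
        else:
            if cur is not None:
                regions.append((cur, cur_max))
            cur, cur_max = iv, count
    if cur is not None:
        regions.append((cur, cur_max))
    return MethylomeProfile(
        sample_id=wc.sample_id,
        threshold_reads=k_star,
        regions=regions,
        lam=lam,
        alpha=alpha,
        chroms=frozenset(wc.chrom_sizes),
    )


def call_methylome(
    reads: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    alpha: float = DEFAULT_ALPHA,
    merge_gap: int = 0,
    sample_id: str = "sample",
) -> MethylomeProfile:
    """End-to-end convenience: count, threshold, and call regions."""
    wc = count_reads_in_windows(reads, window_size, chrom_sizes, sample_id=sample_id)
    k_star, lam = significance_threshold(
        wc.total_reads, wc.genome_size, window_size, alpha=alpha
    )
    return call_regions(wc, k_star, merge_gap=merge_gap, lam=lam, alpha=alpha)
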