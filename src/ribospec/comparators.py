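"""Comparator classifiers: FLOSS and ORFscore.

FLOSS compares a region's ribosome-footprint length distribution against
a reference built by pooling annotated coding regions; the score is half
the L1 distance between the two distributions (total-variation distance,
in [0, 1]; 0 = identical, 1 = disjoint).  Coding-like regions score low;
outliers are flagged per abundance bin with a Tukey upper fence.

ORFscore measures enrichment of P-sites in the annotated reading frame:
with frame counts (F1, F2, F3) and mean Fbar, the chi-square-like
statistic X = sum_i (F_i - Fbar)^2 / Fbar is reported as log2(X + 1),
negated when an out-of-frame count exceeds the in-frame count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LENGTH_RANGE = (20, 40)


@dataclass
class LengthDistribution:
    """Fragment-length fractions over a fixed nt range."""

    fractions: dict[int, float]
    total_reads: int

    @classmethod
    def from_histogram(
        cls,
        histogram: dict[int, int],
        length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    ) -> "LengthDistribution":
        lo, hi = length_range
        kept = {l: c for l, c in histogram.items() if lo <= l <= hi}
        total = sum(kept.values())
        fractions = (
            {l: c / total for l, c in sorted(kept.items())} if total else {}
        )
        return cls(fractions, total)


@dataclass
class FrameCounts:
    """P-site counts in the three codon frames relative to the start."""

    f1: int
    f2: int
    f3: int

    @property
    def total(self) -> int:
        return self.f1 + self.f2 + self.f3


def frame_counts(
    cds_counts: np.ndarray, exclude_edge_codons: bool = True
) -> FrameCounts:
    """Fold a CDS P-site count vector into frame totals.

    The first and last codon are dropped by default (initiation and
    termination pile-ups distort frame usage).
    """
    c = np.asarray(cds_counts)
    n_codons = c.size // 3
    c = c[: n_codons * 3]
    if exclude_edge_codons and n_codons > 2:
        c = c[3:-3]
    return FrameCounts(
        int(c[0::3].sum()), int(c[1::3].sum()), int(c[2::3].sum())
    )


def floss_reference(
    profiles,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> LengthDistribution:
    """Pool length histograms of annotated coding regions into the FLOSS
    reference distribution."""
    pooled: dict[int, int] = {}
    for p in profiles:
        for length, count in p.length_histogram.items():
            pooled[length] = pooled.get(length, 0) + count
    ref = LengthDistribution.from_histogram(pooled, length_range)
    if ref.total_reads == 0:
        raise ValueError("cannot build a FLOSS reference from zero reads")
    return ref


def floss_score(
    dist: LengthDistribution, ref: LengthDistribution
) -> float | None:
    """Total-variation distance between a region's length distribution
    and the reference; None (unscorable) for a zero-read region."""
    if dist.total_reads == 0:
        return None
    lengths = set(dist.fractions) | set(ref.fractions)
    return 0.5 * sum(
        abs(dist.fractions.get(l, 0.0) - ref.fractions.get(l, 0.0))
        for l in lengths
    )


class FlossFence:
    """Abundance-binned Tukey upper fence for FLOSS outlier calls.

    Coding reference points are binned by log10 read count; each bin's
    fence is Q3 + k*IQR (k default 3, "extreme outlier").  Fences are
    made monotone non-increasing in abundance (deeper regions have
    tighter length distributions) and queries interpolate between bin
    centers.
    """

    def __init__(self, centers: np.ndarray, fences: np.ndarray, k: float) -> None:
        self.centers = centers
        self.fences = fences
        self.k = k

    def __call__(self, read_count: float) -> float:
        x = np.log10(max(float(read_count), 1.0))
        return float(np.interp(x, self.centers, self.fences))

    def is_outlier(self, read_count: float, floss: float) -> bool:
        return floss > self(read_count)


def floss_outlier_cutoff(
    points,
    bin_width: float = 0.5,
    fence_multiplier: float = 3.0,
    min_per_bin: int = 10,
) -> FlossFence:
    """Fit the binned Tukey fence from coding (read_count, floss) points.

    Bins with fewer than ``min_per_bin`` points are merged into their
    left neighbour (or the next bin, at the low end).
    """
    pts = [(rc, fl) for rc, fl in points if fl is not None and rc > 0]
    if not pts:
        raise ValueError("no usable reference points")
    rc = np.log10([p[0] for p in pts])
    fl = np.asarray([p[1] for p in pts])
    lo = np.floor(rc.min() / bin_width) * bin_width
    edges = np.arange(lo, rc.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    which = np.clip(np.digitize(rc, edges) - 1, 0, edges.size - 2)

    # merge sparse bins left-to-right
    groups: list[list[int]] = []
    for b in range(edges.size - 1):
        members = list(np.flatnonzero(which == b))
        if groups and (len(members) < min_per_bin or len(groups[-1][1]) < min_per_bin):
            groups[-1][1].extend(members)
            groups[-1][0].append(b)
        else:
            groups.append([[b], members])
    centers, fences = [], []
    for bins, members in groups:
        if not members:
            continue
        vals = fl[members]
        q1, q3 = np.percentile(vals, [25, 75])
        centers.append(np.mean([(edges[b] + edges[b + 1]) / 2 for b in bins]))
        fences.append(q3 + fence_multiplier * (q3 - q1))
    centers = np.asarray(centers)
    fences = np.asarray(fences)
    # enforce monotone non-increasing fence with abundance
    fences = np.minimum.accumulate(fences)
    return FlossFence(centers, fences, fence_multiplier)


def orfscore(fc: FrameCounts) -> float | None:
    """Signed, log-scaled frame-enrichment statistic.

    Positive when the annotated frame (F1) dominates; the sign flips when
    either out-of-frame count exceeds F1.  Unscorable (None) for an
    all-zero region.
    """
    total = fc.total
    if total == 0:
        return None
    fbar = total / 3.0
    x = sum((f - fbar) ** 2 / fbar for f in (fc.f1, fc.f2, fc.f3))
    score = float(np.log2(x + 1.0))
    if fc.f2 > fc.f1 or fc.f3 > fc.f1:
        score = -score
    return score
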