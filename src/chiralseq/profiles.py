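"""Per-base pileup profiles and commutability (concordance) statistics.

A :class:`PileupProfile` holds per-position depth, mismatch, insertion and
deletion counts derived from alignments against a reference.  Profiles of a
chiral pair are compared after reversing one member's position axis
("mirrored" pairing); the headline statistic is the squared Pearson
correlation of (optionally windowed) profiles.

Event attribution is chosen to be exactly mirror-symmetric so that the
profile of coordinate-transformed alignments equals the mirrored profile of
the originals, bit for bit:

* mismatches and deletions are attributed to the reference position they
  occupy;
* an insertion lies in the gap between two reference positions and is
  anchored to the preceding base; insertions in the gaps before the first
  or after the last position of the profiled region are not counted
  (unanchorable);
* :meth:`PileupProfile.mirrored` reverses depth/mismatch/deletion arrays
  and maps each insertion gap to its mirrored gap (a reversal with a
  one-position shift).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alignment import Alignment
from .core import Interval


@dataclass
class PileupProfile:
    contig: str
    start: int
    end: int
    depth: np.ndarray
    mismatch: np.ndarray
    insertion: np.ndarray
    deletion: np.ndarray
    mapq_floor: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start

    def array(self, metric: str) -> np.ndarray:
        if metric == "indel":
            return self.insertion + self.deletion
        return getattr(self, metric.replace("ins", "insertion").replace("del", "deletion"))

    def mirrored(self, contig_length: int | None = None, rev_contig: str = "") -> "PileupProfile":
        """The same profile expressed in mirrored coordinates."""
        L = contig_length if contig_length is not None else self.end
        w = self.width
        ins_m = np.zeros_like(self.insertion)
        if w > 1:
            ins_m[: w - 1] = self.insertion[: w - 1][::-1]
        return PileupProfile(
            contig=rev_contig or self.contig,
            start=L - self.end,
            end=L - self.start,
            depth=self.depth[::-1].copy(),
            mismatch=self.mismatch[::-1].copy(),
            insertion=ins_m,
            deletion=self.deletion[::-1].copy(),
            mapq_floor=self.mapq_floor,
        )


def pileup(
    records: Iterable[Alignment],
    ref: str,
    contig: str,
    start: int = 0,
    end: int | None = None,
    mapq_floor: int = 0,
) -> PileupProfile:
    """Per-position depth and error counts from CIGAR + sequence vs reference.

    ``ref`` is the full contig sequence.  Depth counts reads whose footprint
    spans the position, including deleted positions (so error counts never
    exceed depth).  Reads below ``mapq_floor`` are excluded.
    """
    if end is None:
        end = len(ref)
    if start < 0 or end > len(ref) or start > end:
        raise ValueError(f"region [{start}, {end}) not within contig of length {len(ref)}")
    w = end - start
    depth = np.zeros(w, dtype=np.int64)
    mismatch = np.zeros(w, dtype=np.int64)
    insertion = np.zeros(w, dtype=np.int64)
    deletion = np.zeros(w, dtype=np.int64)
    for a in records:
        if not a.is_mapped or a.contig != contig or a.mapq < mapq_floor:
            continue
        rpos = a.pos
        qpos = 0
        for op, n in a.cigar:
            if op in "M=X":
                for i in range(n):
                    p = rpos + i
                    if start <= p < end:
                        depth[p - start] += 1
                        if a.seq and a.seq[qpos + i] != ref[p]:
                            mismatch[p - start] += 1
                rpos += n
                qpos += n
            elif op == "I":
                # gap between rpos-1 and rpos; anchored to the preceding base
                if start < rpos < end:
                    insertion[rpos - 1 - start] += 1
                qpos += n
            elif op in "DN":
                for i in range(n):
                    p = rpos + i
                    if start <= p < end:
                        depth[p - start] += 1
                        if op == "D":
                            deletion[p - start] += 1
                rpos += n
            elif op == "S":
                qpos += n
            # H, P consume nothing relevant
    return PileupProfile(
        contig=contig, start=start, end=end, depth=depth, mismatch=mismatch,
        insertion=insertion, deletion=deletion, mapq_floor=mapq_floor,
    )


def normalize_profile(p: PileupProfile, mode: str = "mean") -> PileupProfile:
    """Divide each per-position array by its own mean (coverage normalization).

    Arrays with zero mean other than depth are left at zero; a zero-mean
    depth is an error.
    """
    if mode == "none":
        return p
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    if p.depth.mean() == 0:
        raise ValueError("cannot normalize a profile with zero mean depth")

    def norm(arr: np.ndarray) -> np.ndarray:
        m = arr.mean()
        return arr / m if m > 0 else arr.astype(float)

    return replace(
        p,
        depth=norm(p.depth),
        mismatch=norm(p.mismatch),
        insertion=norm(p.insertion),
        deletion=norm(p.deletion),
    )


def window_means(arr: np.ndarray, window: int, step: int | None = None) -> np.ndarray:
    """Sliding-window means; default step is window / 2."""
    if window <= 0:
        raise ValueError("window must be positive")
    if window > len(arr):
        raise ValueError("window exceeds array length")
    step = step or max(1, window // 2)
    starts = range(0, len(arr) - window + 1, step)
    return np.array([arr[s : s + window].mean() for s in starts])


@dataclass(frozen=True)
class ConcordanceResult:
    r_squared: float
    pearson: float
    spearman: float
    n_points: int
    pairing: str


def correlate(x: np.ndarray, y: np.ndarray, pairing: str = "replicate") -> ConcordanceResult:
    if len(x) != len(y):
        raise ValueError(f"profile lengths differ: {len(x)} vs {len(y)}")
    pr = stats.pearsonr(x, y).statistic
    sp = stats.spearmanr(x, y).statistic
    return ConcordanceResult(
        r_squared=pr**2, pearson=pr, spearman=sp, n_points=len(x), pairing=pairing
    )


def concordance(
    p1: PileupProfile,
    p2: PileupProfile,
    pairing: str = "mirrored",
    window: int | None = 40,
    metric: str = "depth",
) -> ConcordanceResult:
    """Concordance of two profiles on a per-base or sliding-window basis.

    With ``pairing="mirrored"`` the second profile's position axis is
    reversed before comparison (chiral twins).  ``window=None`` compares
    per-base; otherwise window means with step window/2 are correlated.
    R^2 is the squared Pearson correlation.
    """
    x = p1.array(metric).astype(float)
    if pairing == "mirrored":
        p2 = p2.mirrored()
    y = p2.array(metric).astype(float)
    if len(x) != len(y):
        raise ValueError(f"profile lengths differ: {len(x)} vs {len(y)}")
    if window:
        x = window_means(x, window)
        y = window_means(y, window)
    return correlate(x, y, pairing)


def error_rates_by_feature(
    p: PileupProfile,
    features: dict[str, Sequence[Interval]],
    metric: str = "indel",
) -> dict[str, float]:
    """Error rate per feature class, normalized to the class's positional
    footprint: total events / total aligned depth over the class positions.

    Classes whose footprint has no coverage are absent from the result.
    """
    errors = p.array(metric)
    out: dict[str, float] = {}
    for label, intervals in features.items():
        mask = np.zeros(p.width, dtype=bool)
        for iv in intervals:
            if iv.start < p.start or iv.end > p.end:
                raise ValueError(f"feature interval [{iv.start}, {iv.end}) outside profiled region")
            mask[iv.start - p.start : iv.end - p.start] = True
        total_depth = int(p.depth[mask].sum())
        if not mask.any() or total_depth == 0:
            continue
        out[label] = float(errors[mask].sum()) / total_depth
    return out


def breadth_at_depth(p: PileupProfile, k: int = 30) -> float:
    """Fraction of profiled positions with depth >= k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if p.width == 0:
        return 0.0
    return float((p.depth >= k).mean())


def insert_size_distribution(records: Iterable[Alignment]) -> tuple[Counter, dict[str, float]]:
    """Histogram of absolute outer fragment distances plus summary stats.

    Uses the stored template length of mate-1 records; unpaired-only input
    is an error.
    """
    sizes = [abs(a.tlen) for a in records if a.is_paired and a.mate == 1 and a.tlen != 0]
    if not sizes:
        raise ValueError("no paired records with template length information")
    arr = np.asarray(sizes, dtype=float)
    summary = {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "n": len(arr),
    }
    return Counter(sizes), summary
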