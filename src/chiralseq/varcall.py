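"""Variant evaluation against sequin truth and score-threshold optimization.

Because every base of a synthetic sequin is known, any variant called
inside a sequin footprint is either a true positive (it matches a planted
allele) or a false positive (it does not).  This internal truth supports
three evaluations:

* detection sensitivity (detected / expected);
* quantitative accuracy — linear regression of observed on expected VAF
  over a stated range (default 1.5–100%);
* score-threshold optimization — the smallest per-score minimum values
  (AND semantics, ties pass) that exclude every sequin false positive
  while retaining the maximum number of true positives, then the maximum
  number of accompanying sample candidates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alignment import Alignment
from .core import Interval
from .design import ExpectedVariant, normalize_variant


@dataclass(frozen=True)
class VariantCall:
    contig: str
    pos: int  # 0-based fwd coordinate, normalized representation
    ref: str
    alt: str
    vaf: float | None = None
    genotype: str | None = None
    scores: dict = field(default_factory=dict)
    origin: str = "sample"  # sample | sequin

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class LabeledCall:
    call: VariantCall
    label: str  # TP | FP


def normalize_call(call: VariantCall, ref_seq: str, offset: int = 0) -> VariantCall:
    """Left-align/minimise a call against its contig sequence (``ref_seq``
    starting at contig position ``offset``)."""
    pos, ref, alt = normalize_variant(ref_seq, call.pos - offset, call.ref, call.alt)
    return VariantCall(
        contig=call.contig, pos=pos + offset, ref=ref, alt=alt, vaf=call.vaf,
        genotype=call.genotype, scores=call.scores, origin=call.origin,
    )


def label_calls(
    calls: Iterable[VariantCall],
    expected: Sequence[ExpectedVariant],
    footprints: Sequence[Interval] | None = None,
) -> list[LabeledCall]:
    """TP iff (contig, pos, ref, alt) matches an expected variant; any other
    call is FP.  With footprints given, a call outside every sequin
    footprint is an error (it cannot be truth-labeled)."""
    truth = {(e.contig, e.pos, e.ref, e.alt) for e in expected}
    labeled = []
    for c in calls:
        if footprints is not None:
            inside = any(
                iv.contig == c.contig and iv.start <= c.pos < iv.end for iv in footprints
            )
            if not inside:
                raise ValueError(
                    f"call at {c.contig}:{c.pos} lies outside every sequin footprint"
                )
        labeled.append(LabeledCall(call=c, label="TP" if c.key in truth else "FP"))
    return labeled


def sensitivity(detected: int, expected: int) -> float:
    """Fraction of expected variants detected (e.g. 85/87 -> 0.98 at 2 dp)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if detected > expected:
        raise ValueError("detected cannot exceed expected")
    return detected / expected


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def vaf_regression(
    observed: Sequence[float],
    expected: Sequence[float],
    vaf_range: tuple[float, float] = (0.015, 1.0),
) -> RegressionResult:
    """Linear regression of observed on expected VAF, restricted to the
    expected-VAF range (default 1.5–100%)."""
    lo, hi = vaf_range
    pts = [(e, o) for e, o in zip(expected, observed) if lo <= e <= hi]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points in VAF range [{lo}, {hi}], got {len(pts)}")
    ex = np.array([p[0] for p in pts])
    ob = np.array([p[1] for p in pts])
    fit = stats.linregress(ex, ob)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), n_points=len(pts),
    )


# ---------------------------------------------------------------------------
# threshold optimization


@dataclass(frozen=True)
class ThresholdRule:
    """Per-score minimum values; a call passes iff every listed score is
    >= its minimum (ties pass).  Scores absent from the rule are
    unconstrained (-inf)."""

    minimums: tuple[tuple[str, float], ...]

    def passes(self, scores: dict) -> bool:
        return all(scores[name] >= value for name, value in self.minimums)

    def as_dict(self) -> dict[str, float]:
        return dict(self.minimums)


@dataclass
class EvalSummary:
    expected_n: int = 0
    detected_n: int = 0
    tp_before: int = 0
    fp_before: int = 0
    tp_after: int = 0
    fp_after: int = 0
    sample_before: int = 0
    sample_after: int = 0
    rejects_all: bool = False

    @property
    def sensitivity(self) -> float | None:
        return self.detected_n / self.expected_n if self.expected_n else None


def optimize_thresholds(
    labeled: Sequence[LabeledCall],
    score_names: Sequence[str],
    sample_calls: Sequence[VariantCall] = (),
) -> tuple[ThresholdRule, EvalSummary]:
    """Grid-search the score thresholds that exclude all sequin FPs.

    Candidate thresholds per score are -inf plus the observed values (plus
    a reject-everything sentinel); among rules retaining zero FPs the
    optimizer maximizes retained TPs, then retained sample candidates,
    then picks the lexicographically smallest threshold vector.
    """
    for lc in labeled:
        for name in score_names:
            if name not in lc.call.scores:
                raise KeyError(f"call at {lc.call.contig}:{lc.call.pos} lacks score {name!r}")
    tp = [tuple(lc.call.scores[n] for n in score_names) for lc in labeled if lc.label == "TP"]
    fp = [tuple(lc.call.scores[n] for n in score_names) for lc in labeled if lc.label == "FP"]
    samp = [tuple(c.scores[n] for n in score_names) for c in sample_calls]
    grids = []
    for d in range(len(score_names)):
        observed = sorted({v[d] for v in itertools.chain(tp, fp, samp)})
        grids.append([-math.inf] + observed + [math.inf])

    def retained(thresholds: tuple[float, ...], vectors: list[tuple[float, ...]]) -> int:
        return sum(all(v[d] >= thresholds[d] for d in range(len(thresholds))) for v in vectors)

    best = None
    for thresholds in itertools.product(*grids):
        if retained(thresholds, fp) > 0:
            continue
        key = (-retained(thresholds, tp), -retained(thresholds, samp), thresholds)
        if best is None or key < best:
            best = key
    assert best is not None  # the all-+inf rule always rejects everything
    neg_tp, neg_samp, thresholds = best
    rule = ThresholdRule(minimums=tuple(zip(score_names, thresholds)))
    summary = EvalSummary(
        tp_before=len(tp),
        fp_before=len(fp),
        tp_after=-neg_tp,
        fp_after=0,
        sample_before=len(samp),
        sample_after=-neg_samp,
        rejects_all=(-neg_tp == 0 and -neg_samp == 0 and (tp or samp) != []),
    )
    return rule, summary


# ---------------------------------------------------------------------------
# naive pileup caller (test plumbing standing in for external callers)


def naive_pileup_caller(
    records: Iterable[Alignment],
    ref: str,
    contig: str,
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
    mapq_floor: int = 0,
) -> list[VariantCall]:
    """Call SNVs where an alternate base reaches the depth and fraction
    thresholds; VAF = alt count / depth.  Deliberately simple — used to
    exercise workflows without an external caller."""
    counts = np.zeros((len(ref), 4), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a in records:
        if not a.is_mapped or a.contig != contig or a.mapq < mapq_floor:
            continue
        rpos, qpos = a.pos, 0
        for op, n in a.cigar:
            if op in "M=X":
                for i in range(n):
                    b = a.seq[qpos + i]
                    if b in base_idx:
                        counts[rpos + i, base_idx[b]] += 1
                rpos += n
                qpos += n
            elif op == "I" or op == "S":
                qpos += n
            elif op in "DN":
                rpos += n
    calls = []
    idx_base = "ACGT"
    for pos in range(len(ref)):
        depth = int(counts[pos].sum())
        if depth < min_depth or ref[pos] not in base_idx:
            continue
        for bi in range(4):
            base = idx_base[bi]
            if base == ref[pos]:
                continue
            alt_n = int(counts[pos, bi])
            if alt_n / depth >= min_alt_fraction:
                vaf = alt_n / depth
                calls.append(
                    VariantCall(
                        contig=contig, pos=pos, ref=ref[pos], alt=base, vaf=vaf,
                        genotype="het" if vaf < 0.8 else "hom",
                        scores={"DP": float(depth), "AF": vaf},
                    )
                )
    return calls


def sensitivity_vs_depth(
    records: Sequence[Alignment],
    expected: Sequence[ExpectedVariant],
    ref: str,
    contig: str,
    fractions: Sequence[float],
    seed: int = 0,
    min_depth: int = 10,
    min_alt_fraction: float = 0.2,
) -> list[tuple[float, float]]:
    """Sensitivity after downsampling to each fraction (descending)."""
    from .reads import downsample_alignments

    truth = {(e.contig, e.pos, e.ref, e.alt) for e in expected}
    curve = []
    for frac in fractions:
        sub = downsample_alignments(records, frac, seed)
        calls = naive_pileup_caller(sub, ref, contig, min_depth, min_alt_fraction)
        detected = len({c.key for c in calls} & truth)
        curve.append((frac, sensitivity(detected, len(truth))))
    return curve
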