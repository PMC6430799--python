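"""Microsatellite instability (MSI) analysis from spanning reads.

A microsatellite's length in each sequenced molecule is measured from reads
that span the repeat locus with a minimum aligned overhang on both sides
(default 4 bp; soft-clipped bases do not count).  The measured lengths form
a histogram of offsets relative to the reference repeat length; indel
sequencing errors broaden it.  Instability appears as a modal shift or as
substantial mass one repeat unit away from the reference length.

Internal sequin controls make the call self-validating: a stable
(wild-type only) and an unstable (wild-type + one-unit mutant) sequin
mixture are measured through the same assay, and if the assay cannot
separate *them*, the patient sample's status is reported as
``insufficient_resolution`` rather than as a false negative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import Alignment
from .design import MsiLocusSpec

MIN_OVERHANG = 4


def collect_spanning_reads(
    records: Iterable[Alignment], locus: MsiLocusSpec, min_overhang: int = MIN_OVERHANG
) -> list[Alignment]:
    """Reads whose aligned reference footprint covers the locus plus
    ``min_overhang`` bases on both sides.  Clipped bases are not aligned
    and do not count toward the overhang."""
    start = locus.locus.start - min_overhang
    end = locus.locus.end + min_overhang
    if start < 0:
        raise ValueError("locus with overhang extends before contig start")
    out = []
    for a in records:
        if not a.is_mapped or a.contig != locus.locus.contig:
            continue
        if a.pos <= start and a.reference_end >= end:
            out.append(a)
    return out


def repeat_length_from_read(a: Alignment, locus: MsiLocusSpec) -> int:
    """Read bases consumed across the locus reference interval, via a CIGAR
    walk: reference width + insertions within - deletions within."""
    lo, hi = locus.locus.start, locus.locus.end
    if a.pos > lo or a.reference_end < hi:
        raise ValueError("read does not span the locus")
    consumed = 0
    rpos = a.pos
    for op, n in a.cigar:
        if op in "M=X":
            overlap = min(rpos + n, hi) - max(rpos, lo)
            if overlap > 0:
                consumed += overlap
            rpos += n
        elif op == "I":
            # insertion in the gap between rpos-1 and rpos: inside the locus
            # when the gap lies strictly within [lo, hi]
            if lo < rpos <= hi:
                consumed += n
        elif op in "DN":
            rpos += n
        # S/H consume no reference
    return consumed


@dataclass
class LengthDistribution:
    """Histogram of measured repeat lengths as offsets from the reference."""

    reference_length: int
    histogram: Counter = field(default_factory=Counter)

    @property
    def n(self) -> int:
        return sum(self.histogram.values())

    def frequency(self, offset: int) -> float:
        return self.histogram.get(offset, 0) / self.n if self.n else 0.0

    @property
    def modal_offset(self) -> int:
        """Offset with the highest count; ties break toward smaller |offset|."""
        if not self.histogram:
            raise ValueError("empty distribution")
        return max(self.histogram, key=lambda o: (self.histogram[o], -abs(o), -o))

    def secondary_mode_mass(self, unit: int) -> float:
        """Largest relative frequency exactly one repeat unit off reference."""
        return max(self.frequency(-unit), self.frequency(unit))


def length_histogram(observations: Sequence[int], reference_length: int) -> LengthDistribution:
    if not observations:
        raise ValueError("no spanning-read observations")
    hist = Counter(int(o) - reference_length for o in observations)
    return LengthDistribution(reference_length=reference_length, histogram=hist)


def measure_locus(
    records: Iterable[Alignment], locus: MsiLocusSpec, min_overhang: int = MIN_OVERHANG
) -> LengthDistribution:
    spanning = collect_spanning_reads(records, locus, min_overhang)
    lengths = [repeat_length_from_read(a, locus) for a in spanning]
    return length_histogram(lengths, locus.locus.width)


@dataclass(frozen=True)
class MsiDecision:
    status: str  # stable | unstable | insufficient_resolution
    modal_shift: int
    secondary_mode_mass: float
    control_separation: float  # unstable-sequin secondary mass minus stable's
    tau: float


def _shifted(test: LengthDistribution, control: LengthDistribution, margin: float) -> bool:
    """Decisive modal shift: the argmax moved AND the control's modal offset
    is clearly below the test's mode in the test distribution (so near-tied
    smeared histograms are not called shifted by sampling noise)."""
    if test.modal_offset == control.modal_offset:
        return False
    return test.frequency(control.modal_offset) < test.frequency(test.modal_offset) - margin


def msi_call(
    test: LengthDistribution,
    control: LengthDistribution,
    sequin_stable: LengthDistribution,
    sequin_unstable: LengthDistribution,
    unit: int,
    tau: float = 0.3,
    mode_margin: float = 0.05,
) -> MsiDecision:
    """Call MSI status with an internal-control resolution check.

    The stable/unstable sequin pair is examined first under the same
    decision metric: if the unstable mixture shows neither a decisive modal
    shift against the stable one nor secondary-mode mass >= tau at one
    repeat unit, the assay cannot resolve instability and the verdict is
    ``insufficient_resolution``.  Otherwise the test sample is unstable iff
    it shows a decisive modal shift against its matched control or
    secondary-mode mass >= tau.
    """
    for name, dist in (
        ("test", test), ("control", control),
        ("sequin_stable", sequin_stable), ("sequin_unstable", sequin_unstable),
    ):
        if dist is None or dist.n == 0:
            raise ValueError(f"missing or empty {name} distribution")
    sequin_mass = sequin_unstable.secondary_mode_mass(unit)
    separable = _shifted(sequin_unstable, sequin_stable, mode_margin) or sequin_mass >= tau
    separation = sequin_mass - sequin_stable.secondary_mode_mass(unit)
    test_mass = test.secondary_mode_mass(unit)
    shift = test.modal_offset - control.modal_offset
    if not separable:
        status = "insufficient_resolution"
    elif _shifted(test, control, mode_margin) or test_mass >= tau:
        status = "unstable"
    else:
        status = "stable"
    return MsiDecision(
        status=status,
        modal_shift=shift,
        secondary_mode_mass=test_mass,
        control_separation=separation,
        tau=tau,
    )
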