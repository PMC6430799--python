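"""Mirror (reverse-without-complement) transforms and sequence properties.

A DNA sequence read 5'->3' is chiral: reversing its nucleotide order yields a
distinct sequence (unless it is a reversal palindrome) that nevertheless shares
composition, entropy and repeat structure with the original.  This module
implements the mirror transform on sequences, whole genomes and coordinate
intervals, plus the sequence-property computations (k-mer entropy, GC windows,
tandem repeats) used to characterise chiral pairs.

Mirroring is *not* reverse complementation: ``mirror("ATGCATGC") == "CGTACGTA"``
whereas the reverse complement is ``"GCATGCAT"``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_bases(bases: str) -> None:
    for i, b in enumerate(bases):
        if b not in VALID_BASES:
            raise ValueError(f"invalid base {b!r} at position {i}")


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        _validate_bases(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


def mirror_sequence(s: NucSequence | str) -> NucSequence | str:
    """Reverse the nucleotide order of ``s`` without complementing.

    Output base ``i`` equals input base ``n - 1 - i``; N is preserved.
    Accepts and returns either a plain string or a :class:`NucSequence`
    (the latter gets a ``_rev``-suffixed id).
    """
    if isinstance(s, NucSequence):
        return NucSequence(id=s.id + "_rev", bases=s.bases[::-1])
    _validate_bases(s)
    return s[::-1]


def complement(bases: str) -> str:
    """Base-wise complement (no reversal)."""
    _validate_bases(bases)
    return bases.translate(_COMPLEMENT)


def reverse_complement(bases: str) -> str:
    return complement(bases)[::-1]


@dataclass(frozen=True)
class ContigPair:
    """A forward contig and its mirrored (chiral) twin of equal length."""

    fwd_name: str
    rev_name: str
    fwd_bases: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", len(self.fwd_bases))

    @property
    def rev_bases(self) -> str:
        return self.fwd_bases[::-1]

    def bases(self, space: str) -> str:
        return self.fwd_bases if space == "fwd" else self.rev_bases

    def name(self, space: str) -> str:
        return self.fwd_name if space == "fwd" else self.rev_name


Space = Literal["fwd", "rev"]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named contig, in fwd or rev space."""

    contig: str
    start: int
    end: int
    space: Space = "fwd"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


def build_mirrored_genome(
    genome: dict[str, str] | Iterable[NucSequence], suffix: str = "_rev"
) -> dict[str, ContigPair]:
    """Create one mirrored twin per forward contig.

    Returns a mapping from forward contig name to :class:`ContigPair`; the
    twin's name is the forward name plus ``suffix``.  A forward contig name
    already carrying the suffix, or colliding with a generated twin name,
    is rejected.
    """
    if not isinstance(genome, dict):
        genome = {s.id: s.bases for s in genome}
    names = set(genome)
    pairs: dict[str, ContigPair] = {}
    for name, bases in genome.items():
        rev_name = name + suffix
        if name.endswith(suffix):
            raise ValueError(f"contig {name!r} already carries suffix {suffix!r}")
        if rev_name in names:
            raise ValueError(f"mirrored name {rev_name!r} collides with an input contig")
        _validate_bases(bases)
        pairs[name] = ContigPair(fwd_name=name, rev_name=rev_name, fwd_bases=bases)
    return pairs


def contig_table(pairs: dict[str, ContigPair]):
    """Combined-index contig table: (name, length, namespace) rows."""
    import pandas as pd

    rows = []
    for p in pairs.values():
        rows.append((p.fwd_name, p.length, "fwd"))
        rows.append((p.rev_name, p.length, "rev"))
    return pd.DataFrame(rows, columns=["name", "length", "namespace"])


def map_interval(iv: Interval, pair: ContigPair) -> Interval:
    """Map an interval between the fwd and rev coordinate systems.

    ``[s, e)`` in one space corresponds to ``[L - e, L - s)`` in the other;
    width is preserved and the map is an involution.
    """
    L = pair.length
    if iv.end > L:
        raise ValueError(f"interval [{iv.start}, {iv.end}) exceeds contig length {L}")
    expected = pair.name(iv.space)
    if iv.contig != expected:
        raise ValueError(f"interval contig {iv.contig!r} is not the {iv.space} member {expected!r}")
    other: Space = "rev" if iv.space == "fwd" else "fwd"
    return Interval(contig=pair.name(other), start=L - iv.end, end=L - iv.start, space=other)


def kmer_entropy(s: NucSequence | str, k: int) -> float:
    """Shannon entropy (bits) of the k-mer frequency distribution of ``s``.

    k-mers containing N are excluded.  Mirroring a sequence permutes its
    k-mer multiset bijectively (each k-mer maps to its reversal), so entropy
    is conserved under the mirror transform.
    """
    bases = s.bases if isinstance(s, NucSequence) else s
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(bases) < k:
        raise ValueError(f"sequence length {len(bases)} < k={k}")
    counts = Counter(
        bases[i : i + k] for i in range(len(bases) - k + 1) if "N" not in bases[i : i + k]
    )
    if not counts:
        return 0.0
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def gc_windows(s: NucSequence | str, window: int, step: int = 1) -> np.ndarray:
    """GC fraction in sliding windows; N bases are excluded from the denominator.

    Windows start at 0, window, ... stepping by ``step``; a window with no
    non-N bases yields NaN.
    """
    bases = s.bases if isinstance(s, NucSequence) else s
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if window > len(bases):
        raise ValueError(f"window {window} exceeds sequence length {len(bases)}")
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    out = []
    for i in range(0, len(bases) - window + 1, step):
        gc = int(is_gc[i : i + window].sum())
        denom = window - int(is_n[i : i + window].sum())
        out.append(gc / denom if denom else math.nan)
    return np.asarray(out)


def gc_fraction(s: NucSequence | str) -> float:
    bases = s.bases if isinstance(s, NucSequence) else s
    return gc_windows(bases, window=len(bases), step=1)[0]


def _min_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True if the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class RepeatAnnotation:
    """A maximal tandem repeat run: ``unit`` repeated ``copies`` times."""

    interval: Interval
    unit: str
    copies: int

    @property
    def total_len(self) -> int:
        return self.copies * len(self.unit)

    @property
    def canonical_unit(self) -> str:
        """Smallest rotation of the unit; label for aggregating runs."""
        return _min_rotation(self.unit)


def find_simple_repeats(
    s: NucSequence | str,
    min_total_len: int,
    max_unit: int = 6,
    contig: str = "",
    space: Space = "fwd",
) -> list[RepeatAnnotation]:
    """Maximal tandem runs of 1..max_unit nt units with total length >= threshold.

    Runs never span N.  Only primitive units are reported (an (AC)n run is
    not re-reported as (ACAC)m).  Each maximal periodic region is reported
    from its leftmost position, so at most ``|unit| - 1`` trailing bases of
    a partial copy are trimmed; :attr:`RepeatAnnotation.canonical_unit`
    gives the rotation-invariant label.  A run wholly contained in a longer
    reported run is suppressed.
    """
    bases = s.bases if isinstance(s, NucSequence) else s
    if isinstance(s, NucSequence) and not contig:
        contig = s.id
    if min_total_len <= 0 or max_unit <= 0:
        raise ValueError("parameters must be positive")
    n = len(bases)
    runs: list[RepeatAnnotation] = []
    for u in range(1, max_unit + 1):
        j = u
        while j <= n:
            # extend maximal region with period u starting at j - u
            start = j - u
            k = j
            while k < n and bases[k] == bases[k - u] and bases[k] != "N":
                k += 1
            region_len = k - start
            if region_len >= 2 * u and "N" not in bases[start : start + u]:
                copies = region_len // u
                unit = bases[start : start + u]
                if copies * u >= min_total_len and _is_primitive(unit):
                    iv = Interval(contig=contig, start=start, end=start + copies * u, space=space)
                    runs.append(RepeatAnnotation(interval=iv, unit=unit, copies=copies))
            j = max(k + 1, j + 1) if region_len >= 2 * u else j + 1
    # suppress runs strictly contained in a longer reported run
    kept = []
    for r in runs:
        contained = any(
            o is not r
            and o.interval.start <= r.interval.start
            and o.interval.end >= r.interval.end
            and o.total_len > r.total_len
            for o in runs
        )
        if not contained:
            kept.append(r)
    kept.sort(key=lambda r: (r.interval.start, len(r.unit)))
    return kept


def homopolymer_spectrum(s: NucSequence | str) -> Counter:
    """Multiset of (base, run length) for all maximal homopolymer runs."""
    bases = s.bases if isinstance(s, NucSequence) else s
    spectrum: Counter = Counter()
    i = 0
    while i < len(bases):
        j = i
        while j < len(bases) and bases[j] == bases[i]:
            j += 1
        spectrum[(bases[i], j - i)] += 1
        i = j
    return spectrum


def repeat_run_lengths(bases: str, max_unit: int = 3) -> np.ndarray:
    """Per-position length of the longest tandem repeat run covering each position.

    Used as the (mirror-invariant) context variable for slippage error models:
    position ``i`` of the mirrored sequence has the same value as position
    ``n - 1 - i`` of the original.
    """
    n = len(bases)
    out = np.ones(n, dtype=np.int32)
    for u in range(1, max_unit + 1):
        j = u
        while j <= n:
            start = j - u
            k = j
            while k < n and bases[k] == bases[k - u] and bases[k] != "N":
                k += 1
            region_len = k - start
            if region_len >= 2 * u:
                out[start:k] = np.maximum(out[start:k], region_len)
                j = k + 1
            else:
                j += 1
    return out
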