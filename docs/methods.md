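# Methods

## The mirror transform and its invariants

The core primitive is the mirror: `mirror(s)[i] = s[n-1-i]`, with no
complementation and `N` preserved. It is an involution on sequences,
genomes and intervals (`[s,e) ↔ [L-e, L-s)`), and it conserves every
statistic that is a function of an unordered or reversal-symmetric view
of the sequence: base composition, GC fraction, the homopolymer length
spectrum, and k-mer entropy (the k-mer multiset maps bijectively onto its
reversal image). These conservation laws are enforced as property tests;
the interval map is checked exhaustively as a width-preserving bijection
for all contig lengths up to 50.

Mirrored contigs are named by a configurable suffix (default `_rev`,
collision-checked), and namespace assignment during partitioning can be
overridden by an explicit contig table for nonstandard builds.

## Pileup event attribution (exact mirror symmetry)

Per-position profiles hold depth, mismatch, insertion and deletion
counts. Attribution rules are chosen so that the profile of
coordinate-transformed alignments equals the mirrored profile of the
originals **bit for bit**, which the test suite checks on randomized
simulated alignment sets:

- mismatches and deletions are attributed to the reference position they
  occupy; depth counts any read whose aligned footprint spans the
  position, including deleted positions, so error counts never exceed
  depth;
- an insertion lives in the *gap* between two reference positions and is
  anchored to the preceding base. Gaps before the first and after the
  last profiled position have no symmetric anchor and are not counted.
  Mirroring a profile maps gap `g` to gap `L - g`, which is a reversal
  of the insertion array with a one-position shift; `PileupProfile.mirrored`
  implements exactly this, and the coordinate transform of an alignment
  reverses its CIGAR (clips swap ends) and reverses sequence and
  qualities without complementation.

Transformed records drop alignment-specific tags (NM, MD) that would be
stale and keep the rest (e.g. read group). Mate positions transform
exactly when mates are processed together (`transform_alignments`); a
lone record assumes an equal-span mate. Flipped proper pairs map to the
forward genome with mirrored pair orientation (innie ↔ outie); proper-pair
flags are therefore never used downstream.

Concordance is squared Pearson correlation of (optionally windowed)
profiles — for simple pairs this equals simple-regression R² — computed
per-base or over 40 bp sliding windows with step = window/2 (the window
size is standard for this analysis; the step is our choice). Profile
normalization divides each array by its own mean; which normalization the
"normalized coverage" style of plot uses is not standardized, and
per-contig mean is our choice.

## Sequin design

Molecules default to 1.8 kb regions centred on an anchor feature (ties
toward the lower coordinate; a region that would overrun its contig is
an error rather than being clamped). Alleles are applied to the forward
region sequence left-to-right with cumulative offset shifts (overlaps
rejected), then the whole molecule is mirrored. Variant records move
between the mirrored coordinate systems by reversing ref/alt strings and
re-anchoring at `L - pos - |ref|`, followed by VCF-style left
normalization; the projection commutes with sequence editing (checked on
hundreds of random indels) and is an involution up to normalization.

Mixtures:

- genotype mixture: het → ref+alt molecules at equal mass (VAF 0.5);
  hom → alt molecule alone (VAF 1.0); sites carry equal total mass.
- VAF ladder: level *i* at VAF 2^−(i−1). Eleven levels reach
  2^−10 ≈ 0.0977%, i.e. 0.1% at one decimal; 11 is therefore the default
  depth for a 100%→0.1% ladder, configurable. Variants are assigned round-robin and the
  per-level occupancy checked against bounds (default 7–9, matching a
  94-variant panel). The matched "normal" mixture carries only the
  wild-type molecules.
- MSI: one wild-type molecule per locus (stable), plus a mutant differing
  by one repeat unit mixed at `mutant_fraction` (unstable). The mixing
  ratio is not something the mixture description pins down; 0.5 is the
  default and it is an explicit parameter.

Primer mirroring is realized as complement-and-role-swap:
`(pf, pr) → (complement(pr), complement(pf))`. This is the unique recipe
under which the mirrored pair amplifies exactly the mirrored interval,
which the in-silico PCR check enforces on both templates; a plain string
reversal of each primer would not anneal to the mirrored template. Both
the input and the mirrored design must pass in-silico PCR (exact forward
primer match, reverse-complemented reverse primer downstream within a
product-size cap).

## Variant evaluation and threshold optimization

Calls are labeled TP iff (contig, pos, ref, alt) matches a manifest
variant after left normalization — exact allele identity, no
distance-window matching. Any other call inside a sequin footprint is a
FP; a "sequin" call outside every footprint is an input error.

The threshold rule is a per-score minimum with AND semantics and ties
passing (a call passes iff every listed score ≥ its minimum). Because
retention only changes when a threshold crosses an observed score, the
optimizer searches the grid of {−∞} ∪ observed values ∪ {+∞} per
dimension, keeps rules retaining zero FPs, and maximizes retained TPs,
then retained sample candidates, then takes the lexicographically
smallest threshold vector — a deterministic optimum that the tests verify
against independent exhaustive search on random instances. The rule
generalizes to any number of named scores; per-variant-class (SNV vs
indel) optimization is available by simply fitting on a filtered call
subset. If only the all-rejecting rule is feasible the result is flagged
(`rejects_all`).

VAF accuracy is summarized by linear regression of observed on expected
VAF restricted to expected VAF ≥ 1.5% (quantification below that is
depth-limited at typical panel depths).

The bundled `naive_pileup_caller` (SNVs from base counts at thresholded
depth/fraction) exists to exercise workflows end-to-end; consuming VCFs
from real callers is the production path, and no external caller is a
dependency.

## MSI decision rule

Repeat length per spanning read is the number of read bases the CIGAR
consumes across the locus interval (reference width + insertions within −
deletions within). Reads must cover the locus with ≥ 4 bp aligned
overhang on both sides; clipped bases do not count. The CIGAR walk is
deterministic and alignment-consistent, with the known limitation that an
indel placed by the aligner just outside the locus boundary is not
re-attributed.

Offsets relative to the reference length form a histogram. The decision
needs an explicit rule where visual histogram comparison is the
tradition, so the rule and its parameters are exposed:

- *secondary-mode mass*: the larger of the relative frequencies at
  offsets ±1 repeat unit; threshold `tau` = 0.3.
- *decisive modal shift*: the argmax offset differs from the control's
  **and** the control's modal offset is at least `mode_margin` = 0.05
  relative frequency below the test's mode within the test distribution.
  The margin exists because a 50:50 wild-type/mutant mixture produces
  near-tied peaks whose argmax flips with sampling noise; without it the
  verdict would depend on which of two equal-height bins won a tie.
- resolution check first: if the unstable sequin mixture shows neither a
  decisive shift against the stable one nor mass ≥ tau, the assay cannot
  resolve a one-unit event and the verdict is `insufficient_resolution`
  regardless of what the patient sample shows. Otherwise the sample is
  unstable iff it shows a decisive shift against its matched control or
  mass ≥ tau.

The decision depends only on relative frequencies, hence is invariant to
read-count scaling.

## Synthetic data

The simulator emulates the statistical structure the method relies on,
not a specific instrument:

- **Genomes**: seeded i.i.d. bases at a target GC, with non-overlapping
  planted tandem repeats; fully reproducible (single generator, fixed
  draw order).
- **Reads**: fragments drawn per molecule ∝ abundance × length
  (equal-abundance, equal-length molecules get equal coverage),
  truncated-normal fragment lengths, uniform starts, both strands
  equiprobable; paired 100 nt reads by default. Truth alignments carry
  the injected-error CIGARs and an origin tag, so pileup and MSI tests
  need no external aligner. Base qualities are a constant Q40; empirical
  quality-score profiles are out of scope.
- **Errors**: per-base mismatch rate plus an indel rate scaled by the
  local repeat context, `indel_rate × (1 + slippage × (run − 1))` capped
  at 0.5, where `run` is the length of the longest tandem run (unit ≤ 3)
  covering the position. The context is mirror-invariant by construction,
  which makes error injection mirror-symmetric — the structural
  assumption behind commutability, here explicit and testable. Inserted
  bases duplicate the current reference base (slippage-like).

Presets (mismatch / indel / slippage): `error_free` 0/0/0; `pcr_free`
0.002/0.0008/0.2 — low-indel chemistry; `standard` 0.003/0.004/1.0 — a
PCR-amplified preparation whose slippage at a 25 nt homopolymer reaches
~10% per base, enough to smear microsatellite length measurements as
heavily degraded libraries do; `nanopore_like` 0.03/0.05/0.3 —
indel-dominated long reads. These rates were fixed once as qualitatively
realistic regimes for their library types.

The mirror benchmark builds 8 × 1.8 kb random templates with repeat runs
of unit 1–3 and total length 8–24 nt planted at template-specific
positions (spacing drawn per template), mirrors them, and simulates reads
over all 16 sequences at equal abundance. Template-specific planting
matters: it is what makes *unpaired* profile correlation vanish while
mirrored pairs stay concordant, mimicking unrelated genome regions.

Reads from molecules that differ from the reference by designed alleles
are re-expressed against the reference by composing their CIGAR with the
molecule's edit script (`lift_to_reference`), so a read crossing the MSI
mutant's deleted unit carries the expected deletion operation.

## Problem sizes and what the tests show

Default test/acceptance scales: mirror benchmark 8 × 1.8 kb at 200×
(~57k read pairs); pileup-mirror identity on 100 random sets of ~120–300
nt at 6×; MSI at 300× pooled coverage (~200–500 spanning reads per
mixture); ladder recovery with 94 variants at 1000× binomial sampling;
optimizer oracle on 200 instances of ≤ 30 calls. These sizes make the
whole suite run in well under a minute while leaving the statistical
margins wide (the benchmark concordance sits near R² ≈ 0.97 against a
0.8 bound; unpaired near 0 against a 0.05 bound).

Passing these tests shows the *pipeline arithmetic and the statistical
logic* are correct under a mirror-symmetric error process. It does not
show that any particular instrument's errors are mirror-symmetric, that
alignment of real reads to a combined index is as clean as exact-match
assignment, or that real library preparations match the preset rates —
those are empirical properties of the assay that the controls themselves
are designed to measure.

## Other design choices and limitations

- Downsampling retains read *pairs* jointly via a seeded hash of the read
  id: order-independent, pair-coherent, and monotone (the retained set at
  a smaller fraction is a subset of that at a larger one). Whether
  per-read or per-pair downsampling is preferable is a judgement call;
  per-pair preserves pairing invariants.
- Repeat finding reports maximal tandem runs of primitive units from
  their leftmost position (at most unit−1 trailing bases of a partial
  copy are trimmed); `canonical_unit` (smallest rotation) is the
  aggregation label. Runs never span N; contained runs are suppressed.
- `extract_region` errors rather than clamps at contig edges; a region
  landing exactly on an edge is legal.
- Coordinates are 0-based half-open everywhere in memory; 1-based only
  inside SAM/VCF text, handled by pysam.
- Re-alignment of flipped FASTQ is delegated to an external aligner in
  production; tests use simulator truth and an exact-match assigner, so
  no aligner is a build dependency.
- Run reports are pydantic models; `report_schema()` publishes their
  JSON schema, and reports are pure functions of (inputs, config, seed).
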