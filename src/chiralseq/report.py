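"""End-to-end workflow orchestration and machine-readable run reports.

Two workflows mirror how the chiral controls are used in practice:

* :func:`run_germline_eval` — spike a genotype mixture into a simulated
  sample, align (simulated truth), partition by namespace, transform the
  chiral alignments into fwd coordinates, downsample to matched coverage,
  call variants with the built-in naive caller, and score sensitivity and
  VAF accuracy against the mixture manifest.
* :func:`run_somatic_eval` — optimize score thresholds on truth-labeled
  sequin calls so that all false positives are excluded, then apply the
  rule to the accompanying sample's candidates.

Reports are pure functions of (inputs, config, seed): rerunning with the
same seed reproduces them bit for bit.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .core import Interval, build_mirrored_genome
from .design import (
    AlleleSpec,
    VariantDesign,
    design_genotype_mixture,
)
from .profiles import pileup
from .reads import downsample_alignments, partition_alignments
from .sim import simulate_genome, simulate_reads, SimGenomeSpec
from .varcall import (
    LabeledCall,
    VariantCall,
    label_calls,
    naive_pileup_caller,
    optimize_thresholds,
    sensitivity,
    vaf_regression,
)


class RunReport(BaseModel):
    """Machine-readable record of one workflow run."""

    tool: str = "chiralseq"
    version: str = __version__
    workflow: str
    seed: int
    config: dict[str, Any] = Field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = Field(default_factory=dict)


def report_schema() -> dict:
    """The published JSON schema for run reports."""
    return RunReport.model_json_schema()


GERMLINE_DEFAULTS: dict[str, Any] = {
    "n_variants": 12,
    "region_length": 1800,
    "coverage": 60.0,
    "chiral_coverage": 120.0,
    "error_model": "error_free",
    "read_length": 100,
    "min_depth": 8,
    "min_alt_fraction": 0.2,
    "suffix": "_rev",
}


def run_germline_eval(config: dict[str, Any] | None = None, seed: int = 0) -> RunReport:
    """Simulated germline workflow: design -> sequence -> partition ->
    transform -> downsample -> call -> label -> report.

    The sample genome is one contig tiled with non-overlapping regions,
    each carrying a single SNV (genotypes alternating het/hom); the chiral
    mixture is the matching genotype design.  Variant positions are planted
    deterministically; reads and errors are seeded by ``seed``.
    """
    cfg = dict(GERMLINE_DEFAULTS)
    cfg.update(config or {})
    rng = np.random.default_rng(seed)
    n = int(cfg["n_variants"])
    rlen = int(cfg["region_length"])
    contig = "chr1"
    genome, _ = simulate_genome(
        SimGenomeSpec(contigs=((contig, n * rlen, 0.45),), seed=int(rng.integers(2**31)))
    )
    seq = genome[contig]
    pairs = build_mirrored_genome({contig: seq}, suffix=cfg["suffix"])
    pair = pairs[contig]

    designs = []
    for i in range(n):
        region = Interval(contig=contig, start=i * rlen, end=(i + 1) * rlen, space="fwd")
        offset = rlen // 2
        ref_base = seq[region.start + offset]
        alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        designs.append(
            VariantDesign(
                name=f"v{i:03d}",
                region=region,
                region_seq=seq[region.start : region.end],
                allele=AlleleSpec(kind="SNV", fwd_offset=offset, ref=ref_base, alt=alt_base),
                genotype="het" if i % 2 else "hom",
            )
        )
    molecules, manifest = design_genotype_mixture(designs)

    human = simulate_reads(
        {contig: seq},
        coverage=float(cfg["coverage"]),
        read_length=int(cfg["read_length"]),
        error_model=cfg["error_model"],
        seed=int(rng.integers(2**31)),
        qname_prefix="hum",
    )
    # sequin reads: simulate from molecule sequences, then place the truth
    # alignments onto the rev contig at the mirrored source interval
    mol_seqs = {m.id: m.bases for m in molecules}
    mol_shift = {m.id: pair.length - m.source.end for m in molecules}
    chiral_raw = simulate_reads(
        mol_seqs,
        abundances=manifest.entries,
        coverage=float(cfg["chiral_coverage"]),
        read_length=int(cfg["read_length"]),
        error_model=cfg["error_model"],
        seed=int(rng.integers(2**31)),
        qname_prefix="seq",
    )
    rev_name = pair.rev_name
    chiral = [
        a.copy(
            contig=rev_name,
            pos=a.pos + mol_shift[a.tags["XO"]],
            mate_contig=rev_name,
            mate_pos=a.mate_pos + mol_shift[a.tags["XO"]],
            tags={**a.tags, "XO": rev_name},
        )
        for a in chiral_raw
    ]
    for a in human:
        a.tags["XO"] = contig

    part = partition_alignments(human + chiral, suffix=cfg["suffix"])
    if len(part.human) + len(part.chiral) + len(part.unmapped) != len(human) + len(chiral):
        raise RuntimeError("partition stage lost records")

    from .reads import transform_alignments

    transformed = transform_alignments(part.chiral, pair)
    human_cov = float(pileup(part.human, seq, contig).depth.mean())
    chiral_cov = float(pileup(transformed, seq, contig).depth.mean())
    fraction = min(1.0, human_cov / chiral_cov) if chiral_cov > 0 else 1.0
    downsampled = downsample_alignments(transformed, fraction, seed=seed)
    down_cov = float(pileup(downsampled, seq, contig).depth.mean())

    calls = naive_pileup_caller(
        downsampled, seq, contig,
        min_depth=int(cfg["min_depth"]),
        min_alt_fraction=float(cfg["min_alt_fraction"]),
    )
    truth_keys = {(e.contig, e.pos, e.ref, e.alt) for e in manifest.expected_variants}
    detected = len({c.key for c in calls} & truth_keys)
    sn = sensitivity(detected, len(truth_keys))
    by_key = {c.key: c for c in calls}
    obs, exp = [], []
    for e in manifest.expected_variants:
        c = by_key.get((e.contig, e.pos, e.ref, e.alt))
        if c is not None and c.vaf is not None:
            obs.append(c.vaf)
            exp.append(e.vaf)
    reg = vaf_regression(obs, exp, vaf_range=(0.015, 1.0)) if len(obs) >= 3 else None

    return RunReport(
        workflow="germline_eval",
        seed=seed,
        config=cfg,
        stages={
            "partition": {
                "counts": part.counts,
                "cross_alignment": part.cross_alignment,
            },
            "downsample": {
                "fraction": fraction,
                "human_coverage": human_cov,
                "chiral_coverage": chiral_cov,
                "downsampled_coverage": down_cov,
            },
            "variants": {
                "expected_n": len(truth_keys),
                "detected_n": detected,
                "sensitivity": round(sn, 2),
                "sensitivity_exact": sn,
                "vaf_regression": (
                    {"slope": reg.slope, "intercept": reg.intercept, "r_squared": reg.r_squared,
                     "n_points": reg.n_points}
                    if reg
                    else None
                ),
            },
        },
    )


SOMATIC_DEFAULTS: dict[str, Any] = {
    "n_tp": 60,
    "n_fp": 60,
    "n_sample": 150,
    "score_names": ["QSS", "SomaticEVS"],
}


def _synthetic_somatic_calls(
    cfg: dict[str, Any], rng: np.random.Generator
) -> tuple[list[LabeledCall], list[VariantCall]]:
    """Score distributions emulating a somatic caller's output: true calls
    score higher on both axes than artifacts, with overlap."""
    names = list(cfg["score_names"])

    def mk(kind: str, i: int, mus: tuple[float, float], sds: tuple[float, float]) -> VariantCall:
        scores = {n: float(rng.normal(mu, sd)) for n, mu, sd in zip(names, mus, sds)}
        return VariantCall(
            contig="sequin" if kind != "sample" else "chr1",
            pos=i, ref="A", alt="C", scores=scores,
            origin="sequin" if kind != "sample" else "sample",
        )

    labeled = [
        LabeledCall(call=mk("tp", i, (60.0, 14.0), (20.0, 3.0)), label="TP")
        for i in range(int(cfg["n_tp"]))
    ] + [
        LabeledCall(call=mk("fp", 1000 + i, (18.0, 6.0), (10.0, 2.5)), label="FP")
        for i in range(int(cfg["n_fp"]))
    ]
    sample = [mk("sample", 2000 + i, (40.0, 10.0), (25.0, 5.0)) for i in range(int(cfg["n_sample"]))]
    return labeled, sample


def run_somatic_eval(
    config: dict[str, Any] | None = None,
    seed: int = 0,
    labeled_sequin: Sequence[LabeledCall] | None = None,
    sample_calls: Sequence[VariantCall] | None = None,
) -> RunReport:
    """Optimize score thresholds on sequin calls; apply them to the sample.

    Call sets may be supplied directly (e.g. parsed from caller VCFs); when
    absent, a seeded synthetic instance stands in, since re-implementing an
    external somatic caller is out of scope.
    """
    cfg = dict(SOMATIC_DEFAULTS)
    cfg.update(config or {})
    rng = np.random.default_rng(seed)
    if labeled_sequin is None or sample_calls is None:
        labeled_sequin, sample_calls = _synthetic_somatic_calls(cfg, rng)
    names = list(cfg["score_names"])
    for lc in labeled_sequin:
        for nm in names:
            if nm not in lc.call.scores:
                raise KeyError(f"sequin call lacks score {nm!r}")
    rule, summary = optimize_thresholds(labeled_sequin, names, sample_calls)
    retained_fp = sum(
        1 for lc in labeled_sequin if lc.label == "FP" and rule.passes(lc.call.scores)
    )
    if retained_fp != 0:
        raise RuntimeError("optimized rule retained sequin false positives")
    return RunReport(
        workflow="somatic_eval",
        seed=seed,
        config={k: v for k, v in cfg.items()},
        stages={
            "optimize": {
                "thresholds": rule.as_dict(),
                "tp_before": summary.tp_before,
                "tp_after": summary.tp_after,
                "fp_before": summary.fp_before,
                "fp_after": summary.fp_after,
                "rejects_all": summary.rejects_all,
            },
            "apply": {
                "sample_before": summary.sample_before,
                "sample_after": summary.sample_after,
            },
        },
    )
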