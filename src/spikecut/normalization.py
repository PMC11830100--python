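"""Spike-in calibration of CUT&RUN libraries.

Two schemes are implemented.  The primary one rescales the IgG control to
each experimental sample via the spike-in/genome read ratios:

    ratio_expr  = expr_spike / expr_genome
    ratio_ctrl  = ctrl_spike / ctrl_genome
    size_factor = ratio_ctrl / ratio_expr
    norm_ctrl_genome = size_factor * ctrl_genome

The alternative ("aimed-reads") scheme — useful when the ratio scheme
yields too few peaks for an antibody — rescales every sample by its
sequencing-target attainment relative to the cohort, then by its
genome/spike ratios against the control:

    sample_totalReads = sample_aimedReads / sample_totalReadsProcessed
    all_totalReads    = all_aimedReads / all_totalReadsProcessed
    norm_totalReads   = sample_genome * sample_totalReads / all_totalReads
    ratio_genome      = sample_genome / ctrl_genome
    ratio_spike       = sample_spike / ctrl_spike
    norm_sample_genome = norm_totalReads / (ratio_genome / ratio_spike)

The coverage-comparison scale S applied to the control when forming
log2-ratio tracks is ratio_expr / ratio_ctrl = 1 / size_factor.

Zero counts in any denominator are an error: the formulas are undefined
there and a silent pseudocount would corrupt the factors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AlignmentCounts

__all__ = [
    "SizeFactors",
    "AltSample",
    "AltNormFactors",
    "CoverageScale",
    "compute_size_factors",
    "compute_alt_norm",
    "coverage_scale",
]


@dataclass(frozen=True)
class SizeFactors:
    sample_id: str
    ratio_expr: float
    ratio_ctrl: float
    size_factor: float
    norm_ctrl_genome: float


@dataclass(frozen=True)
class AltSample:
    """Inputs for the aimed-reads scheme: counts plus sequencing targets."""

    counts: AlignmentCounts
    aimed_reads: float
    processed_reads: float


@dataclass(frozen=True)
class AltNormFactors:
    sample_id: str
    sample_total_reads: float
    all_total_reads: float
    norm_total_reads: float
    ratio_genome: float
    ratio_spike: float
    norm_sample_genome: float


@dataclass(frozen=True)
class CoverageScale:
    """Scale S applied to control coverage in 1:S track comparisons."""

    S: float


def _require_positive(**named_counts: float) -> None:
    for name, value in named_counts.items():
        if value <= 0:
            raise ValueError(f"{name} is {value}; spike-in normalization requires it > 0")


def compute_size_factors(expr: AlignmentCounts, ctrl: AlignmentCounts) -> SizeFactors:
    """Size factor rescaling the IgG control to an experimental sample."""
    _require_positive(
        expr_genome=expr.genome_reads,
        expr_spike=expr.spike_reads,
        ctrl_genome=ctrl.genome_reads,
        ctrl_spike=ctrl.spike_reads,
    )
    ratio_expr = expr.spike_reads / expr.genome_reads
    ratio_ctrl = ctrl.spike_reads / ctrl.genome_reads
    size_factor = ratio_ctrl / ratio_expr
    return SizeFactors(
        sample_id=expr.sample_id,
        ratio_expr=ratio_expr,
        ratio_ctrl=ratio_ctrl,
        size_factor=size_factor,
        norm_ctrl_genome=size_factor * ctrl.genome_reads,
    )


def coverage_scale(expr: AlignmentCounts, ctrl: AlignmentCounts) -> CoverageScale:
    """S = ratio_expr / ratio_ctrl, the reciprocal of the size factor."""
    sf = compute_size_factors(expr, ctrl)
    return CoverageScale(S=sf.ratio_expr / sf.ratio_ctrl)


def compute_alt_norm(samples: list[AltSample], ctrl: AlignmentCounts) -> list[AltNormFactors]:
    """Aimed-reads normalization of each sample against the control.

    Cohort totals (all_aimedReads, all_totalReadsProcessed) are the sums
    over the listed samples; include the control in ``samples`` if it is
    part of the sequencing cohort.  Each listed sample — the control
    included, should it appear — is normalized with its own genome/spike
    counts in the sample role and the control's counts in the control role.
    """
    if not samples:
        raise ValueError("compute_alt_norm needs at least one sample")
    _require_positive(ctrl_genome=ctrl.genome_reads, ctrl_spike=ctrl.spike_reads)
    all_aimed = sum(s.aimed_reads for s in samples)
    all_processed = sum(s.processed_reads for s in samples)
    _require_positive(all_totalReadsProcessed=all_processed, all_aimedReads=all_aimed)
    all_total_reads = all_aimed / all_processed
    out = []
    for s in samples:
        _require_positive(
            sample_aimedReads=s.aimed_reads,
            sample_totalReadsProcessed=s.processed_reads,
            sample_genome=s.counts.genome_reads,
            sample_spike=s.counts.spike_reads,
        )
        sample_total_reads = s.aimed_reads / s.processed_reads
        norm_total_reads = s.counts.genome_reads * sample_total_reads / all_total_reads
        ratio_genome = s.counts.genome_reads / ctrl.genome_reads
        ratio_spike = s.counts.spike_reads / ctrl.spike_reads
        out.append(
            AltNormFactors(
                sample_id=s.counts.sample_id,
                sample_total_reads=sample_total_reads,
                all_total_reads=all_total_reads,
                norm_total_reads=norm_total_reads,
                ratio_genome=ratio_genome,
                ratio_spike=ratio_spike,
                norm_sample_genome=norm_total_reads / (ratio_genome / ratio_spike),
            )
        )
    return out
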