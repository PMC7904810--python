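"""TERRA expression and telomere/satellite ChIP enrichment.

TERRA (telomeric repeat-containing lncRNA) is quantified from RNA reads
passing the 14-repeats-per-100-bp rule, counted regardless of mapping
position and normalized per million total reads.

ChIP enrichment compares the fraction of repeat-class reads in the IP with
the fraction in the input library::

    log2_enrichment = log2( (repeat_IP / mapped_IP) / (repeat_input / mapped_input) )

where the repeat class is telomere (8 repeats per 100 bp), SatII or SatIII
(canonical-motif substring). Repeat numerators scan all records including
unmapped ones; denominators count mapped, non-duplicate reads only.
Samples failing the fraction-of-reads-in-peaks QC (FRiP below 1 %) are
flagged excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import AlignmentRecord, Config
from .telomere_reads import is_satellite, is_telomeric_per100bp


@dataclass(slots=True)
class TerraResult:
    sample_id: str
    terra_reads: int
    total_reads: int
    terra_per_million: float


@dataclass(slots=True)
class EnrichmentResult:
    sample_id: str
    mark: str
    repeat_class: str  # telomere | satII | satIII
    ip_repeat_reads: int
    ip_mapped_total: int
    input_repeat_reads: int
    input_mapped_total: int
    log2_enrichment: Optional[float]
    frip: Optional[float] = None
    excluded: bool = False
    reason: Optional[str] = None


def terra_quantify(
    records: Sequence[AlignmentRecord],
    sample_id: str = "",
    cfg: Config | None = None,
) -> TerraResult:
    """Count TERRA reads (>= 14 repeats per 100 bp, any mapping state) per
    million total non-duplicate reads."""
    cfg = cfg or Config()
    total = 0
    terra = 0
    for rec in records:
        if rec.is_duplicate:
            continue
        total += 1
        if is_telomeric_per100bp(
            rec.seq, cfg.rna_rt_per_100bp, cfg.hexamer_patterns, cfg.count_overlapping
        ):
            terra += 1
    if total == 0:
        raise ValueError("empty read set")
    return TerraResult(
        sample_id=sample_id,
        terra_reads=terra,
        total_reads=total,
        terra_per_million=terra / total * 1e6,
    )


def _repeat_predicate(repeat_class: str, rt: float, cfg: Config):
    if repeat_class == "telomere":
        return lambda seq: is_telomeric_per100bp(
            seq, rt, cfg.hexamer_patterns, cfg.count_overlapping
        )
    if repeat_class == "satII":
        return lambda seq: is_satellite(seq, cfg.satII_canonical)
    if repeat_class == "satIII":
        return lambda seq: is_satellite(seq, cfg.satIII_canonical)
    raise ValueError(f"unknown repeat class {repeat_class!r}")


def _count_repeat_and_mapped(
    records: Iterable[AlignmentRecord], predicate
) -> tuple[int, int]:
    repeat = 0
    mapped = 0
    for rec in records:
        if rec.is_duplicate:
            continue
        if rec.is_mapped:
            mapped += 1
        if predicate(rec.seq):
            repeat += 1
    return repeat, mapped


def repeat_enrichment(
    ip_records: Sequence[AlignmentRecord],
    input_records: Sequence[AlignmentRecord],
    repeat_class: str = "telomere",
    rt: Optional[float] = None,
    sample_id: str = "",
    mark: str = "",
    cfg: Config | None = None,
) -> EnrichmentResult:
    """log2 enrichment of repeat-class reads in IP over input."""
    cfg = cfg or Config()
    rt = cfg.chip_rt_per_100bp if rt is None else rt
    predicate = _repeat_predicate(repeat_class, rt, cfg)
    ip_repeat, ip_mapped = _count_repeat_and_mapped(ip_records, predicate)
    in_repeat, in_mapped = _count_repeat_and_mapped(input_records, predicate)
    if ip_mapped == 0 or in_mapped == 0:
        raise ValueError("both IP and input must contain mapped reads")
    log2_enr: Optional[float] = None
    reason: Optional[str] = None
    if in_repeat == 0:
        reason = "zero repeat reads in input"
    elif ip_repeat == 0:
        reason = "zero repeat reads in IP"
    else:
        log2_enr = math.log2(
            (ip_repeat / ip_mapped) / (in_repeat / in_mapped)
        )
    return EnrichmentResult(
        sample_id=sample_id,
        mark=mark,
        repeat_class=repeat_class,
        ip_repeat_reads=ip_repeat,
        ip_mapped_total=ip_mapped,
        input_repeat_reads=in_repeat,
        input_mapped_total=in_mapped,
        log2_enrichment=log2_enr,
        reason=reason,
    )


def frip_filter(
    result: EnrichmentResult, frip: float, cfg: Config | None = None
) -> EnrichmentResult:
    """Flag samples with a fraction of reads in peaks below 1 % as excluded.

    FRiP is supplied externally (peak calling is upstream of this package);
    the boundary is inclusive on the keep side (frip == threshold is kept).
    """
    cfg = cfg or Config()
    if not 0.0 <= frip <= 1.0:
        raise ValueError("FRiP must lie in [0, 1]")
    result.frip = frip
    result.excluded = frip < cfg.frip_min
    return result
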