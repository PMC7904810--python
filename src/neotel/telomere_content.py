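"""GC-normalized telomere content and the tumor/control log2 ratio.

Telomere content is the number of telomeric reads (unmapped or MAPQ < 8,
passing the six-hexamer fixed-count rule) per million reads whose GC content
lies in the 48-52 % bin. The bin normalizes for library GC bias so contents
are comparable across samples; the tumor value is then expressed as a log2
ratio over the matched blood control (or, absent one, the mean content of
controls sequenced under the same protocol). A log2 ratio above 1 is the
genomic ALT evidence used by TMM subgrouping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_formats import AlignmentRecord, Config
from .telomere_reads import is_telomeric_fixed


@dataclass(slots=True)
class TelomereContentResult:
    sample_id: str
    tel_read_count: int
    gc_bin_read_count: int
    content: float  # telomeric reads per million GC-bin reads
    log2_ratio_vs_control: Optional[float] = None
    normalization: Optional[str] = None  # matched_control | protocol_mean


def select_telomere_reads(
    records: Iterable[AlignmentRecord], cfg: Config | None = None
) -> int:
    """Count non-duplicate telomeric reads: (unmapped or MAPQ < 8) and
    passing the fixed-count hexamer rule."""
    cfg = cfg or Config()
    n = 0
    for rec in records:
        if rec.is_duplicate:
            continue
        if rec.is_mapped and rec.mapq >= cfg.low_mapq:
            continue
        if is_telomeric_fixed(
            rec.seq, cfg.wgs_min_hexamers, cfg.hexamer_patterns, cfg.count_overlapping
        ):
            n += 1
    return n


def gc_fraction(seq: str) -> Optional[float]:
    """GC fraction over non-N bases; None for an all-N read."""
    seq = seq.upper()
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        return None
    gc = sum(1 for b in seq if b in "GC")
    return gc / denom


def count_gc_bin(
    records: Iterable[AlignmentRecord], cfg: Config | None = None
) -> int:
    """Count non-duplicate reads with GC content inside the (inclusive) bin."""
    cfg = cfg or Config()
    lo, hi = cfg.gc_bin
    n = 0
    for rec in records:
        if rec.is_duplicate:
            continue
        frac = gc_fraction(rec.seq)
        if frac is not None and lo <= frac <= hi:
            n += 1
    return n


def telomere_content(
    sample_id: str,
    records: Sequence[AlignmentRecord],
    cfg: Config | None = None,
) -> TelomereContentResult:
    """Per-sample telomere content: telomeric reads per million GC-bin reads."""
    cfg = cfg or Config()
    tel = select_telomere_reads(records, cfg)
    gc = count_gc_bin(records, cfg)
    if gc == 0:
        raise ValueError(f"{sample_id}: no reads in the GC normalization bin")
    return TelomereContentResult(
        sample_id=sample_id,
        tel_read_count=tel,
        gc_bin_read_count=gc,
        content=tel / gc * 1e6,
    )


def log2_ratio(
    tumor: TelomereContentResult,
    control: TelomereContentResult | Sequence[TelomereContentResult],
    protocol_key: Optional[str] = None,
) -> float:
    """log2(tumor content / control content).

    With a cohort of controls instead of a matched one, the denominator is
    the arithmetic mean content of the controls (callers pre-filter the
    cohort to the tumor's sequencing protocol via ``protocol_key``).
    Updates ``tumor.log2_ratio_vs_control`` in place.
    """
    if isinstance(control, TelomereContentResult):
        denom = control.content
        norm = "matched_control"
    else:
        controls = list(control)
        if not controls:
            raise ValueError(
                f"no controls available for protocol {protocol_key!r}"
            )
        denom = sum(c.content for c in controls) / len(controls)
        norm = "protocol_mean"
    if denom <= 0:
        raise ValueError("control telomere content must be positive")
    ratio = math.log2(tumor.content / denom)
    tumor.log2_ratio_vs_control = ratio
    tumor.normalization = norm
    return ratio
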