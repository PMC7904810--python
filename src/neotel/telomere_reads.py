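"""Read-level classification of telomeric and satellite repeat content.

Two telomere rules are used by downstream stages:

* **fixed count** — a read is telomeric when it contains at least six
  non-consecutive instances of the four most common telomeric hexamers
  (TTAGGG, TCAGGG, TGAGGG, TTGGGG) on one strand. This is the WGS
  telomere-extraction rule.
* **per 100 bp** — a read is telomeric when the per-strand hexamer count
  reaches ``rt`` repeats per 100 bp of read length (14 for RNA/TERRA, 8 for
  ChIP), scaled to the actual read length and rounded up.

Satellite reads (SatII/SatIII heterochromatin comparators) are detected by
exact substring match of the canonical repeat or its reverse complement.

Occurrences are counted as non-overlapping matches in a left-to-right scan;
instances need not be adjacent. Forward (G-strand) and reverse (C-strand)
counts are computed independently and the maximum is used — a genuine
telomeric read is strand-coherent, and summing would double-count chimeras.
N bases never match any pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import G_STRAND_HEXAMERS, SATII_CANONICAL, SATIII_CANONICAL

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


C_STRAND_HEXAMERS = tuple(reverse_complement(p) for p in G_STRAND_HEXAMERS)


@dataclass(slots=True, frozen=True)
class RepeatCallResult:
    read_id: str
    fwd_count: int
    rev_count: int
    best_strand: str  # "G" or "C"
    is_telomeric: bool
    rule: str  # "fixed_count" or "per_100bp"


def _scan_count(seq: str, patterns: tuple[str, ...], overlapping: bool) -> int:
    """Count pattern occurrences scanning left to right.

    Non-overlapping by default: a match advances the scan past the matched
    hexamer. With ``overlapping`` every start position is tested.
    """
    k = len(patterns[0])
    pats = set(patterns)
    n = 0
    i = 0
    end = len(seq) - k
    while i <= end:
        if seq[i : i + k] in pats:
            n += 1
            i += 1 if overlapping else k
        else:
            i += 1
    return n


def count_hexamers(
    seq: str,
    patterns: tuple[str, ...] = G_STRAND_HEXAMERS,
    overlapping: bool = False,
) -> tuple[int, int]:
    """Return (forward, reverse-complement) hexamer occurrence counts.

    The two strands are scanned independently; ``patterns`` are the G-strand
    hexamers and their reverse complements are matched for the C strand.
    """
    seq = seq.upper()
    rev_patterns = tuple(reverse_complement(p) for p in patterns)
    fwd = _scan_count(seq, patterns, overlapping)
    rev = _scan_count(seq, rev_patterns, overlapping)
    return fwd, rev


def is_telomeric_fixed(
    seq: str,
    min_hexamers: int = 6,
    patterns: tuple[str, ...] = G_STRAND_HEXAMERS,
    overlapping: bool = False,
) -> bool:
    """Fixed-count telomere rule (WGS): max strand count >= ``min_hexamers``."""
    fwd, rev = count_hexamers(seq, patterns, overlapping)
    return max(fwd, rev) >= min_hexamers


def is_telomeric_per100bp(
    seq: str,
    rt: float,
    patterns: tuple[str, ...] = G_STRAND_HEXAMERS,
    overlapping: bool = False,
) -> bool:
    """Length-scaled telomere rule: ``rt`` repeats per 100 bp, rounded up.

    A 50-mer at rt=8 therefore needs ceil(8 * 0.5) = 4 occurrences.
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    required = math.ceil(rt * len(seq) / 100.0)
    fwd, rev = count_hexamers(seq, patterns, overlapping)
    return max(fwd, rev) >= required


def is_satellite(seq: str, canonical: str) -> bool:
    """True when the canonical satellite repeat (either strand) is a substring."""
    seq = seq.upper()
    return canonical in seq or reverse_complement(canonical) in seq


def is_satII(seq: str) -> bool:
    return is_satellite(seq, SATII_CANONICAL)


def is_satIII(seq: str) -> bool:
    return is_satellite(seq, SATIII_CANONICAL)


def classify_read(
    read_id: str,
    seq: str,
    rule: str = "fixed_count",
    min_hexamers: int = 6,
    rt: float = 14.0,
    overlapping: bool = False,
) -> RepeatCallResult:
    """Classify one read under the chosen rule, reporting strand counts."""
    fwd, rev = count_hexamers(seq, overlapping=overlapping)
    if rule == "fixed_count":
        hit = max(fwd, rev) >= min_hexamers
    elif rule == "per_100bp":
        required = math.ceil(rt * len(seq) / 100.0)
        hit = max(fwd, rev) >= required
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return RepeatCallResult(
        read_id=read_id,
        fwd_count=fwd,
        rev_count=rev,
        best_strand="G" if fwd >= rev else "C",
        is_telomeric=hit,
        rule=rule,
    )
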