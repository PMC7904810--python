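"""Readers and writers for the formats every pipeline stage touches.

Internal convention: all coordinates are 0-based half-open. SAM is 1-based
and BED is 0-based; conversion happens only in this module, at the format
boundary. Duplicate-flagged reads are kept in the streams (callers decide
whether to count them; every counting stage in this package skips them).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
import yaml

logger = logging.getLogger("neotel")

CigarOp = tuple[str, int]

#: CIGAR operations that consume read bases.
_READ_OPS = frozenset("MSI")
#: CIGAR operations that consume reference bases.
_REF_OPS = frozenset("MD")


@dataclass(slots=True)
class AlignmentRecord:
    """One aligned or unmapped read with mate information.

    ``pos`` is the 0-based leftmost reference position; ``chrom`` and ``pos``
    are ``None`` for unmapped reads (mapq forced to 0). ``cigar`` is an
    ordered list of ``(op, length)`` over the ops M/S/I/D.
    """

    read_id: str
    chrom: Optional[str]
    pos: Optional[int]
    mapq: int
    strand: str
    cigar: list[CigarOp]
    seq: str
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_strand: Optional[str] = None
    is_proper_pair: bool = False
    is_duplicate: bool = False
    is_read1: bool = True

    def __post_init__(self) -> None:
        if (self.chrom is None) != (self.pos is None):
            raise ValueError(f"{self.read_id}: pos must be null iff chrom is null")
        if self.chrom is None:
            self.mapq = 0
        if self.cigar:
            read_len = sum(n for op, n in self.cigar if op in _READ_OPS)
            if read_len != len(self.seq):
                raise ValueError(
                    f"{self.read_id}: CIGAR consumes {read_len} bases, "
                    f"sequence has {len(self.seq)}"
                )

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def reference_end(self) -> Optional[int]:
        if self.pos is None:
            return None
        return self.pos + self.reference_span

    def left_clip(self) -> int:
        """Length of a leading soft clip (0 when none)."""
        if self.cigar and self.cigar[0][0] == "S":
            return self.cigar[0][1]
        return 0

    def right_clip(self) -> int:
        if self.cigar and self.cigar[-1][0] == "S":
            return self.cigar[-1][1]
        return 0


@dataclass(slots=True, frozen=True)
class CopySegment:
    """A copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end} empty")


G_STRAND_HEXAMERS = ("TTAGGG", "TCAGGG", "TGAGGG", "TTGGGG")
SATII_CANONICAL = "ATTCCATTCGATTCCATTCG"
SATIII_CANONICAL = "ATTCCATTCCATTCCATTCCATTCCATTCC"


@dataclass
class Config:
    """All numeric thresholds of the pipeline, with their defaults.

    The defaults encode the published decision rules: six fixed-count
    hexamers for WGS telomere reads, 14 repeats/100 bp for RNA (TERRA) and
    8 for ChIP, MAPQ bounds 8/30, the 1 kb / 4 discordant / 3 split locus
    caller thresholds, the 15-sample panel-of-normals cutoff, the 4-fold &
    20 %-of-positive-control C-Circle rule, the log2 telomere-content > 1
    ALT rule, and the 8-copy amplification rule.
    """

    hexamer_patterns: tuple[str, ...] = G_STRAND_HEXAMERS
    satII_canonical: str = SATII_CANONICAL
    satIII_canonical: str = SATIII_CANONICAL
    wgs_min_hexamers: int = 6
    low_mapq: int = 8
    anchor_min_mapq: int = 30
    region_size_bp: int = 1000
    min_discordant: int = 4
    max_control_discordant: int = 0
    pon_min_samples: int = 15
    min_split_reads: int = 3
    two_sided_window_bp: int = 10_000
    gc_bin: tuple[float, float] = (0.48, 0.52)
    rna_rt_per_100bp: float = 14.0
    chip_rt_per_100bp: float = 8.0
    ccircle_fold: float = 4.0
    ccircle_pos_frac: float = 0.20
    alt_log2_telcontent: float = 1.0
    amp_min_copies: float = 8.0
    tertp_min_alt_reads: int = 2
    tertp_min_vaf: float = 0.20
    frip_min: float = 0.01
    hotspot_merge_bp: int = 1_000_000
    hotspot_min_samples: int = 3
    cn_boundary_tol_bp: int = 50_000
    count_overlapping: bool = False
    cluster_mode: str = "linkage"  # or "tile"
    junction_tolerance_bp: int = 0
    amp_mode: str = "ploidy_scaled"  # or "absolute"

    def __post_init__(self) -> None:
        if self.gc_bin[0] > self.gc_bin[1]:
            raise ValueError("gc_bin endpoints must be ordered")
        for name in (
            "wgs_min_hexamers", "low_mapq", "anchor_min_mapq", "region_size_bp",
            "min_discordant", "pon_min_samples", "min_split_reads",
            "two_sided_window_bp", "rna_rt_per_100bp", "chip_rt_per_100bp",
            "ccircle_fold", "ccircle_pos_frac", "alt_log2_telcontent",
            "amp_min_copies", "tertp_min_alt_reads", "tertp_min_vaf",
            "frip_min", "hotspot_merge_bp", "hotspot_min_samples",
            "cn_boundary_tol_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hexamer_patterns"] = list(self.hexamer_patterns)
        d["gc_bin"] = list(self.gc_bin)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        kwargs = dict(d)
        if "hexamer_patterns" in kwargs:
            kwargs["hexamer_patterns"] = tuple(kwargs["hexamer_patterns"])
        if "gc_bin" in kwargs:
            kwargs["gc_bin"] = tuple(kwargs["gc_bin"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

_CIGAR_NUM_TO_OP = "MIDNSHP=XB"


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar: list[CigarOp] = []
    if seg.cigartuples:
        for op, n in seg.cigartuples:
            letter = _CIGAR_NUM_TO_OP[op]
            if letter not in "MSID":
                raise ValueError(
                    f"{seg.query_name}: unsupported CIGAR op {letter}{n}"
                )
            cigar.append((letter, n))
    unmapped = seg.is_unmapped
    return AlignmentRecord(
        read_id=seg.query_name,
        chrom=None if unmapped else seg.reference_name,
        pos=None if unmapped else seg.reference_start,
        mapq=0 if unmapped else seg.mapping_quality,
        strand="-" if seg.is_reverse else "+",
        cigar=cigar,
        seq=seg.query_sequence or "",
        mate_chrom=None if seg.mate_is_unmapped or seg.next_reference_id < 0
        else seg.next_reference_name,
        mate_pos=None if seg.mate_is_unmapped or seg.next_reference_id < 0
        else seg.next_reference_start,
        mate_strand=None if not seg.is_paired
        else ("-" if seg.mate_is_reverse else "+"),
        is_proper_pair=seg.is_proper_pair,
        is_duplicate=seg.is_duplicate,
        is_read1=not seg.is_read2,
    )


def read_alignments(
    path: str | Path, region: Optional[str] = None
) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` from a SAM or BAM file.

    SAM 1-based positions are converted to the internal 0-based convention
    by pysam. ``region`` (``chrom:start-end``, 1-based as samtools) requires
    an indexed BAM; a missing index raises ``FileNotFoundError``.
    Duplicate-flagged reads are yielded, not dropped.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if region is not None:
            if not fh.has_index():
                raise FileNotFoundError(
                    f"region query on {path} requires an index (.bai)"
                )
            it: Iterable[pysam.AlignedSegment] = fh.fetch(region=region)
        else:
            it = fh.fetch(until_eof=True)
        for seg in it:
            yield _from_pysam(seg)


def write_alignments(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    references: dict[str, int],
) -> None:
    """Write records as SAM text (header built from ``references``)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            flag = 0x1  # paired
            flag |= 0x40 if rec.is_read1 else 0x80
            if rec.strand == "-":
                flag |= 0x10
            if rec.mate_strand == "-":
                flag |= 0x20
            if rec.chrom is None:
                flag |= 0x4
            if rec.mate_chrom is None:
                flag |= 0x8
            if rec.is_proper_pair:
                flag |= 0x2
            if rec.is_duplicate:
                flag |= 0x400
            seg.flag = flag
            if rec.chrom is not None:
                seg.reference_id = fh.header.get_tid(rec.chrom)
                seg.reference_start = rec.pos
                seg.mapping_quality = rec.mapq
                seg.cigartuples = [
                    (_CIGAR_NUM_TO_OP.index(op), n) for op, n in rec.cigar
                ]
            if rec.mate_chrom is not None:
                seg.next_reference_id = fh.header.get_tid(rec.mate_chrom)
                seg.next_reference_start = rec.mate_pos
            fh.write(seg)


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

LOCI_BED_HEADER = (
    "#chrom\tchromStart\tchromEnd\tname\tscore\tstrand\t"
    "n_split\tn_discordant\tmicrohomology_bp\tcn_class\tsidedness"
)


def write_loci_bed(loci: Sequence, path: str | Path) -> None:
    """Write called repeat loci as BED6+ (0-based half-open, 1 bp features).

    The name column encodes orientation and sidedness; extra columns carry
    split/discordant support, microhomology and the CN-association class.
    An empty locus list produces a header-only file.
    """
    lines = [LOCI_BED_HEADER]
    for loc in loci:
        name = f"{loc.orientation}|{loc.sidedness}"
        strand = "+" if loc.orientation == "tel_right" else "-"
        mh = "." if loc.microhomology_bp is None else str(loc.microhomology_bp)
        lines.append(
            "\t".join(
                [
                    loc.chrom,
                    str(loc.junction),
                    str(loc.junction + 1),
                    name,
                    str(loc.n_split),
                    strand,
                    str(loc.n_split),
                    str(loc.n_discordant),
                    mh,
                    loc.cn_class,
                    loc.sidedness,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments_tsv(path: str | Path) -> list[CopySegment]:
    """Read copy-number segments from TSV (chrom, start, end, total_cn[, minor_cn])."""
    segments: list[CopySegment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            minor = None
            if "minor_cn" in idx and parts[idx["minor_cn"]] not in ("", "."):
                minor = float(parts[idx["minor_cn"]])
            segments.append(
                CopySegment(
                    chrom=parts[idx["chrom"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    total_cn=float(parts[idx["total_cn"]]),
                    minor_cn=minor,
                )
            )
    _check_segments(segments)
    return segments


def write_segments_tsv(segments: Sequence[CopySegment], path: str | Path) -> None:
    lines = ["chrom\tstart\tend\ttotal_cn\tminor_cn"]
    for s in segments:
        minor = "." if s.minor_cn is None else f"{s.minor_cn:g}"
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn:g}\t{minor}")
    Path(path).write_text("\n".join(lines) + "\n")


def _check_segments(segments: Sequence[CopySegment]) -> None:
    by_chrom: dict[str, list[CopySegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"segments overlap or unsorted on {chrom}")
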