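"""Deterministic simulator for every input the pipeline consumes.

The simulator emits aligner-style records directly — soft clips, mate
fields and mapping qualities set by construction — rather than running an
external aligner, because the caller consumes alignment semantics, not raw
reads. It emulates the read-level signatures of neo-telomere junctions:

* fragments drawn from a derivative chromosome (retained reference up to
  the junction, plus an appended telomeric tract; the distal segment is
  dropped when ``distal_loss``);
* reads fully inside the tract become unmapped telomeric records whose
  mates anchor uniquely (MAPQ 60) — the discordant-pair signal;
* junction-spanning reads become soft-clipped records clipped exactly at
  the junction — the split-read signal;
* everything else is an ordinary proper pair.

Telomeric tracts default to 90 % TTAGGG / 10 % variant hexamers so both the
fixed-count and per-100-bp classification rules are exercised. Substitution
errors (default 0.1 %) are never placed within the 6 bp junction-defining
window, so ground-truth junction positions stay exact. All randomness
flows from one integer seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_formats import AlignmentRecord, Config
from .telomere_reads import reverse_complement

G_HEXAMER = "TTAGGG"
C_HEXAMER = "CCCTAA"
VARIANT_HEXAMERS = ("TCAGGG", "TGAGGG", "TTGGGG")

_MIN_ANCHOR_BP = 20  # below this a junction read is emitted as unmapped


@dataclass(slots=True)
class SimEvent:
    """One implanted telomeric-repeat junction.

    ``kind`` is ``neo_telomere`` (one junction, telomeric tract on one
    side) or ``insertion`` (a short telomeric tract implanted between
    ``junction_pos`` and ``end_pos``, producing two opposite-orientation
    junctions). ``microhomology_bp`` engineers the retained flank so the
    maximal repeat-matching run is exactly that long.
    """

    chrom: str
    junction_pos: int
    orientation: str = "tel_right"  # tel_right | tel_left (neo_telomere)
    microhomology_bp: int = 0
    distal_loss: bool = True
    kind: str = "neo_telomere"
    end_pos: Optional[int] = None  # right junction of an insertion
    variant_fraction: float = 0.10
    max_discordant_support: Optional[int] = None
    max_split_support: Optional[int] = None


@dataclass(slots=True)
class SimScenario:
    """Study conditions for one simulated sample set.

    Defaults model a desk-scale tumor genome: a single 1 Mb contig at 50 %
    GC, 2x100 bp reads at 30x total coverage with a 350 +/- 35 bp insert,
    and three implanted neo-telomere junctions with microhomology 0, 2 and
    4 bp. Half the coverage comes from the unmodified background haplotype
    and half from the event derivatives, emulating a heterozygous terminal
    deletion healed by a neo-telomere.
    """

    seed: int = 0
    chrom: str = "sim1"
    genome_length_bp: int = 1_000_000
    gc: float = 0.5
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    coverage: float = 30.0
    events: list[SimEvent] = field(default_factory=list)
    tract_length_bp: int = 2_000
    derivative_fraction: float = 0.5
    base_error_rate: float = 0.001
    telomeric_read_fraction: float = 1e-4
    wgs_telomere_fraction: float = 5e-4
    tumor_telomere_excess: float = 4.0
    n_pon_samples: int = 16
    pon_coverage: float = 1.0
    pon_artifact: Optional[tuple[int, int]] = None  # (position, n_samples)

    def __post_init__(self) -> None:
        for ev in self.events:
            if not 0 <= ev.microhomology_bp <= 6:
                raise ValueError("microhomology_bp must lie in [0, 6]")
            lo, hi = 1000, self.genome_length_bp - 1000
            if not lo <= ev.junction_pos <= hi:
                raise ValueError("junctions must be >= 1 kb from contig ends")


def default_scenario(seed: int = 0) -> SimScenario:
    """The reference study conditions: three junctions, microhomology 0/2/4."""
    return SimScenario(
        seed=seed,
        events=[
            SimEvent("sim1", 200_000, "tel_right", microhomology_bp=0),
            SimEvent("sim1", 500_000, "tel_left", microhomology_bp=2),
            SimEvent("sim1", 800_000, "tel_right", microhomology_bp=4),
        ],
    )


def insertion_scenario(seed: int = 0, gap_bp: int = 5_000) -> SimScenario:
    """A telomeric-tract insertion producing two opposite junctions.

    A 300 bp tract (G-strand then C-strand half) replaces the reference
    between the two junctions. The library insert is widened to 600 +/- 60
    bp so read pairs spanning the short tract exist — the evidence a true
    insertion leaves; with the default 350 bp insert the tract geometry
    admits essentially none, mirroring why large insertions evade
    short-read detection.
    """
    return SimScenario(
        seed=seed,
        insert_mean=600.0,
        insert_sd=60.0,
        events=[
            SimEvent(
                "sim1", 400_000, kind="insertion", end_pos=400_000 + gap_bp
            )
        ],
    )


def independent_pair_scenario(seed: int = 0, gap_bp: int = 15_000) -> SimScenario:
    """Two independent opposite-orientation neo-telomeres ``gap_bp`` apart."""
    return SimScenario(
        seed=seed,
        events=[
            SimEvent("sim1", 400_000, "tel_right", microhomology_bp=1),
            SimEvent("sim1", 400_000 + gap_bp, "tel_left", microhomology_bp=1),
        ],
    )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def make_genome(scenario: SimScenario) -> dict[str, str]:
    """Random reference at the target GC with engineered junction flanks.

    For each neo-telomere event the retained flank adjacent to the
    junction is rewritten so that exactly ``microhomology_bp`` bases match
    the phased continuation of the telomeric repeat and the next base
    mismatches it.
    """
    rng = np.random.default_rng(scenario.seed)
    arr = _random_sequence(rng, scenario.genome_length_bp, scenario.gc)
    for ev in scenario.events:
        if ev.kind != "neo_telomere":
            continue
        j = ev.junction_pos
        k = ev.microhomology_bp
        if ev.orientation == "tel_right":
            # tract starts at phase 0; extension walks backwards through TTAGGG
            for i in range(k):
                arr[j - 1 - i] = G_HEXAMER[(-1 - i) % 6].encode()
            expected = G_HEXAMER[(-1 - k) % 6]
            arr[j - 1 - k] = _other_base(rng, expected).encode()
        else:
            # tract ends ...CCCTAA (phase 5); extension continues CCCTAA forward
            for i in range(k):
                arr[j + i] = C_HEXAMER[i % 6].encode()
            expected = C_HEXAMER[k % 6]
            arr[j + k] = _other_base(rng, expected).encode()
    return {scenario.chrom: arr.tobytes().decode()}


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _telomeric_tract(
    rng: np.random.Generator, n_hexamers: int, variant_fraction: float, strand: str
) -> str:
    """Concatenated hexamers, mostly canonical with a variant admixture."""
    out = []
    for _ in range(n_hexamers):
        if rng.random() < variant_fraction:
            hexamer = VARIANT_HEXAMERS[rng.integers(len(VARIANT_HEXAMERS))]
        else:
            hexamer = G_HEXAMER
        out.append(hexamer)
    tract = "".join(out)
    return reverse_complement(tract) if strand == "C" else tract


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _apply_errors(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: tuple[int, int] | None = None,
) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    positions = rng.integers(0, len(seq), size=n_err)
    for p in positions:
        if protected is not None and protected[0] <= p < protected[1]:
            continue
        chars[p] = _other_base(rng, chars[p])
    return "".join(chars)


def _proper(insert_mean: float, insert_sd: float, ref_span: float) -> bool:
    return abs(ref_span - insert_mean) <= 10 * insert_sd


class _HaplotypeReads:
    """Draws read pairs from one haplotype with a coordinate map to the
    reference: ``segments`` is a list of (hap_start, hap_end, ref_start or
    None) where None marks telomeric (unmappable) sequence."""

    def __init__(
        self,
        scenario: SimScenario,
        rng: np.random.Generator,
        hap_seq: str,
        segments: list[tuple[int, int, Optional[int]]],
        sample_prefix: str,
    ) -> None:
        self.sc = scenario
        self.rng = rng
        self.seq = hap_seq
        self.segments = segments
        self.prefix = sample_prefix
        self.counter = 0

    def _map(self, d: int) -> Optional[int]:
        for start, end, ref_start in self.segments:
            if start <= d < end:
                return None if ref_start is None else ref_start + (d - start)
        return None

    def _boundaries_in(self, s: int, e: int) -> list[int]:
        """Segment boundaries strictly inside haplotype interval [s, e)."""
        cuts = []
        for start, _end, _ref in self.segments:
            if s < start < e:
                cuts.append(start)
        return sorted(cuts)

    def _one_read(self, s: int, strand: str, read_id: str, is_read1: bool):
        rl = self.sc.read_length
        e = s + rl
        seq = self.seq[s:e]
        cuts = self._boundaries_in(s, e)
        protected: Optional[tuple[int, int]] = None
        if not cuts:
            ref = self._map(s)
            if ref is None:
                rec = dict(chrom=None, pos=None, mapq=0, cigar=[])
            else:
                rec = dict(chrom=self.sc.chrom, pos=ref, mapq=60, cigar=[("M", rl)])
        elif len(cuts) == 1:
            cut = cuts[0]
            left_len, right_len = cut - s, e - cut
            left_ref, right_ref = self._map(s), self._map(cut)
            if left_ref is not None and right_ref is None and left_len >= _MIN_ANCHOR_BP:
                rec = dict(
                    chrom=self.sc.chrom, pos=left_ref, mapq=60,
                    cigar=[("M", left_len), ("S", right_len)],
                )
                protected = (left_len - 6, left_len + 6)
            elif left_ref is None and right_ref is not None and right_len >= _MIN_ANCHOR_BP:
                rec = dict(
                    chrom=self.sc.chrom, pos=right_ref, mapq=60,
                    cigar=[("S", left_len), ("M", right_len)],
                )
                protected = (left_len - 6, left_len + 6)
            elif left_ref is not None and right_ref is not None:
                # a deletion-bridging read; align the longer side, clip the rest
                if left_len >= right_len and left_len >= _MIN_ANCHOR_BP:
                    rec = dict(
                        chrom=self.sc.chrom, pos=left_ref, mapq=60,
                        cigar=[("M", left_len), ("S", right_len)],
                    )
                elif right_len >= _MIN_ANCHOR_BP:
                    rec = dict(
                        chrom=self.sc.chrom, pos=right_ref, mapq=60,
                        cigar=[("S", left_len), ("M", right_len)],
                    )
                else:
                    rec = dict(chrom=None, pos=None, mapq=0, cigar=[])
            else:
                rec = dict(chrom=None, pos=None, mapq=0, cigar=[])
        else:
            # read crosses two boundaries (short tract): keep the longest
            # mappable piece if any, otherwise unmapped
            rec = dict(chrom=None, pos=None, mapq=0, cigar=[])
            best = 0
            pieces = [s] + cuts + [e]
            for a, b in zip(pieces, pieces[1:]):
                ref = self._map(a)
                if ref is not None and b - a >= max(_MIN_ANCHOR_BP, best):
                    best = b - a
                    rec = dict(
                        chrom=self.sc.chrom, pos=ref, mapq=60,
                        cigar=[("S", a - s), ("M", b - a), ("S", e - b)],
                    )
                    rec["cigar"] = [c for c in rec["cigar"] if c[1] > 0]
        seq = _apply_errors(self.rng, seq, self.sc.base_error_rate, protected)
        return rec, seq, strand, read_id, is_read1

    def pairs(self, n_pairs: int, region: tuple[int, int] | None = None):
        """Draw ``n_pairs`` fragments (optionally restricted to a haplotype
        window) and emit both reads of each pair."""
        sc = self.sc
        rl = sc.read_length
        lo, hi = region if region else (0, len(self.seq))
        records: list[AlignmentRecord] = []
        frag_lens = np.maximum(
            self.rng.normal(sc.insert_mean, sc.insert_sd, n_pairs).astype(int),
            2 * rl,
        )
        starts = self.rng.integers(lo, np.maximum(hi - frag_lens, lo + 1))
        for f, flen in zip(starts, frag_lens):
            f = int(f)
            flen = int(min(flen, len(self.seq) - f))
            if flen < 2 * rl:
                continue
            self.counter += 1
            rid = f"{self.prefix}:{self.counter}"
            r1 = self._one_read(f, "+", rid, True)
            r2 = self._one_read(f + flen - rl, "-", rid, False)
            recs = []
            infos = [r1, r2]
            both_mapped = all(info[0]["chrom"] is not None for info in infos)
            if both_mapped:
                span = (infos[1][0]["pos"] + rl) - infos[0][0]["pos"]
                proper = _proper(sc.insert_mean, sc.insert_sd, span)
            else:
                proper = False
            for info, mate in ((r1, r2), (r2, r1)):
                rec_d, seq, strand, rid_, is_read1 = info
                mate_d = mate[0]
                recs.append(
                    AlignmentRecord(
                        read_id=rid_,
                        chrom=rec_d["chrom"],
                        pos=rec_d["pos"],
                        mapq=rec_d["mapq"],
                        strand=strand,
                        cigar=rec_d["cigar"],
                        seq=seq,
                        mate_chrom=mate_d["chrom"],
                        mate_pos=mate_d["pos"],
                        mate_strand=mate[2],
                        is_proper_pair=proper,
                        is_read1=is_read1,
                    )
                )
            records.extend(recs)
        return records


def _baseline_telomere_pairs(
    scenario: SimScenario,
    rng: np.random.Generator,
    n_sample_reads: int,
    fraction: float,
    prefix: str,
) -> list[AlignmentRecord]:
    """Unmapped telomeric read pairs from the sample's real chromosome ends.

    Every WGS library — tumor or blood control — contains reads from the
    genuine telomeres; they are unmapped with an unmapped mate and carry no
    positional signal, so they feed telomere-content estimation without
    touching the locus caller.
    """
    n_pairs = int(round(n_sample_reads * fraction / 2))
    rl = scenario.read_length
    records: list[AlignmentRecord] = []
    for i in range(n_pairs):
        for mate_idx in (0, 1):
            strand = "G" if mate_idx == 0 else "C"
            seq = _telomeric_tract(rng, rl // 6 + 2, 0.10, strand)
            offset = int(rng.integers(0, 6))
            records.append(
                AlignmentRecord(
                    read_id=f"{prefix}_tel:{i}",
                    chrom=None, pos=None, mapq=0,
                    strand="+" if mate_idx == 0 else "-",
                    cigar=[], seq=seq[offset : offset + rl],
                    mate_chrom=None, mate_pos=None,
                    mate_strand="-" if mate_idx == 0 else "+",
                    is_proper_pair=False,
                    is_read1=mate_idx == 0,
                )
            )
    return records


def _derivative(
    scenario: SimScenario, genome: dict[str, str], ev: SimEvent, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, Optional[int]]], tuple[int, int]]:
    """Build the derivative haplotype for one event.

    Returns (sequence, coordinate segments, focus window in haplotype
    coordinates around the junction(s))."""
    ref = genome[ev.chrom]
    n_hex = scenario.tract_length_bp // 6
    pad = int(3 * scenario.insert_mean)
    if ev.kind == "insertion":
        if ev.end_pos is None:
            raise ValueError("insertion events need end_pos")
        half = 25  # 25 G-hexamers then 25 C-hexamers: 300 bp tract
        tract = G_HEXAMER * half + C_HEXAMER * half
        p, q = ev.junction_pos, ev.end_pos
        seq = ref[:p] + tract + ref[q:]
        segments = [
            (0, p, 0),
            (p, p + len(tract), None),
            (p + len(tract), len(seq), q),
        ]
        focus = (max(0, p - pad), min(len(seq), p + len(tract) + pad))
        return seq, segments, focus
    if ev.orientation == "tel_right":
        tract = _telomeric_tract(rng, n_hex, ev.variant_fraction, "G")
        # junction-adjacent hexamer kept canonical so the phase is defined
        tract = G_HEXAMER + tract[6:]
        j = ev.junction_pos
        seq = ref[:j] + tract
        segments = [(0, j, 0), (j, len(seq), None)]
        focus = (max(0, j - pad), len(seq))
    else:
        tract = _telomeric_tract(rng, n_hex, ev.variant_fraction, "G")
        tract = reverse_complement(tract)  # plus strand shows CCCTAA repeats
        # force the junction-adjacent hexamer canonical so phase is defined
        tract = tract[:-6] + C_HEXAMER
        j = ev.junction_pos
        seq = tract + ref[j:]
        segments = [(0, len(tract), None), (len(tract), len(seq), j)]
        focus = (0, min(len(seq), len(tract) + pad))
    return seq, segments, focus


def _is_telomeric_read(rec: AlignmentRecord) -> bool:
    from .telomere_reads import is_telomeric_fixed

    return is_telomeric_fixed(rec.seq)


def _yields_anchor(pair: list[AlignmentRecord]) -> bool:
    """Would the caller extract a discordant anchor from this pair?"""
    if len(pair) != 2:
        return False
    a, b = pair
    for anchor, mate in ((a, b), (b, a)):
        if (
            anchor.chrom is not None
            and anchor.mapq > 30
            and not anchor.is_proper_pair
            and not _is_telomeric_read(anchor)
            and _is_telomeric_read(mate)
        ):
            return True
    return False


def _split_orientation(rec: AlignmentRecord) -> Optional[tuple[str, int]]:
    """(orientation, boundary) when the read is a telomere-clip split read."""
    if rec.chrom is None:
        return None
    rc = rec.right_clip()
    if rc >= 6 and G_HEXAMER in rec.seq[-rc:]:
        return "tel_right", rec.pos + rec.reference_span
    lc = rec.left_clip()
    if lc >= 6 and C_HEXAMER in rec.seq[:lc]:
        return "tel_left", rec.pos
    return None


def _yields_split(pair: list[AlignmentRecord]) -> bool:
    return any(_split_orientation(r) is not None for r in pair)


def _cap_support(
    records: list[AlignmentRecord], ev: SimEvent
) -> list[AlignmentRecord]:
    """Enforce optional per-event support caps (threshold-sharpness checks).

    Caps mirror the caller's counting: the discordant cap limits pairs that
    would yield an anchor, the split cap limits pairs carrying a
    telomere-clip split read; a pair counting against an exhausted cap is
    dropped entirely.
    """
    if ev.max_discordant_support is None and ev.max_split_support is None:
        return records
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.read_id, []).append(rec)
    kept: list[AlignmentRecord] = []
    n_disc = 0
    n_split = 0
    for pair in by_id.values():
        anchor_pair = _yields_anchor(pair)
        split_pair = _yields_split(pair)
        if (
            anchor_pair
            and ev.max_discordant_support is not None
            and n_disc >= ev.max_discordant_support
        ):
            continue
        if (
            split_pair
            and ev.max_split_support is not None
            and n_split >= ev.max_split_support
        ):
            continue
        if anchor_pair:
            n_disc += 1
        if split_pair:
            n_split += 1
        kept.extend(pair)
    return kept


def simulate_tumor_alignments(
    scenario: SimScenario, genome: Optional[dict[str, str]] = None
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Simulate the tumor read set and its ground truth.

    Background coverage comes from the unmodified reference; each event
    contributes derivative-haplotype reads restricted to a window around
    its junction (the derivative is identical to the reference elsewhere).
    The ground-truth table lists every implanted junction with the
    discordant and split support actually emitted.
    """
    genome = genome or make_genome(scenario)
    rng = np.random.default_rng(scenario.seed + 1)
    sc = scenario
    ref = genome[sc.chrom]
    rl = sc.read_length
    records: list[AlignmentRecord] = []

    bg_cov = sc.coverage * (1 - sc.derivative_fraction) if sc.events else sc.coverage
    n_bg = int(len(ref) * bg_cov / (2 * rl))
    bg = _HaplotypeReads(sc, rng, ref, [(0, len(ref), 0)], "tum_bg")
    records.extend(bg.pairs(n_bg))

    truth_rows = []
    for idx, ev in enumerate(sc.events):
        hap_seq, segments, focus = _derivative(sc, genome, ev, rng)
        hap = _HaplotypeReads(sc, rng, hap_seq, segments, f"tum_ev{idx}")
        dv_cov = sc.coverage * sc.derivative_fraction
        n_pairs = int((focus[1] - focus[0]) * dv_cov / (2 * rl))
        ev_records = hap.pairs(n_pairs, region=focus)
        ev_records = _cap_support(ev_records, ev)
        by_id: dict[str, list[AlignmentRecord]] = {}
        for rec in ev_records:
            by_id.setdefault(rec.read_id, []).append(rec)
        n_disc = sum(1 for pair in by_id.values() if _yields_anchor(pair))
        records.extend(ev_records)
        junctions = (
            [(ev.junction_pos, "tel_right"), (ev.end_pos, "tel_left")]
            if ev.kind == "insertion"
            else [(ev.junction_pos, ev.orientation)]
        )
        for jpos, orient in junctions:
            n_split = sum(
                1
                for rec in ev_records
                if _split_orientation(rec) == (orient, jpos)
            )
            truth_rows.append(
                {
                    "chrom": ev.chrom,
                    "junction": jpos,
                    "orientation": orient,
                    "kind": ev.kind,
                    "microhomology_bp": ev.microhomology_bp,
                    "n_discordant_emitted": n_disc,
                    "n_split_emitted": n_split,
                    "distal_loss": ev.distal_loss,
                }
            )
    records.extend(
        _baseline_telomere_pairs(
            sc, rng, len(records),
            sc.wgs_telomere_fraction * sc.tumor_telomere_excess, "tum",
        )
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "junction", "orientation", "kind", "microhomology_bp",
            "n_discordant_emitted", "n_split_emitted", "distal_loss",
        ],
    )
    return records, truth


def simulate_control_and_pon(
    scenario: SimScenario, genome: Optional[dict[str, str]] = None
) -> tuple[list[AlignmentRecord], list[list[AlignmentRecord]]]:
    """Event-free matched control plus a panel of control samples.

    With ``scenario.pon_artifact = (position, k)`` the first ``k`` panel
    samples carry a shared artifact: a few discordant telomere-mate pairs
    anchored at the given position, exercising the panel filter.
    """
    genome = genome or make_genome(scenario)
    sc = scenario
    ref = genome[sc.chrom]
    rl = sc.read_length
    rng = np.random.default_rng(sc.seed + 2)
    control = _HaplotypeReads(
        sc, rng, ref, [(0, len(ref), 0)], "ctl"
    ).pairs(int(len(ref) * sc.coverage / (2 * rl)))
    control.extend(
        _baseline_telomere_pairs(
            sc, rng, len(control), sc.wgs_telomere_fraction, "ctl"
        )
    )

    panel: list[list[AlignmentRecord]] = []
    for s in range(sc.n_pon_samples):
        srng = np.random.default_rng(sc.seed + 100 + s)
        reads = _HaplotypeReads(
            sc, srng, ref, [(0, len(ref), 0)], f"pon{s}"
        ).pairs(int(len(ref) * sc.pon_coverage / (2 * rl)))
        if sc.pon_artifact is not None and s < sc.pon_artifact[1]:
            pos = sc.pon_artifact[0]
            for k in range(3):
                apos = pos + int(srng.integers(0, 300))
                rid = f"pon{s}:artifact{k}"
                tract = _telomeric_tract(srng, rl // 6 + 1, 0.1, "G")[:rl]
                reads.append(
                    AlignmentRecord(
                        read_id=rid, chrom=sc.chrom, pos=apos, mapq=60,
                        strand="+", cigar=[("M", rl)],
                        seq=ref[apos : apos + rl],
                        mate_chrom=None, mate_pos=None, mate_strand="-",
                        is_proper_pair=False, is_read1=True,
                    )
                )
                reads.append(
                    AlignmentRecord(
                        read_id=rid, chrom=None, pos=None, mapq=0,
                        strand="-", cigar=[], seq=tract,
                        mate_chrom=sc.chrom, mate_pos=apos, mate_strand="+",
                        is_proper_pair=False, is_read1=False,
                    )
                )
        panel.append(reads)
    return control, panel


# ---------------------------------------------------------------------------
# repeat-enriched read sets (ChIP / RNA)
# ---------------------------------------------------------------------------

def simulate_repeat_readset(
    n_reads: int,
    telomeric_fraction: float,
    satII_fraction: float = 0.0,
    read_length: int = 100,
    seed: int = 0,
    satIII_fraction: float = 0.0,
    chrom: str = "sim1",
) -> list[AlignmentRecord]:
    """Read set with configured telomeric/satellite fractions.

    Telomeric reads are concatenated hexamers (qualifying under both the
    fixed-count and per-100-bp rules) and are emitted unmapped; satellite
    reads contain the canonical motif; the remainder is random sequence at
    50 % GC, mapped with MAPQ 60.
    """
    if telomeric_fraction + satII_fraction + satIII_fraction > 1:
        raise ValueError("class fractions must sum to <= 1")
    from .io_formats import SATII_CANONICAL, SATIII_CANONICAL

    rng = np.random.default_rng(seed)
    kinds = rng.choice(
        4,
        size=n_reads,
        p=[
            telomeric_fraction,
            satII_fraction,
            satIII_fraction,
            1 - telomeric_fraction - satII_fraction - satIII_fraction,
        ],
    )
    records: list[AlignmentRecord] = []
    for i, kind in enumerate(kinds):
        rid = f"rr:{i}"
        if kind == 0:
            seq = _telomeric_tract(rng, read_length // 6 + 2, 0.10, "G")
            offset = int(rng.integers(0, 6))
            seq = seq[offset : offset + read_length]
            records.append(
                AlignmentRecord(
                    read_id=rid, chrom=None, pos=None, mapq=0, strand="+",
                    cigar=[], seq=seq, is_proper_pair=False,
                )
            )
            continue
        seq = _random_sequence(rng, read_length, 0.5).tobytes().decode()
        if kind in (1, 2):
            motif = SATII_CANONICAL if kind == 1 else SATIII_CANONICAL
            start = int(rng.integers(0, read_length - len(motif) + 1))
            seq = seq[:start] + motif + seq[start + len(motif):]
        pos = int(rng.integers(0, 10_000_000))
        records.append(
            AlignmentRecord(
                read_id=rid, chrom=chrom, pos=pos, mapq=60, strand="+",
                cigar=[("M", read_length)], seq=seq, is_proper_pair=True,
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def simulate_cohort_table(
    n: int,
    group_fraction: float = 0.5,
    baseline_outcome_prob: float = 0.5,
    odds_ratio: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample binary exposure/outcome labels under a logistic model.

    The outcome probability is ``baseline_outcome_prob`` in the unexposed
    group and shifted by ``log(odds_ratio)`` on the logit scale in the
    exposed group. Ground-truth parameters are stored in ``df.attrs``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    group = rng.random(n) < group_fraction
    logit0 = math.log(baseline_outcome_prob / (1 - baseline_outcome_prob))
    p = 1 / (1 + np.exp(-(logit0 + np.log(odds_ratio) * group)))
    outcome = rng.random(n) < p
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "group": group.astype(int),
            "outcome": outcome.astype(int),
        }
    )
    df.attrs["ground_truth"] = {
        "n": n,
        "group_fraction": group_fraction,
        "baseline_outcome_prob": baseline_outcome_prob,
        "odds_ratio": odds_ratio,
        "seed": seed,
    }
    return df


def cohort_table_to_2x2(df: pd.DataFrame):
    """Collapse a simulated cohort table to the exposure-by-outcome 2x2."""
    from .cohort_stats import TwoByTwo

    a = int(((df["group"] == 1) & (df["outcome"] == 1)).sum())
    b = int(((df["group"] == 1) & (df["outcome"] == 0)).sum())
    c = int(((df["group"] == 0) & (df["outcome"] == 1)).sum())
    d = int(((df["group"] == 0) & (df["outcome"] == 0)).sum())
    return TwoByTwo(a, b, c, d)
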