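"""Classify individual reads as telomeric under the two decision rules.

WGS telomere extraction uses a fixed count (six hexamers anywhere in the
read); RNA (TERRA) and ChIP use a length-scaled threshold (14 or 8 repeats
per 100 bp). Satellite reads are detected by their canonical motif.
"""

from neotel import count_hexamers, is_satellite, is_telomeric_fixed, is_telomeric_per100bp
from neotel.io_formats import SATII_CANONICAL

reads = {
    "pure_telomere": "TTAGGG" * 17,
    "variant_mix": ("TTAGGG" * 3 + "TCAGGG" + "TGAGGG" + "TTGGGG") + "ACGT" * 16,
    "c_strand": "CCCTAA" * 17,
    "five_repeats_only": "TTAGGG" * 5 + "A" * 72,
    "satellite_II": "ACGT" * 10 + SATII_CANONICAL + "TGCA" * 10,
    "random": ("ACGGTA" * 17)[:102],
}

print(f"{'read':>18}  {'fwd':>3} {'rev':>3}  {'wgs(6)':>6} {'rna(14)':>7} {'chip(8)':>7} {'satII':>5}")
for name, seq in reads.items():
    fwd, rev = count_hexamers(seq)
    print(
        f"{name:>18}  {fwd:>3} {rev:>3}  "
        f"{str(is_telomeric_fixed(seq)):>6} "
        f"{str(is_telomeric_per100bp(seq, 14)):>7} "
        f"{str(is_telomeric_per100bp(seq, 8)):>7} "
        f"{str(is_satellite(seq, SATII_CANONICAL)):>5}"
    )

print(
    "\nfwd/rev are per-strand non-overlapping hexamer counts; a read is"
    "\ntelomeric when the larger strand count reaches the rule's threshold"
    "\n(the per-100bp rules scale with read length and round up, so a"
    "\n102-mer needs ceil(14*1.02)=15 repeats for RNA and 9 for ChIP)."
)
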