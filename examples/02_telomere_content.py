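"""GC-normalized telomere content and the ALT-defining log2 ratio.

Builds a tumor read set with a 4x telomeric excess over its matched
control and shows the content arithmetic: telomeric reads (unmapped or
MAPQ < 8, six-hexamer rule) per million reads in the 48-52% GC bin.
"""

from neotel import log2_ratio, telomere_content
from neotel.io_formats import AlignmentRecord

TEL = "TTAGGG" * 17


def build_sample(n_telomeric: int, n_background: int):
    reads = [
        AlignmentRecord(f"t{i}", None, None, 0, "+", [], TEL)
        for i in range(n_telomeric)
    ]
    reads += [
        AlignmentRecord(
            f"b{i}", "chr1", i, 60, "+", [("M", 100)], "G" * 50 + "A" * 50
        )
        for i in range(n_background)
    ]
    return reads


tumor = telomere_content("tumor", build_sample(400, 99_600))
control = telomere_content("control", build_sample(100, 99_900))
ratio = log2_ratio(tumor, control)

for r in (tumor, control):
    print(
        f"{r.sample_id:>8}: {r.tel_read_count} telomeric / "
        f"{r.gc_bin_read_count} GC-bin reads -> {r.content:.1f} per million"
    )
print(f"log2(tumor/control) = {ratio:.3f}")
print(
    "\nA log2 ratio above 1 (more than twice the control's telomere"
    "\ncontent) is the genomic ALT criterion used in TMM subgrouping;"
    "\nthis tumor's 4x excess gives exactly 2.0."
)
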