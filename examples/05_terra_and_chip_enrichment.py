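"""TERRA expression and telomeric ChIP enrichment on simulated read sets.

TERRA (telomeric lncRNA) abundance is reads passing the 14-per-100bp rule
per million total reads. ChIP enrichment is the log2 ratio of the repeat
read fraction in the IP over the input; a 4x telomeric excess in the IP
should give an enrichment near 2.
"""

from neotel import repeat_enrichment, terra_quantify
from neotel.repeat_quantification import frip_filter
from neotel.synthetic_data import simulate_repeat_readset

rna = simulate_repeat_readset(200_000, telomeric_fraction=5e-4, seed=11)
terra = terra_quantify(rna, sample_id="tumor_rna")
print(
    f"TERRA: {terra.terra_reads} of {terra.total_reads} reads "
    f"-> {terra.terra_per_million:.1f} per million"
)

ip = simulate_repeat_readset(100_000, telomeric_fraction=4e-3, seed=12)
inp = simulate_repeat_readset(100_000, telomeric_fraction=1e-3, seed=13)
enr = repeat_enrichment(ip, inp, repeat_class="telomere", mark="H3K9me3")
frip_filter(enr, frip=0.03)
print(
    f"H3K9me3 telomere enrichment: log2("
    f"{enr.ip_repeat_reads}/{enr.ip_mapped_total} / "
    f"{enr.input_repeat_reads}/{enr.input_mapped_total}) "
    f"= {enr.log2_enrichment:.2f} (FRiP {enr.frip}, excluded={enr.excluded})"
)
print(
    "\nThe simulated 4:1 IP/input telomeric fraction is recovered as an"
    "\nenrichment near 2.0; heterochromatin-bound telomeres in ALT tumors"
    "\nshow this signature for H3K9me3."
)
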