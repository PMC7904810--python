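"""Telomere-maintenance-mechanism subgrouping of example tumors.

Combines C-Circle assay AUC triples, the telomere-content log2 ratio,
MYCN amplification and TERT events into the five TMM labels.
"""

from neotel import call_ccircle, classify_gene_cnv, classify_tmm
from neotel.tmm_classify import call_tert_promoter

samples = [
    # name, (auc_sample, auc_no_poly, auc_pos_ctrl), log2 ratio, mycn_cn, tert
    ("NB-alt", (8.0, 1.0, 10.0), 1.8, 2.0, False),
    ("NB-mna", (0.5, 0.4, 10.0), -0.2, 40.0, False),
    ("NB-tert", (0.3, 0.2, 10.0), 0.1, 2.0, True),
    ("NB-het", (1.0, 0.9, 10.0), 1.6, 25.0, False),
    ("NB-other", (0.4, 0.3, 10.0), 0.0, 2.0, False),
]

print(f"{'sample':>9} {'ccircle':>7} {'mycn':>9} {'label':>12}  evidence")
for name, auc, ratio, mycn_cn, tert in samples:
    ccircle = call_ccircle(*auc)
    mycn_class = classify_gene_cnv(mycn_cn, ploidy=2.0, minor_cn=1.0)
    call = classify_tmm(
        ccircle, ratio, mycn_class == "amplified", tert, sample_id=name
    )
    print(
        f"{name:>9} {str(ccircle):>7} {mycn_class:>9} {call.label:>12}  "
        f"{','.join(sorted(call.evidence)) or '-'}"
    )

# the relaxed TERT promoter rule: 2 supporting reads at >= 20% VAF suffice
print(
    f"\nTERT promoter call at 2 alt / 6 ref reads: "
    f"{call_tert_promoter(ref_reads=6, alt_reads=2)}"
)
print(
    "\nNB-het shows the heterogeneous rule: C-Circle negative but MYCN-"
    "\namplified with a telomere-content ratio above 1 -> HET_ALT_MNA."
)
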