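"""Recompute the published cohort association statistics.

The package ships the 2x2 contingency tables of the two published
neuroblastoma cohorts (C-Circle ALT status against stage, risk group,
sex, MYCN and histology) reconstructed from printed group counts; the
two-sided Fisher tests reproduce the printed p-values.
"""

from neotel.cohort_stats import (
    COHORT_PRESETS,
    cohort_fisher_tests,
    positive_fraction,
)

for cohort in ("screening", "inform"):
    frac = positive_fraction(cohort)
    print(f"\n{cohort} cohort: {100 * frac:.1f}% C-Circle positive")
    results = cohort_fisher_tests(cohort)
    for contrast, res in results.items():
        t = COHORT_PRESETS[cohort][contrast]
        print(
            f"  {contrast:<24} [[{t.a},{t.b}],[{t.c},{t.d}]]"
            f"  OR={res['odds_ratio']:<8.3g} p={res['p_value']:.4g}"
        )

print(
    "\nALT is associated with stage 4, high-risk disease and normal MYCN"
    "\nin the screening cohort (n=720), and is strongly enriched (47.5%"
    "\nvs 9.2%) among relapsed tumors."
)
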