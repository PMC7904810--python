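# Methods

This note documents the models and procedures `neotel` implements, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Read-level repeat classification

Telomeric hexamer occurrences are counted per strand as non-overlapping
matches in a left-to-right scan; instances need not be adjacent. The four
patterns are TTAGGG and its common variants TCAGGG, TGAGGG, TTGGGG; the
C-strand patterns are their literal reverse complements (CCCTAA, CCCTGA,
CCCTCA, CCCCAA), computed programmatically so the strand-symmetry
invariant holds exactly. The forward and reverse counts are never summed:
a genuine telomeric read is strand-coherent, and summing would
double-count chimeric reads. An overlapping-count mode exists behind
`Config.count_overlapping` but is off by default; for this alphabet
overlapping hexamer matches are rare and the choice is immaterial in
practice. N bases never match.

Two decision rules share these counts:

* **fixed count** (WGS telomere extraction): max strand count ≥ 6;
* **per 100 bp** (RNA rt = 14, ChIP rt = 8): max strand count ≥
  ceil(rt × read_length / 100). Rounding up implements threshold
  semantics — a 50-mer at rt = 8 needs 4 occurrences, a 102-mer at
  rt = 14 needs 15.

Satellite classification is an exact substring test of the canonical
SatII (ATTCCATTCGATTCCATTCG) or SatIII (ATTCCATTCC ×3) motif on either
strand. Satellite and telomere labels are independent, not exclusive.

## Telomere content

Content = telomeric reads / GC-bin reads × 10⁶, where telomeric reads
are non-duplicate reads that are unmapped or have MAPQ < 8 and pass the
fixed-count rule, and the GC bin is 48–52 % inclusive, computed over
non-N bases (all-N reads are excluded for lack of a denominator). The
bin endpoints being inclusive and the per-million scaling are this
package's choices; the downstream ALT criterion uses only the
tumor/control log2 ratio, which is scale-free, so neither choice affects
classification. Without a matched control the denominator is the
arithmetic mean content of controls sharing the sequencing protocol.
Duplicate-flagged reads are excluded from numerator and denominator
alike.

## The neo-telomere locus caller

The caller looks for junctions where telomeric repeat sequence abuts
uniquely mapped genome — the signature of telomeric repeats healing a
broken chromosome end. Stages and thresholds:

1. **Discordant anchors.** Non-proper, non-duplicate pairs where one end
   passes the fixed-count telomere rule and the other is non-telomeric
   and uniquely mapped with MAPQ > 30 (strict). Orphan records are
   skipped with a counter.
2. **Candidate regions.** Anchors are clustered per chromosome by single
   linkage with a 1 kb gap, sub-split so each cluster spans ≤ 1 kb.
   Regions need ≥ 4 tumor anchors and zero matched-control anchors
   within the cluster span padded by 1 kb on each side (the control
   lookup window is this package's definition). Fixed 1 kb genome tiles
   are available via `Config.cluster_mode = "tile"`; clustering is the
   default because junction signal falling across a tile boundary would
   otherwise split below threshold.
3. **Panel of normals.** A region is removed when ≥ 15 *distinct* panel
   samples contribute ≥ 1 discordant anchor in its padded span —
   counting samples, not reads, so one noisy control cannot veto a
   region. A panel smaller than 15 samples makes the filter inert, with
   a warning.
4. **Junction refinement.** Split reads are soft-clipped alignments
   whose clip (≥ 6 bp) contains TTAGGG (right clip → telomere
   downstream, `tel_right`) or CCCTAA (left clip → telomere upstream,
   `tel_left`). The junction is the clip boundary supported by ≥ 3 split
   reads agreeing exactly; `Config.junction_tolerance_bp` (default 0)
   relaxes the agreement for noisy data. The repeat phase — the offset
   within the hexamer of the telomeric base adjacent to the junction —
   is taken by majority vote (for `tel_right` the phase of the first
   clipped base in TTAGGG, for `tel_left` the phase of the last clipped
   base in CCCTAA; the junction-adjacent base is the robust anchor on
   both sides).
5. **Microhomology.** The telomeric repeat is extended backwards across
   the junction in its observed phase and orientation; the score is the
   maximal run of retained-flank reference bases adjacent to the
   junction matching that extension. The phase is fixed at its observed
   value, not maximized over phases — the literal reading of homology
   to the repeat as it actually continued. Junctions within 6 bp of a
   contig edge score null.
6. **Two-sided events.** Opposite-orientation loci within 10 kb are
   paired greedily by gap (each locus in at most one event). A pair is a
   *true insertion* when at least one read pair spans both junctions
   with MAPQ > 30 on both ends; otherwise it may be two independent
   healings.
7. **Copy-number context.** The nearest segment boundary within 50 kb of
   the junction (50 kb being the stated detection limit of typical
   segmentation) decides the class: telomeric-side copy number lower
   than the retained side → loss, higher → gain; no discriminating
   boundary → neutral, subdivided by whether an independent SV
   breakpoint lies within 10 kb.
8. **Hotspots.** Cohort junctions are merged per chromosome by single
   linkage with a 1 Mb gap; clusters recurring in ≥ 3 distinct samples
   are reported. The 1 Mb / 3-sample parameters are this package's
   defaults, chosen so a recurrent cluster spanning about a megabase
   (the scale of reported recurrent regions) forms one hotspot.

Manual review of near-threshold calls is out of scope; the caller instead
emits an audit list of all candidate regions, including unresolved ones.

## TMM subgrouping

C-Circle positivity requires a ≥ 4-fold AUC increase over the
no-polymerase control **and** ≥ 20 % of the ALT-positive assay control.
A no-polymerase AUC of exactly zero satisfies the fold condition
(configurable); negative AUCs are rejected.

Label decision order: (1) C-Circle negative **and** log2 telomere
content > 1 **and** MYCN amplified → `HET_ALT_MNA`; (2) C-Circle
positive **or** log2 content > 1 → `ALT`; (3) MYCN amplified → `MNA`;
(4) TERT SV or promoter mutation → `TERT`; (5) else `OTHER`. The order
resolves overlaps: a C-Circle-positive MYCN-amplified tumor is `ALT`
with `mycn_amp` retained in the evidence set (such heterogeneous tumors
exist but are rare), and ALT evidence pre-empts TERT events (empirically
near-exclusive; co-occurrence is logged). Evidence flags record every
true predicate regardless of the final label.

Gene amplification reconciles two published wordings ("8-fold" vs "≥ 8
copies") as ≥ 8 copies scaled by ploidy/2 — 8 copies in a diploid, 16 in
a tetraploid; a flat 8-copy mode is selectable (`Config.amp_mode`).

## TERRA and ChIP enrichment

TERRA reads pass the rt = 14 per-100-bp rule regardless of mapping
state, normalized per million total non-duplicate reads (RNA libraries
here are poly-A selected, so this measures polyadenylated TERRA).
Enrichment is log2 of the IP repeat-read fraction over the input
fraction; numerators scan all records including unmapped ones,
denominators count mapped non-duplicate reads, matching how repeat reads
escape the assembly while library size is measured on mapped output.
Zero repeat reads in either library make the ratio undefined (reported
null with a reason, never ±inf). The FRiP exclusion threshold "below
one" is read as below 1 % (FRiP < 0.01), configurable and recorded in
the output; the boundary keeps frip = 0.01.

## Cohort statistics

The two-sided Fisher exact p-value follows the R convention: the sum of
hypergeometric probabilities, over all tables with the observed margins,
that do not exceed the observed table's probability within a relative
tolerance of 1e-7. This convention is required to reproduce published
p-values computed in R; scipy's implementation agrees on all tested
tables and serves as an independent cross-check in the test suite, not
as the implementation. A zero margin forces p = 1; the odds ratio is the
sample OR. Wilcoxon rank-sum uses the exact distribution for tie-free
samples of combined n ≤ 50 and the normal approximation with tie and
continuity correction otherwise; Spearman is Pearson on mid-ranks.

The built-in cohort presets are the 2×2 tables of the two published
neuroblastoma cohorts reconstructed from printed group counts. Stage
contrasts follow the table layout: stage 1–3 vs 4 over staged tumors as
one 2×2, and 4S vs all other staged tumors as a second — the contrast
that exactly reproduces the published stage p-values. Contrasts with
missing annotations (risk, MYCN) use the counts actually printed, so
margins differ slightly between contrasts.

## Synthetic data

The simulator emits aligner-style records directly — soft clips, mate
fields, mapping qualities set by construction — rather than running an
aligner: the caller consumes alignment semantics, and direct emission is
deterministic and desk-scale. Default study conditions: one 1 Mb contig
at 50 % GC, 2×100 bp pairs with a 350 ± 35 bp insert at 30× coverage,
three implanted neo-telomere junctions with microhomology 0, 2 and 4 bp.
Half the coverage comes from the unmodified background haplotype and
half from the per-event derivative (a heterozygous terminal deletion
healed by a 2 kb telomeric tract of 90 % TTAGGG / 10 % variant
hexamers, exercising both classification rules). Derivative reads are
drawn from a window of ±3 inserts around the junction, where the
derivative differs from the reference. Every sample — tumor, control,
panel — also receives baseline unmapped telomeric read pairs emulating
reads from real chromosome ends (0.05 % of reads in controls, 4× that
in tumors), which feed telomere-content estimation but carry no
positional signal. Substitution errors (0.1 %) are never placed within
6 bp of a clip boundary so ground-truth junctions stay exact.

The insertion scenario implants a 300 bp tract (a G-strand half then a
C-strand half, so the two junctions present opposite orientations to the
caller) and widens the insert to 600 ± 60 bp so read pairs spanning the
tract exist; with a standard insert the geometry admits essentially
none — the same reason large insertions evade short-read detection.

What the simulator does **not** emulate: indels and quality-score error
profiles, GC-dependent coverage bias, mappability structure, subclonal
mixtures, or real telomere-length distributions. Passing tests therefore
demonstrate the correctness of the decision rules and the caller's
arithmetic on clean alignment semantics, not robustness to every real
artifact; the panel-of-normals and matched-control filters are exercised
with constructed artifacts only.

The cohort simulator draws a binary exposure and a binary outcome from a
logistic model with a configurable odds ratio, embedding its parameters
in the table's metadata; it backs the calibration checks (type-I error
of the Fisher test near α at n = 600, power > 0.9 at OR = 5).

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open everywhere; SAM (1-based)
  and BED conversions happen only at the I/O boundary.
* Duplicate-flagged reads are excluded from every counting operation but
  preserved by readers and writers.
* Junction ties in refinement resolve to higher split support, then the
  leftmost boundary; repeat phase by majority vote.
* The exact Fisher test is intrinsically conservative on discrete
  tables (true size ≈ 0.045 at n = 600 under the default calibration
  conditions), so a 1,000-replicate type-I estimate scatters around
  that value, not around 0.05 exactly.
* Problem sizes in tests and the acceptance script (1 Mb genome, 30×,
  10⁵-read quantification sets, 1,000 statistical replicates) are chosen
  so the full suite completes in a few minutes on one CPU while every
  support count stays an order of magnitude above its threshold.

## Known limitations

* The caller assumes coordinate-level alignment semantics (clips placed
  exactly at junctions by the upstream aligner); it does not realign.
* Telomere fusions without telomeric sequence at the junction, and
  interstitial telomeric repeats fully embedded in mapped reads, are by
  design not called.
* Hotspot parameters are heuristics, not fitted quantities.
* CRAM input and VCF output are unsupported.
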