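"""Sample-level telomere-maintenance-mechanism (TMM) calls.

Combines the C-Circle assay call, the genomic telomere-content ratio,
MYCN amplification and TERT events into one of five subgroup labels:

* ``ALT`` — C-Circle positive, or log2 telomere content ratio > 1;
* ``MNA`` — telomerase activation by amplified MYCN;
* ``TERT`` — structural variant affecting TERT or a TERT promoter mutation;
* ``HET_ALT_MNA`` — C-Circle negative but log2 telomere content > 1 with
  amplified MYCN (heterogeneous ALT/MNA tumors);
* ``OTHER`` — no genetic evidence of an activated mechanism.

The heterogeneous rule is evaluated first so it can pre-empt the plain ALT
rule; a C-Circle-positive MYCN-amplified tumor is labelled ALT with
``mycn_amp`` kept in the evidence set, and ALT takes precedence over TERT
(empirically mutually exclusive; co-occurrence is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import Config

logger = logging.getLogger("neotel")

TMM_LABELS = ("ALT", "MNA", "TERT", "OTHER", "HET_ALT_MNA")


@dataclass(slots=True)
class CCircleMeasurement:
    """One C-Circle assay quantification (blot AUC values)."""

    sample_id: str
    auc_sample: float
    auc_no_polymerase: float
    auc_positive_control: float
    call: bool = False


@dataclass(slots=True)
class TMMCall:
    sample_id: str
    label: str
    evidence: frozenset[str] = field(default_factory=frozenset)


def call_ccircle(
    auc_sample: float,
    auc_no_polymerase: float,
    auc_positive_control: float,
    cfg: Config | None = None,
) -> bool:
    """C-Circle positivity: >= 4-fold over the no-polymerase control and
    >= 20 % of the ALT-positive assay control signal.

    A no-polymerase AUC of exactly zero satisfies the fold condition (any
    signal is infinitely many folds above zero).
    """
    cfg = cfg or Config()
    if min(auc_sample, auc_no_polymerase, auc_positive_control) < 0:
        raise ValueError("AUC values must be non-negative")
    if auc_positive_control <= 0:
        raise ValueError("positive-control AUC must be positive")
    fold_ok = (
        auc_no_polymerase == 0
        or auc_sample >= cfg.ccircle_fold * auc_no_polymerase
    )
    frac_ok = auc_sample >= cfg.ccircle_pos_frac * auc_positive_control
    return fold_ok and frac_ok


def classify_gene_cnv(
    gene_cn: float,
    ploidy: float,
    minor_cn: float | None = None,
    cfg: Config | None = None,
) -> str:
    """Gene-level copy-number class.

    Amplified when the gene copy number reaches 8 copies scaled by ploidy
    (>= 8 in a diploid genome; ``cfg.amp_mode = "absolute"`` uses a flat
    8-copy cutoff). Below 0.5 copies is a homozygous deletion; any
    non-homozygous loss below ploidy is a deletion; loss of heterozygosity
    that is not also a deletion (copy-neutral LOH) is LOH.
    """
    cfg = cfg or Config()
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    amp_cut = (
        cfg.amp_min_copies
        if cfg.amp_mode == "absolute"
        else cfg.amp_min_copies * ploidy / 2.0
    )
    if gene_cn >= amp_cut:
        return "amplified"
    if gene_cn < 0.5:
        return "homozygous_deletion"
    if gene_cn < ploidy:
        return "deletion"
    if minor_cn is not None and minor_cn == 0:
        return "LOH"
    return "neutral"


def call_tert_promoter(
    ref_reads: int, alt_reads: int, cfg: Config | None = None
) -> bool:
    """Relaxed TERT promoter hotspot call: mutated base in >= 2 reads at a
    variant allele frequency >= 20 %."""
    cfg = cfg or Config()
    depth = ref_reads + alt_reads
    if depth <= 0:
        raise ValueError("zero read depth at the promoter position")
    return (
        alt_reads >= cfg.tertp_min_alt_reads
        and alt_reads / depth >= cfg.tertp_min_vaf
    )


def classify_tmm(
    ccircle: bool,
    log2_telcontent: float,
    mycn_amplified: bool,
    tert_event: bool,
    sample_id: str = "",
    cfg: Config | None = None,
) -> TMMCall:
    """Assign the TMM subgroup label; evidence flags record every true
    predicate regardless of the final label."""
    cfg = cfg or Config()
    telcontent_high = log2_telcontent > cfg.alt_log2_telcontent
    evidence = set()
    if ccircle:
        evidence.add("ccircle_pos")
    if telcontent_high:
        evidence.add("telcontent_high")
    if mycn_amplified:
        evidence.add("mycn_amp")
    if tert_event:
        evidence.add("tert_event")

    if not ccircle and telcontent_high and mycn_amplified:
        label = "HET_ALT_MNA"
    elif ccircle or telcontent_high:
        label = "ALT"
        if tert_event:
            logger.info(
                "%s: ALT evidence co-occurs with a TERT event; labelled ALT",
                sample_id or "<sample>",
            )
    elif mycn_amplified:
        label = "MNA"
    elif tert_event:
        label = "TERT"
    else:
        label = "OTHER"
    return TMMCall(sample_id=sample_id, label=label, evidence=frozenset(evidence))
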