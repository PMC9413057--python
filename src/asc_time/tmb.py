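"""Tumor mutation burden from targeted-panel variant calls.

A candidate somatic variant passes the quality cascade when its variant
allele fraction is >= 2%, it has at least five high-quality supporting
reads (base Phred >= 30, mapping quality >= 30) and shows no paired-end
read bias.  TMB is the count of *nonsynonymous* passing mutations
normalized to the 0.7-Mb targeted coding region, reported per megabase.

For a biphasic tumor, the whole-tumor ("union") TMB integrates the
nonsynonymous mutations of both components, de-duplicated by locus and
allele -- trunk mutations shared by both components count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import VariantCall

__all__ = ["TmbResult", "filter_somatic", "compute_tmb", "union_tmb"]

#: reject-reason codes, in evaluation order
REASON_VAF = "vaf"
REASON_READS = "reads"
REASON_BIAS = "bias"


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    component: str  # "ACC", "SCCC" or "union"
    n_input: int
    n_pass: int
    n_nonsyn_pass: int
    panel_mb: float
    tmb: float  # nonsynonymous mutations per megabase


def filter_somatic(
    variants: Sequence[VariantCall],
    vaf_min: float = 0.02,
    min_hq_reads: int = 5,
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Split variants into (passed, rejected-with-reason).

    Pass requires vaf >= ``vaf_min`` AND hq_support_reads >=
    ``min_hq_reads`` AND no paired-end bias (both cutoffs inclusive).
    Each rejected variant is labeled with the *first* failing criterion,
    evaluated in the fixed order vaf, reads, bias.
    """
    passed: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    for v in variants:
        if v.vaf < vaf_min:
            rejected.append((v, REASON_VAF))
        elif v.hq_support_reads < min_hq_reads:
            rejected.append((v, REASON_READS))
        elif v.pe_bias:
            rejected.append((v, REASON_BIAS))
        else:
            passed.append(v)
    return passed, rejected


def compute_tmb(
    passed: Sequence[VariantCall],
    panel_mb: float = 0.7,
    sample_id: str = "",
    component: str = "",
    n_input: int | None = None,
) -> TmbResult:
    """TMB of one component: nonsynonymous passing mutations / panel_mb."""
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be positive, got {panel_mb}")
    n_nonsyn = sum(v.consequence == "nonsynonymous" for v in passed)
    return TmbResult(
        sample_id=sample_id,
        component=component,
        n_input=len(passed) if n_input is None else n_input,
        n_pass=len(passed),
        n_nonsyn_pass=n_nonsyn,
        panel_mb=panel_mb,
        tmb=n_nonsyn / panel_mb,
    )


def union_tmb(
    acc_passed: Iterable[VariantCall],
    sccc_passed: Iterable[VariantCall],
    panel_mb: float = 0.7,
    sample_id: str = "",
) -> TmbResult:
    """Whole-tumor TMB from the union of both components' mutations.

    Mutations are identified by (chrom, pos, ref, alt); a shared trunk
    mutation counts once even when its VAF differs between components.
    """
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be positive, got {panel_mb}")
    merged: dict[tuple, VariantCall] = {}
    for v in list(acc_passed) + list(sccc_passed):
        merged.setdefault(v.key, v)
    variants = list(merged.values())
    n_nonsyn = sum(v.consequence == "nonsynonymous" for v in variants)
    return TmbResult(
        sample_id=sample_id,
        component="union",
        n_input=len(variants),
        n_pass=len(variants),
        n_nonsyn_pass=n_nonsyn,
        panel_mb=panel_mb,
        tmb=n_nonsyn / panel_mb,
    )
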