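"""Somatic SNV filter chain: caller consensus, artifact, and expression.

Three pure stages applied in order. A variant is kept only if it passes
all three; the verdict names the first failing stage.

* consensus: most somatic callers are DNA-centric, so a variant is allowed
  through if at most ``max_reject`` of the callers rejected it (absent
  callers do not count as rejections).
* oxog: library construction can oxidise guanines, producing low
  allele-fraction C>A / G>T calls supported predominantly by one read of
  the pair. The read-provenance clause drops variants whose alt support
  comes solely from read 1 or solely from read 2 regardless of
  substitution class (the verdict annotates whether the change is
  OxoG-consistent); a second clause drops low allele-fraction variants
  (< cutoff, strict) with no RNA alt-allele evidence.
* expression: unexpressed proteins can never be displayed to T cells, so
  variants are dropped when the gene is unexpressed, when RNA reads span
  but none cover the position (splice variant), or when the ALT allele has
  no RNA evidence.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from neomhc.config import ToolConfig
from neomhc.variants import VariantRecord

STAGES = ("consensus", "oxog", "expression")


@dataclasses.dataclass(frozen=True)
class FilterVerdict:
    kept: bool
    stage: str  # consensus|oxog|expression|passed
    reason: str

    def __post_init__(self) -> None:
        if self.kept != (self.stage == "passed"):
            raise ValueError("kept must be equivalent to stage == 'passed'")


def _kept(stage_reason: str = "ok") -> FilterVerdict:
    return FilterVerdict(kept=True, stage="passed", reason=stage_reason)


def consensus_filter(v: VariantRecord, max_reject: int = 2) -> FilterVerdict:
    """Keep unless strictly more than ``max_reject`` callers rejected."""
    statuses = [s for s in v.caller_status.values() if s]
    if not statuses:
        raise ValueError(f"{v.key}: no caller evidence at all")
    n_rejected = sum(1 for s in statuses if s == "rejected")
    if n_rejected > max_reject:
        return FilterVerdict(
            kept=False, stage="consensus",
            reason=f"rejected-by-{n_rejected}-callers",
        )
    return _kept()


def oxog_filter(v: VariantRecord,
                allele_fraction_cutoff: float = 0.1) -> FilterVerdict:
    """Read-provenance and low-AF/no-RNA artifact clauses."""
    r1, r2 = v.alt_read1_count, v.alt_read2_count
    if r1 == 0 and r2 == 0:
        raise ValueError(f"{v.key}: no alt-supporting reads in either mate")
    oxog_tag = "oxog-consistent" if v.is_oxog_consistent else "other-substitution"
    if (r1 > 0) != (r2 > 0):
        mate = "read1-only" if r1 > 0 else "read2-only"
        return FilterVerdict(kept=False, stage="oxog",
                             reason=f"{mate} ({oxog_tag})")
    rna_alt = v.rna_alt_count if v.rna_alt_count is not None else 0
    if v.allele_fraction < allele_fraction_cutoff and rna_alt == 0:
        return FilterVerdict(kept=False, stage="oxog",
                             reason=f"low-AF-no-RNA ({oxog_tag})")
    return _kept()


def expression_filter(v: VariantRecord,
                      expression_cutoff: float = 0.0) -> FilterVerdict:
    """Drop variants with no usable RNA expression evidence."""
    gexp = v.gene_expression if v.gene_expression is not None else 0.0
    if gexp <= expression_cutoff:
        return FilterVerdict(kept=False, stage="expression",
                             reason="unexpressed-gene")
    spanning = v.rna_spanning_reads or 0
    depth = v.rna_depth if v.rna_depth is not None else 0
    if spanning > 0 and depth == 0:
        return FilterVerdict(kept=False, stage="expression",
                             reason="splice-variant")
    rna_alt = v.rna_alt_count if v.rna_alt_count is not None else 0
    if rna_alt == 0:
        return FilterVerdict(kept=False, stage="expression",
                             reason="unexpressed-ALT")
    return _kept()


def run_filter_chain(
    records: Iterable[VariantRecord],
    config: ToolConfig | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply consensus -> oxog -> expression in order.

    Returns the kept records plus an audit table with one row per input
    (variant key, stage, reason, kept). The verdict records only the first
    failing stage.
    """
    cfg = config or ToolConfig()
    kept: list[VariantRecord] = []
    rows = []
    for v in records:
        verdict = consensus_filter(v, cfg.max_caller_rejects)
        if verdict.kept:
            verdict = oxog_filter(v, cfg.allele_fraction_cutoff)
        if verdict.kept:
            verdict = expression_filter(v, cfg.expression_cutoff)
        if verdict.kept:
            kept.append(v)
        rows.append({"variant": v.key, "stage": verdict.stage,
                     "reason": verdict.reason, "kept": verdict.kept})
    audit = pd.DataFrame(rows, columns=["variant", "stage", "reason", "kept"])
    return kept, audit
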