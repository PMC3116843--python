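"""Orchestration of the candidate funnel and the per-stage report.

Stages run in screening order: proximity to methylation -> exclusion of
known methylation-regulated and imprinted-cluster miRNAs -> expression
concordance between the methylated line and its demethylated
derivative -> demethylating-drug re-expression in the primary cell
line -> cross-cell-line confirmation -> host-gene independence.  Every
stage-1 candidate keeps a :class:`CandidateRecord` tracing the evidence
it accumulated and the stage at which it dropped out, and the
:class:`FunnelReport` carries the per-stage counts and id lists with a
weak-monotonicity invariant along the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from mirmeth.context import (
    ContextCall,
    Context,
    HostResponse,
    Independence,
    TranscriptModel,
    classify_context,
    derive_host_response,
    independence_call,
    promoter_methylation_flag,
)
from mirmeth.expression import (
    Concordance,
    DifferentialResult,
    ExpressionMatrix,
    classify_concordance,
    differential_expression,
    normalize_matrix,
)
from mirmeth.intervals import GenomicInterval
from mirmeth.methylome import MethylomeProfile, call_methylome
from mirmeth.proximity import MiRNAAnnotation, ProximityCall, screen_candidates
from mirmeth.qpcr import (
    QPCRMeasurement,
    ReexpressionResult,
    confirm_across_lines,
    reexpression_test,
)


class ExclusionReason(str, Enum):
    KNOWN_REGULATED = "known_regulated"
    IMPRINTED = "imprinted"
    NONE = "none"


class FinalClass(str, Enum):
    NOVEL_METH_REGULATED = "novel_meth_regulated"
    EXCLUDED = "excluded"
    FAILED_EXPRESSION = "failed_expression"
    FAILED_REEXPRESSION = "failed_reexpression"
    FAILED_CONFIRMATION = "failed_confirmation"
    FAILED_INDEPENDENCE = "failed_independence"
    UNTESTED = "untested"


@dataclass
class CandidateRecord:
    """One miRNA's accumulated evidence across every funnel stage."""

    mirna_id: str
    proximity: ProximityCall
    excluded_reason: ExclusionReason = ExclusionReason.NONE
    differential: DifferentialResult | None = None
    concordance: Concordance | None = None
    aza_results: dict[str, ReexpressionResult] = field(default_factory=dict)
    confirmed: bool = False
    context: ContextCall | None = None
    final_class: FinalClass | None = None


@dataclass
class FunnelReport:
    """Per-stage id lists; counts derive from the lists."""

    proximal: list[str]
    known_or_imprinted_excluded: list[str]
    novel_candidates: list[str]
    expression_consistent: list[str]
    aza_upregulated_primary: list[str]
    confirmed_all_lines: list[str]
    independent_final: list[str]

    def counts(self) -> dict[str, int]:
        return {
            "proximal": len(self.proximal),
            "known_or_imprinted_excluded": len(self.known_or_imprinted_excluded),
            "novel_candidates": len(self.novel_candidates),
            "expression_consistent": len(self.expression_consistent),
            "aza_upregulated_primary": len(self.aza_upregulated_primary),
            "confirmed_all_lines": len(self.confirmed_all_lines),
            "independent_final": len(self.independent_final),
        }

    def validate(self) -> None:
        c = self.counts()
        if c["novel_candidates"] != c["proximal"] - c["known_or_imprinted_excluded"]:
            raise RuntimeError(
                "funnel inconsistency: novel != proximal - excluded "
                f"({c['novel_candidates']} != {c['proximal']} - "
                f"{c['known_or_imprinted_excluded']})"
            )
        chain = [
            "novel_candidates",
            "expression_consistent",
            "aza_upregulated_primary",
            "confirmed_all_lines",
            "independent_final",
        ]
        for a, b in zip(chain, chain[1:]):
            if c[b] > c[a]:
                raise RuntimeError(
                    f"funnel inconsistency: {b} ({c[b]}) exceeds {a} ({c[a]})"
                )


def apply_exclusions(
    candidates: list[ProximityCall],
    known_ids: set[str],
    imprinted_ids: set[str],
) -> tuple[list[ProximityCall], dict[str, ExclusionReason]]:
    """Partition candidates into novel and excluded.

    A candidate on both lists is excluded once, with known-regulated
    taking precedence over imprinted.
    """
    excluded: dict[str, ExclusionReason] = {}
    remaining: list[ProximityCall] = []
    for call in candidates:
        if call.mirna_id in known_ids:
            excluded[call.mirna_id] = ExclusionReason.KNOWN_REGULATED
        elif call.mirna_id in imprinted_ids:
            excluded[call.mirna_id] = ExclusionReason.IMPRINTED
        else:
            remaining.append(call)
    return remaining, excluded


def _expression_matrix_from_tidy(
    tidy: pd.DataFrame,
) -> ExpressionMatrix:
    values = tidy.pivot(index="mirna_id", columns="sample", values="value")
    meta = (
        tidy[["sample", "cell_line"]]
        .drop_duplicates()
        .set_index("sample")
    )
    return ExpressionMatrix(values=values, sample_meta=meta)


def _measurements_from_tidy(
    tidy: pd.DataFrame,
) -> tuple[dict[tuple[str, str, str], QPCRMeasurement], set[str]]:
    """Group a tidy Ct table into measurements keyed (target, line, condition).

    Targets whose target-channel Ct is missing in every well are
    reported as undetectable (the not-expressed host-gene case) rather
    than raising.
    """
    measurements: dict[tuple[str, str, str], QPCRMeasurement] = {}
    undetectable: set[str] = set()
    for target, sub in tidy.groupby("target"):
        if sub["ct_target"].isna().all():
            undetectable.add(str(target))
            continue
        for (line, condition), grp in sub.groupby(["cell_line", "condition"]):
            grp = grp.sort_values("replicate")
            measurements[(str(target), str(line), str(condition))] = QPCRMeasurement(
                target_id=str(target),
                reference_id=str(grp["reference"].iloc[0]),
                cell_line=str(line),
                condition=str(condition),
                target_ct=tuple(float(x) for x in grp["ct_target"]),
                reference_ct=tuple(float(x) for x in grp["ct_reference"]),
            )
    return measurements, undetectable


def _reexpression_by_line(
    measurements: dict[tuple[str, str, str], QPCRMeasurement],
    target: str,
    lines: tuple[str, ...],
    alpha: float,
) -> dict[str, ReexpressionResult]:
    out = {}
    for line in lines:
        treated = measurements.get((target, line, "treated"))
        untreated = measurements.get((target, line, "untreated"))
        if treated is None or untreated is None:
            continue
        out[line] = reexpression_test(treated, untreated, alpha=alpha)
    return out


def funnel_report(
    records: dict[str, CandidateRecord],
    primary_line: str = "lineA",
) -> FunnelReport:
    """Re-derive the per-stage report from completed candidate records.

    The report is a pure function of the records; the validation step
    raises on any internal inconsistency rather than correcting it
    silently.
    """
    proximal = sorted(records)
    excluded = sorted(
        m for m, r in records.items() if r.excluded_reason != ExclusionReason.NONE
    )
    novel = sorted(set(proximal) - set(excluded))
    novel_set = set(novel)
    consistent = sorted(
        m
        for m in novel
        if records[m].concordance
        in (Concordance.CONSISTENT_UPREGULATED, Concordance.CONSISTENT_RETAINED_SILENCED)
        or records[m].aza_results  # rescued candidates routed onward anyway
    )
    upregulated = sorted(
        m
        for m, r in records.items()
        if m in novel_set
        and primary_line in r.aza_results
        and r.aza_results[primary_line].significant
    )
    confirmed = sorted(m for m in upregulated if records[m].confirmed)
    final = sorted(
        m
        for m in confirmed
        if records[m].final_class == FinalClass.NOVEL_METH_REGULATED
    )
    report = FunnelReport(
        proximal=proximal,
        known_or_imprinted_excluded=excluded,
        novel_candidates=novel,
        expression_consistent=consistent,
        aza_upregulated_primary=upregulated,
        confirmed_all_lines=confirmed,
        independent_final=final,
    )
    report.validate()
    return report


def run_screen(
    mirnas: list[MiRNAAnnotation],
    ref_reads: list[GenomicInterval],
    demeth_reads: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    expression_tidy: pd.DataFrame,
    qpcr_tidy: pd.DataFrame,
    transcripts: list[TranscriptModel],
    ref_line: str = "HCT116like",
    demeth_line: str = "DKOlike",
    primary_line: str = "lineA",
    validation_lines: tuple[str, ...] = ("lineB", "lineC"),
    window_size: int = 500,
    alpha: float = 0.01,
    max_dist: int = 500,
    fold_threshold: float = 1.5,
    q_threshold: float = 0.05,
    qpcr_alpha: float = 0.05,
    promoter_flank: int = 1000,
    rescue_inconsistent: bool = False,
    known_ids: set[str] | None = None,
    imprinted_ids: set[str] | None = None,
) -> tuple[dict[str, CandidateRecord], FunnelReport]:
    """Execute every stage of the screen and build the funnel report.

    Exclusion lists default to the flags carried on the annotations.
    ``rescue_inconsistent`` routes expression-inconsistent candidates
    to the qPCR stage anyway (off by default).  Returns the per-miRNA
    records and the validated report.
    """
    if known_ids is None:
        known_ids = {m.mirna_id for m in mirnas if m.known_methylation_regulated}
    if imprinted_ids is None:
        imprinted_ids = {m.mirna_id for m in mirnas if m.imprinted_cluster}

    # stage 1: methylomes and proximity
    ref_profile = call_methylome(
        ref_reads, chrom_sizes, window_size=window_size, alpha=alpha, sample_id="reference"
    )
    demeth_profile = call_methylome(
        demeth_reads,
        chrom_sizes,
        window_size=window_size,
        alpha=alpha,
        sample_id="demethylated",
    )
    calls = screen_candidates(mirnas, ref_profile, demeth_profile, max_dist=max_dist)
    records = {c.mirna_id: CandidateRecord(mirna_id=c.mirna_id, proximity=c) for c in calls}

    # stage 2: exclusions
    novel_calls, excluded = apply_exclusions(calls, known_ids, imprinted_ids)
    for mid, reason in excluded.items():
        records[mid].excluded_reason = reason
        records[mid].final_class = FinalClass.EXCLUDED

    # stage 3: expression concordance
    if len(expression_tidy) and novel_calls:
        matrix = normalize_matrix(_expression_matrix_from_tidy(expression_tidy))
        diff = differential_expression(matrix, ref_line, demeth_line)
    else:
        diff = {}
    consistent_ids: list[str] = []
    to_qpcr: list[str] = []
    for call in novel_calls:
        rec = records[call.mirna_id]
        rec.differential = diff.get(call.mirna_id)
        rec.concordance = classify_concordance(
            call, rec.differential, fold_threshold=fold_threshold,
            sig_threshold=q_threshold,
        )
        if rec.concordance in (
            Concordance.CONSISTENT_UPREGULATED,
            Concordance.CONSISTENT_RETAINED_SILENCED,
        ):
            consistent_ids.append(call.mirna_id)
            to_qpcr.append(call.mirna_id)
        elif rescue_inconsistent and rec.concordance == Concordance.INCONSISTENT:
            to_qpcr.append(call.mirna_id)
        elif rec.concordance == Concordance.UNTESTED:
            rec.final_class = FinalClass.UNTESTED
        else:
            rec.final_class = FinalClass.FAILED_EXPRESSION

    # stages 4-5: re-expression in the primary line, then confirmation
    if len(qpcr_tidy):
        measurements, undetectable = _measurements_from_tidy(qpcr_tidy)
    else:
        measurements, undetectable = {}, set()
    lines = (primary_line, *validation_lines)
    upregulated_primary: list[str] = []
    all_results: list[ReexpressionResult] = []
    for mid in to_qpcr:
        rec = records[mid]
        rec.aza_results = _reexpression_by_line(
            measurements, f"pri-{mid}", lines, alpha=qpcr_alpha
        )
        all_results.extend(rec.aza_results.values())
        prim = rec.aza_results.get(primary_line)
        if prim is not None and prim.significant:
            upregulated_primary.append(mid)
        elif rec.final_class is None:
            rec.final_class = FinalClass.FAILED_REEXPRESSION

    confirmed_set, _partial = confirm_across_lines(
        all_results, primary_line, list(validation_lines)
    )
    confirmed_ids: list[str] = []
    for mid in upregulated_primary:
        rec = records[mid]
        if f"pri-{mid}" in confirmed_set:
            rec.confirmed = True
            confirmed_ids.append(mid)
        elif rec.final_class is None:
            rec.final_class = FinalClass.FAILED_CONFIRMATION

    # stage 6: genomic context and independence
    final_ids: list[str] = []
    by_id = {m.mirna_id: m for m in mirnas}
    tx_by_gene = {t.gene_id: t for t in transcripts}
    for mid in confirmed_ids:
        rec = records[mid]
        cc = classify_context(by_id[mid], transcripts)
        if cc.context == Context.INTRONIC and cc.host_gene_id is not None:
            host = tx_by_gene[cc.host_gene_id]
            cc.host_promoter_methylated = promoter_methylation_flag(
                host, ref_profile, flank=promoter_flank
            )
            host_results = _reexpression_by_line(
                measurements, cc.host_gene_id, lines, alpha=qpcr_alpha
            )
            mirna_sig = {ln for ln, r in rec.aza_results.items() if r.significant}
            cc.host_response = derive_host_response(
                list(host_results.values()),
                mirna_sig,
                host_detectable=cc.host_gene_id not in undetectable,
            )
        cc.independence = independence_call(cc, mirna_aza_significant=True)
        rec.context = cc
        if cc.independence == Independence.INDEPENDENT:
            rec.final_class = FinalClass.NOVEL_METH_REGULATED
            final_ids.append(mid)
        else:
            rec.final_class = FinalClass.FAILED_INDEPENDENCE

    report = FunnelReport(
        proximal=sorted(records),
        known_or_imprinted_excluded=sorted(excluded),
        novel_candidates=sorted(c.mirna_id for c in novel_calls),
        expression_consistent=sorted(set(consistent_ids) | set(to_qpcr)),
        aza_upregulated_primary=sorted(upregulated_primary),
        confirmed_all_lines=sorted(confirmed_ids),
        independent_final=sorted(final_ids),
    )
    report.validate()
    return records, report
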