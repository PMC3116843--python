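"""Genomic context and host-gene transcriptional independence.

An intronic miRNA can be co-transcribed from its host gene's promoter,
in which case proximal DNA methylation at the miRNA would not be the
regulator of its transcription.  This module classifies each candidate
stem-loop as intergenic, intronic or exonic against a set of transcript
models, flags methylation at the putative host promoter (+/-1000 bp
around the TSS), derives the host gene's demethylating-drug response
category from qPCR results, and applies the independence decision
table:

- intergenic                                    -> independent
- intronic, host no_change or not_expressed     -> independent
- host inconsistent_increase / concordant_increase -> possibly_coregulated
- missing host data (or exonic context)         -> indeterminate
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from intervaltree import IntervalTree

from mirmeth.intervals import GenomicInterval
from mirmeth.methylome import MethylomeProfile
from mirmeth.proximity import MiRNAAnnotation
from mirmeth.qpcr import ReexpressionResult

DEFAULT_PROMOTER_FLANK = 1000


class Context(str, Enum):
    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    EXONIC = "exonic"


class HostResponse(str, Enum):
    NO_CHANGE = "no_change"
    INCONSISTENT_INCREASE = "inconsistent_increase"
    CONCORDANT_INCREASE = "concordant_increase"
    NOT_EXPRESSED = "not_expressed"


class Independence(str, Enum):
    INDEPENDENT = "independent"
    POSSIBLY_COREGULATED = "possibly_coregulated"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with strand-aware TSS and exon structure."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: transcript needs an explicit strand")
        for exon in self.exons:
            if not self.interval.contains(exon):
                raise ValueError(
                    f"{self.gene_id}: exon {exon.start}-{exon.end} outside transcript"
                )

    @property
    def tss(self) -> int:
        """Transcription start site: the strand-appropriate transcript end."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1


@dataclass
class ContextCall:
    mirna_id: str
    context: Context
    host_gene_id: str | None = None
    all_hosts: tuple[str, ...] = ()
    host_promoter_methylated: bool | None = None
    host_response: HostResponse | None = None
    independence: Independence | None = None


def classify_context(
    mirna: MiRNAAnnotation, transcripts: list[TranscriptModel]
) -> ContextCall:
    """Assign exactly one genomic context to a miRNA stem-loop.

    Exonic when the stem-loop overlaps any exon; otherwise intronic
    when fully contained in at least one transcript (the host is the
    smallest containing transcript, all containing transcripts are
    reported); intergenic otherwise.
    """
    sl = mirna.stemloop
    if any(
        exon.overlaps(sl) for t in transcripts for exon in t.exons
    ):
        containing = [t for t in transcripts if t.interval.contains(sl)]
        host = min(containing, key=lambda t: len(t.interval)).gene_id if containing else None
        return ContextCall(
            mirna_id=mirna.mirna_id,
            context=Context.EXONIC,
            host_gene_id=host,
            all_hosts=tuple(t.gene_id for t in containing),
        )
    containing = [t for t in transcripts if t.interval.contains(sl)]
    if containing:
        host = min(containing, key=lambda t: len(t.interval))
        return ContextCall(
            mirna_id=mirna.mirna_id,
            context=Context.INTRONIC,
            host_gene_id=host.gene_id,
            all_hosts=tuple(t.gene_id for t in containing),
        )
    return ContextCall(mirna_id=mirna.mirna_id, context=Context.INTERGENIC)


def promoter_methylation_flag(
    host: TranscriptModel,
    profile: MethylomeProfile,
    flank: int = DEFAULT_PROMOTER_FLANK,
) -> bool:
    """True iff a significant region overlaps [TSS - flank, TSS + flank).

    Half-open overlap: a region abutting the window end does not count.
    """
    window_start = max(0, host.tss - flank)
    window = GenomicInterval(host.interval.chrom, window_start, host.tss + flank)
    tree = IntervalTree()
    for region in profile.intervals():
        if region.chrom == window.chrom:
            tree[region.start : region.end] = region
    return bool(tree.overlap(window.start, window.end))


def derive_host_response(
    host_results: list[ReexpressionResult],
    mirna_significant_lines: set[str],
    host_detectable: bool = True,
) -> HostResponse:
    """Categorise the host gene's demethylating-drug response.

    Compares the lines where the host re-expressed significantly with
    the lines where its embedded miRNA did: significant nowhere ->
    no_change; significant in every line the miRNA responded in ->
    concordant_increase; significant in a strict subset ->
    inconsistent_increase.  A host with undetectable Ct in all
    conditions is not_expressed.
    """
    if not host_detectable:
        return HostResponse.NOT_EXPRESSED
    host_lines = {r.cell_line for r in host_results if r.significant}
    if not host_lines:
        return HostResponse.NO_CHANGE
    if mirna_significant_lines and mirna_significant_lines <= host_lines:
        return HostResponse.CONCORDANT_INCREASE
    return HostResponse.INCONSISTENT_INCREASE


def independence_call(cc: ContextCall, mirna_aza_significant: bool) -> Independence:
    """Decision table for host-gene transcriptional independence.

    Only confirmed drug responders are classified; calling this with
    ``mirna_aza_significant=False`` is a precondition violation.
    """
    if not mirna_aza_significant:
        raise ValueError(
            f"{cc.mirna_id}: independence is only decided for confirmed responders"
        )
    if cc.context == Context.INTERGENIC:
        return Independence.INDEPENDENT
    if cc.context == Context.EXONIC:
        return Independence.INDETERMINATE
    if cc.host_response is None:
        return Independence.INDETERMINATE
    if cc.host_response in (HostResponse.NO_CHANGE, HostResponse.NOT_EXPRESSED):
        return Independence.INDEPENDENT
    return Independence.POSSIBLY_COREGULATED
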