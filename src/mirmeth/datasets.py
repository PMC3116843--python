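"""Built-in fixtures: the ten confirmed candidates of the colorectal screen.

The screen's ten drug-confirmed candidate miRNAs, with their published
genomic contexts, putative host genes, host-promoter methylation status
and host-gene demethylating-drug responses, are small enough to carry
as a built-in dataset.  Genomic coordinates here are synthetic: each
intronic candidate is placed inside an intron of a transcript model
standing in for its named host, and the intergenic candidates sit
outside all transcripts, so the context classifier reproduces the
published context assignments from geometry alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from mirmeth.context import (
    Context,
    ContextCall,
    HostResponse,
    TranscriptModel,
)
from mirmeth.intervals import GenomicInterval
from mirmeth.proximity import MiRNAAnnotation


@dataclass(frozen=True)
class ConfirmedCandidate:
    mirna_id: str
    host_gene: str | None  # None = intergenic
    host_promoter_methylated: bool | None
    host_response: HostResponse | None


#: The ten confirmed candidates: genomic context, host-promoter
#: methylation in the methylated line, and host response to 5-aza-dC.
CONFIRMED_CANDIDATES: tuple[ConfirmedCandidate, ...] = (
    ConfirmedCandidate("hsa-miR-1237", "RPS6KA4", False, HostResponse.NO_CHANGE),
    ConfirmedCandidate("hsa-miR-1247", None, None, None),
    ConfirmedCandidate("hsa-miR-1826", None, None, None),
    ConfirmedCandidate("hsa-miR-219-2", None, None, None),
    ConfirmedCandidate("hsa-miR-24-1", "C9orf3", False, HostResponse.INCONSISTENT_INCREASE),
    ConfirmedCandidate("hsa-miR-27b", "C9orf3", False, HostResponse.INCONSISTENT_INCREASE),
    ConfirmedCandidate("hsa-miR-602", "AB058779", False, HostResponse.NO_CHANGE),
    ConfirmedCandidate("hsa-miR-663b", "ANKRD30BL", True, HostResponse.NOT_EXPRESSED),
    ConfirmedCandidate("hsa-miR-941-1", "DNAJC5", False, HostResponse.NO_CHANGE),
    ConfirmedCandidate("hsa-miR-941-3", "DNAJC5", False, HostResponse.NO_CHANGE),
)


def confirmed_candidate_context_calls() -> list[ContextCall]:
    """The ten candidates as ready-made :class:`ContextCall` records."""
    calls = []
    for c in CONFIRMED_CANDIDATES:
        if c.host_gene is None:
            calls.append(ContextCall(mirna_id=c.mirna_id, context=Context.INTERGENIC))
        else:
            calls.append(
                ContextCall(
                    mirna_id=c.mirna_id,
                    context=Context.INTRONIC,
                    host_gene_id=c.host_gene,
                    all_hosts=(c.host_gene,),
                    host_promoter_methylated=c.host_promoter_methylated,
                    host_response=c.host_response,
                )
            )
    return calls


def confirmed_candidate_annotation() -> tuple[list[MiRNAAnnotation], list[TranscriptModel]]:
    """Synthetic-coordinate annotation realizing the published contexts.

    One 10 kb slot per candidate on a single synthetic chromosome; the
    two candidates sharing a host (miR-24-1 and miR-27b in C9orf3, the
    miR-941 copies in DNAJC5) are placed in separate introns of one
    shared transcript model.
    """
    slot = 10_000
    chrom = "chrSyn"
    mirnas: list[MiRNAAnnotation] = []
    hosts: dict[str, list[int]] = {}
    for i, c in enumerate(CONFIRMED_CANDIDATES):
        s = i * slot
        mirnas.append(
            MiRNAAnnotation(
                mirna_id=c.mirna_id,
                stemloop=GenomicInterval(chrom, s + 4000, s + 4085, "+"),
            )
        )
        if c.host_gene is not None:
            hosts.setdefault(c.host_gene, []).append(i)
    transcripts: list[TranscriptModel] = []
    for gene, slots_used in hosts.items():
        lo, hi = min(slots_used) * slot, max(slots_used) * slot
        start, end = lo + 1000, hi + 9000
        # one exon per inter-miRNA boundary so each stem-loop is intronic
        exon_edges = [start]
        for i in slots_used:
            exon_edges.extend([i * slot + 3000, i * slot + 6000])
        exon_edges.append(end)
        exons = tuple(
            GenomicInterval(chrom, exon_edges[k], exon_edges[k] + 200, "+")
            for k in range(0, len(exon_edges), 2)
        )
        transcripts.append(
            TranscriptModel(
                gene_id=gene,
                interval=GenomicInterval(chrom, start, end, "+"),
                exons=exons,
            )
        )
    return mirnas, transcripts
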