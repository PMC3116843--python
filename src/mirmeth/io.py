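"""File-format adapters: BED6, GFF3, FASTA and the TSV tables.

Everything genomic is exchanged in plain-text standard formats so that
real data (read placements from an aligner, miRBase-style annotations,
RefSeq transcript models) can be dropped in for the synthetic
fixtures.  FASTA goes through Biopython; GFF3 through gffutils; the
tabular formats through pandas.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirmeth.context import TranscriptModel
from mirmeth.intervals import GenomicInterval
from mirmeth.methylome import MethylomeProfile
from mirmeth.proximity import MiRNAAnnotation

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(
    intervals: Iterable[tuple[GenomicInterval, str, int]], path: str | os.PathLike
) -> None:
    """Write (interval, name, score) triples as BED6."""
    rows = [
        (iv.chrom, iv.start, iv.end, name, score, iv.strand)
        for iv, name, score in intervals
    ]
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED file (3-6 columns) into a DataFrame with BED6 names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    return df


def read_reads_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    df = read_bed(path)
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def read_mirna_bed(
    path: str | os.PathLike, flags: pd.DataFrame | None = None
) -> list[MiRNAAnnotation]:
    """miRNA stem-loop annotations from BED6, with optional flag table.

    ``flags`` is an optional DataFrame indexed by miRNA id with boolean
    columns ``known_methylation_regulated`` and ``imprinted_cluster``.
    """
    df = read_bed(path)
    out = []
    for r in df.itertuples():
        known = imprinted = False
        if flags is not None and r.name in flags.index:
            row = flags.loc[r.name]
            known = bool(row.get("known_methylation_regulated", False))
            imprinted = bool(row.get("imprinted_cluster", False))
        out.append(
            MiRNAAnnotation(
                mirna_id=str(r.name),
                stemloop=GenomicInterval(
                    str(r.chrom), int(r.start), int(r.end), str(r.strand)
                ),
                known_methylation_regulated=known,
                imprinted_cluster=imprinted,
            )
        )
    return out


def write_regions_bed(profile: MethylomeProfile, path: str | os.PathLike) -> None:
    """Called methylated regions as BED6; score = max window read count."""
    write_bed(
        ((iv, f"{profile.sample_id}_region_{i}", score) for i, (iv, score) in enumerate(profile.regions)),
        path,
    )


def read_regions_bed(
    path: str | os.PathLike, sample_id: str, threshold_reads: int = 1
) -> MethylomeProfile:
    df = read_bed(path)
    regions = [
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), int(r.score))
        for r in df.itertuples()
    ]
    return MethylomeProfile(
        sample_id=sample_id, threshold_reads=threshold_reads, regions=regions
    )


def write_transcripts_gff3(
    transcripts: Iterable[TranscriptModel], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            iv = t.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "mirmeth",
                        "transcript",
                        str(iv.start + 1),  # GFF3 is 1-based inclusive
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={t.gene_id};gene_id={t.gene_id}",
                    ]
                )
                + "\n"
            )
            for i, exon in enumerate(t.exons):
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "mirmeth",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            iv.strand,
                            ".",
                            f"ID={t.gene_id}.exon{i};Parent={t.gene_id}",
                        ]
                    )
                    + "\n"
                )


def read_transcripts_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type("transcript"):
        exons = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end, feat.strand)
            for e in db.children(feat, featuretype="exon", order_by="start")
        )
        out.append(
            TranscriptModel(
                gene_id=feat.id,
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand),
                exons=exons,
            )
        )
    return sorted(out, key=lambda t: (t.interval.chrom, t.interval.start, t.gene_id))


def write_fasta(records: dict[str, str], path: str | os.PathLike) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
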