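"""Synthetic two-cell-line world with planted ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: a methylated reference cell line and an isogenic demethylated
derivative that retains only a fraction of the planted methylated
regions; MBD-enrichment reads with Poisson background and fold-enriched
peaks over planted regions; a triplicate expression matrix in which
miRNAs that lose their proximal methylation re-express; qPCR Ct tables
with a planted demethylating-drug response for the regulated miRNAs
(and, for host-driven miRNAs, a concordant response of the host gene);
bisulfite clones drawn per-CpG Bernoulli; and phenotype assay tables
with planted group effects.  Everything is deterministic under the
configured seed, and a :class:`TruthManifest` records every planted
effect for recovery testing.

The genome is laid out in fixed feature slots so that placements can
never collide: each miRNA occupies one slot containing (left to right)
an optional host transcript TSS and first exon, the intronic stem-loop,
the planted methylated region overlapping the stem-loop, and the host's
last exon.  Host promoters (+/-1000 bp of the TSS) never overlap
planted regions, so an intronic miRNA's methylation is attributable to
the miRNA, not the host — host-driven regulation is planted in the qPCR
layer instead.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from mirmeth import io as mio
from mirmeth.bisulfite import in_silico_convert
from mirmeth.context import TranscriptModel
from mirmeth.intervals import GenomicInterval, gap_distance
from mirmeth.proximity import MiRNAAnnotation

READ_LENGTH = 36  # GAII-era single-end reads, fixed length

# slot geometry (bp offsets within a 7000 bp slot)
SLOT_SIZE = 7000
TX_START, TX_END = 500, 5500
EXON1_END = 900
EXON2_START = 4500
STEMLOOP_START, STEMLOOP_END = 2800, 2880
REGION_START, REGION_END = 2500, 3000

REFERENCE_SAMPLE = "reference"
DEMETHYLATED_SAMPLE = "demethylated"
AZA_TREATED_SAMPLE = "aza_treated"
CELL_LINES = ("lineA", "lineB", "lineC")

# deterministic 10-bp amplicon block: CpG at offset 5, a lone non-CpG C at 1
_AMPLICON_BLOCK = "ACTAACGTAA"
AMPLICON_N_CPGS = 20


@dataclass
class WorldConfig:
    """Parameters of the synthetic two-cell-line world.

    Proportions lie in [0, 1]; ``peak_enrichment`` is the fold increase
    of the in-region read rate over ``background_read_rate``;
    ``expression_silencing_factor`` is the fold by which a silenced
    miRNA re-expresses once its methylation is lost; ``replicate_cv``
    is the coefficient of variation of the multiplicative replicate
    noise.  The same seed always yields byte-identical outputs.
    """

    genome_length: int = 140_000
    n_chroms: int = 2
    n_mirnas: int = 30
    n_transcripts: int = 12
    frac_methylated_mirnas: float = 0.3
    frac_retained_in_demethylated: float = 0.75
    background_read_rate: float = 0.02
    peak_enrichment: float = 8.0
    expression_silencing_factor: float = 3.0
    replicate_cv: float = 0.1
    bisulfite_conversion_rate: float = 0.99
    seed: int = 0
    # funnel-composition knobs
    n_known_regulated: int = 2
    n_imprinted: int = 1
    n_coregulated: int = 1
    # assay noise and planted effect sizes
    qpcr_ct_sd: float = 0.1
    aza_fold: float = 4.0
    cpg_meth_high: float = 0.9
    cpg_meth_low: float = 0.3
    n_clones: int = 8
    baseline_expression: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "frac_methylated_mirnas",
            "frac_retained_in_demethylated",
            "bisulfite_conversion_rate",
            "cpg_meth_high",
            "cpg_meth_low",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.peak_enrichment <= 1:
            raise ValueError("peak_enrichment must exceed 1")
        if self.genome_length < 10 * SLOT_SIZE:
            raise ValueError(
                f"genome_length must be >= {10 * SLOT_SIZE} "
                "(ten times the largest feature span)"
            )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.genome_length for i in range(self.n_chroms)}


@dataclass
class TruthManifest:
    """Every planted effect, for downstream recovery testing."""

    methylated_regions: dict[str, list[GenomicInterval]]
    regulated_mirnas: list[str]
    coregulated_mirnas: list[str]
    imprinted_or_known_ids: list[str]
    per_cpg_methylation: dict[str, dict[str, float]]
    retained_mirnas: list[str] = field(default_factory=list)
    lost_mirnas: list[str] = field(default_factory=list)
    region_by_mirna: dict[str, GenomicInterval] = field(default_factory=dict)
    host_by_mirna: dict[str, str] = field(default_factory=dict)

    @property
    def expected_final(self) -> set[str]:
        """Planted independently methylation-regulated miRNAs."""
        return set(self.regulated_mirnas)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, GenomicInterval):
                return {"chrom": o.chrom, "start": o.start, "end": o.end}
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=enc, indent=1, sort_keys=True)


@dataclass
class World:
    config: WorldConfig
    mirnas: list[MiRNAAnnotation]
    transcripts: list[TranscriptModel]
    amplicons: dict[str, str]
    manifest: TruthManifest


def _rng(config: WorldConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per generator stage."""
    return np.random.default_rng(
        [zlib.crc32(stream.encode()) % (2**31), config.seed]
    )


def generate_world(
    config: WorldConfig, out_dir: str | os.PathLike | None = None
) -> World:
    """Lay out the genome and plant the ground truth.

    Returns the in-memory world; when ``out_dir`` is given, also writes
    ``mirnas.bed``, ``transcripts.gff3``, ``amplicons.fasta`` and
    ``manifest.json`` there.
    """
    rng = _rng(config, "world")
    slots_per_chrom = config.genome_length // SLOT_SIZE
    chroms = list(config.chrom_sizes)
    total_slots = slots_per_chrom * len(chroms)
    if config.n_mirnas > total_slots:
        raise ValueError(
            f"infeasible placement: {config.n_mirnas} miRNAs need "
            f"{config.n_mirnas} slots of {SLOT_SIZE} bp but the genome "
            f"provides only {total_slots}"
        )

    n_meth = round(config.frac_methylated_mirnas * config.n_mirnas)
    n_special = config.n_known_regulated + config.n_imprinted + config.n_coregulated
    if n_meth and n_special > n_meth:
        raise ValueError(
            f"infeasible composition: {n_special} known/imprinted/coregulated "
            f"ids exceed the {n_meth} methylated miRNAs"
        )

    order = rng.permutation(total_slots)[: config.n_mirnas]
    mirnas: list[MiRNAAnnotation] = []
    slots: dict[str, int] = {}
    for i, slot in enumerate(sorted(int(s) for s in order)):
        chrom = chroms[slot // slots_per_chrom]
        s = (slot % slots_per_chrom) * SLOT_SIZE
        mid = f"syn-miR-{i + 1:03d}"
        slots[mid] = slot
        mirnas.append(
            MiRNAAnnotation(
                mirna_id=mid,
                stemloop=GenomicInterval(
                    chrom, s + STEMLOOP_START, s + STEMLOOP_END, "+"
                ),
            )
        )

    ids = [m.mirna_id for m in mirnas]
    meth_ids = (
        [str(x) for x in rng.choice(ids, size=n_meth, replace=False)] if n_meth else []
    )
    known = meth_ids[: config.n_known_regulated] if n_meth else []
    imprinted = meth_ids[
        config.n_known_regulated : config.n_known_regulated + config.n_imprinted
    ]
    coregulated = meth_ids[
        config.n_known_regulated
        + config.n_imprinted : config.n_known_regulated
        + config.n_imprinted
        + config.n_coregulated
    ]
    regulated = meth_ids[n_special:]

    mirnas = [
        MiRNAAnnotation(
            mirna_id=m.mirna_id,
            stemloop=m.stemloop,
            known_methylation_regulated=m.mirna_id in set(known),
            imprinted_cluster=m.mirna_id in set(imprinted),
        )
        for m in mirnas
    ]

    # host transcripts: every host-driven miRNA gets one, then other
    # miRNAs in id order until n_transcripts are placed
    hosted = list(coregulated)
    for mid in ids:
        if len(hosted) >= config.n_transcripts:
            break
        if mid not in hosted:
            hosted.append(mid)
    transcripts: list[TranscriptModel] = []
    host_by_mirna: dict[str, str] = {}
    for j, mid in enumerate(sorted(hosted, key=lambda x: slots[x])):
        slot = slots[mid]
        chrom = chroms[slot // slots_per_chrom]
        s = (slot % slots_per_chrom) * SLOT_SIZE
        gene = f"SYNHOST{j + 1}"
        transcripts.append(
            TranscriptModel(
                gene_id=gene,
                interval=GenomicInterval(chrom, s + TX_START, s + TX_END, "+"),
                exons=(
                    GenomicInterval(chrom, s + TX_START, s + EXON1_END, "+"),
                    GenomicInterval(chrom, s + EXON2_START, s + TX_END, "+"),
                ),
            )
        )
        host_by_mirna[mid] = gene

    # planted methylated regions: one per methylated miRNA, overlapping
    # the stem-loop; the demethylated line keeps a retained subset
    region_by_mirna: dict[str, GenomicInterval] = {}
    for mid in meth_ids:
        slot = slots[mid]
        chrom = chroms[slot // slots_per_chrom]
        s = (slot % slots_per_chrom) * SLOT_SIZE
        region_by_mirna[mid] = GenomicInterval(chrom, s + REGION_START, s + REGION_END)

    novel = sorted(regulated) + sorted(coregulated)
    n_retained = round(config.frac_retained_in_demethylated * len(novel))
    retained = (
        [str(x) for x in rng.choice(novel, size=n_retained, replace=False)]
        if novel
        else []
    )
    lost = [mid for mid in novel if mid not in set(retained)]
    # known/imprinted loci keep their methylation in the demethylated line
    demeth_keep = set(retained) | set(known) | set(imprinted)

    per_cpg: dict[str, dict[str, float]] = {}
    amplicons: dict[str, str] = {}
    amp_rng = _rng(config, "amplicons")
    for mid in sorted(meth_ids):
        amplicons[mid] = _make_amplicon(amp_rng)
        per_cpg[mid] = {
            REFERENCE_SAMPLE: config.cpg_meth_high,
            DEMETHYLATED_SAMPLE: (
                config.cpg_meth_high if mid in demeth_keep else config.cpg_meth_low
            ),
            AZA_TREATED_SAMPLE: config.cpg_meth_low,
        }

    manifest = TruthManifest(
        methylated_regions={
            REFERENCE_SAMPLE: [region_by_mirna[m] for m in sorted(meth_ids)],
            DEMETHYLATED_SAMPLE: [
                region_by_mirna[m] for m in sorted(meth_ids) if m in demeth_keep
            ],
        },
        regulated_mirnas=sorted(regulated),
        coregulated_mirnas=sorted(coregulated),
        imprinted_or_known_ids=sorted(set(known) | set(imprinted)),
        per_cpg_methylation=per_cpg,
        retained_mirnas=sorted(retained),
        lost_mirnas=sorted(lost),
        region_by_mirna=region_by_mirna,
        host_by_mirna=host_by_mirna,
    )
    world = World(
        config=config,
        mirnas=mirnas,
        transcripts=transcripts,
        amplicons=amplicons,
        manifest=manifest,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        mio.write_bed(
            ((m.stemloop, m.mirna_id, 0) for m in mirnas),
            os.path.join(out_dir, "mirnas.bed"),
        )
        mio.write_transcripts_gff3(
            transcripts, os.path.join(out_dir, "transcripts.gff3")
        )
        mio.write_fasta(amplicons, os.path.join(out_dir, "amplicons.fasta"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            fh.write(manifest.to_json())
    return world


def _make_amplicon(rng: np.random.Generator) -> str:
    """A 200 bp amplicon: 20 CpGs at fixed offsets plus non-CpG C controls."""
    return _AMPLICON_BLOCK * AMPLICON_N_CPGS


def amplicon_cpg_positions() -> tuple[int, ...]:
    return tuple(10 * i + 5 for i in range(AMPLICON_N_CPGS))


def generate_mbd_reads(
    manifest: TruthManifest,
    config: WorldConfig,
    sample: str = REFERENCE_SAMPLE,
) -> list[GenomicInterval]:
    """MBD-enrichment read placements for one sample.

    Background reads are Poisson(``background_read_rate`` x length) per
    chromosome, uniformly placed.  Each planted region active in the
    sample receives extra reads at ``(peak_enrichment - 1) x``
    background rate so that its total in-region rate is exactly
    ``peak_enrichment``-fold over background.  Reads are fixed-length
    (36 bp) and sorted by coordinate.
    """
    if sample not in manifest.methylated_regions:
        raise ValueError(f"unknown sample {sample!r}")
    rng = _rng(config, f"reads:{sample}")
    reads: list[GenomicInterval] = []
    for chrom, size in config.chrom_sizes.items():
        n_bg = rng.poisson(config.background_read_rate * size)
        starts = rng.integers(0, size - READ_LENGTH, size=n_bg)
        reads.extend(GenomicInterval(chrom, int(s), int(s) + READ_LENGTH) for s in starts)
    extra_rate = config.background_read_rate * (config.peak_enrichment - 1.0)
    for region in manifest.methylated_regions[sample]:
        n_extra = rng.poisson(extra_rate * len(region))
        starts = rng.integers(region.start, region.end - READ_LENGTH, size=n_extra)
        reads.extend(
            GenomicInterval(region.chrom, int(s), int(s) + READ_LENGTH) for s in starts
        )
    return sorted(reads, key=lambda r: (r.chrom, r.start))


def _replicate_noise(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_expression(
    manifest: TruthManifest, config: WorldConfig, n_replicates: int = 3
) -> pd.DataFrame:
    """Triplicate expression values for the two cell lines, tidy layout.

    Columns: mirna_id, sample, cell_line, replicate, value.  Regulated
    or host-driven miRNAs whose methylation is lost in the demethylated
    line have their demethylated-line mean multiplied by
    ``expression_silencing_factor``; retained-methylation miRNAs stay
    at baseline, as does everything unmethylated.
    """
    rng = _rng(config, "expression")
    lost = set(manifest.lost_mirnas)
    all_ids = sorted(
        set(manifest.regulated_mirnas)
        | set(manifest.coregulated_mirnas)
        | set(manifest.imprinted_or_known_ids)
        | set(manifest.region_by_mirna)
        | set(manifest.host_by_mirna)
    )
    rows = []
    for mid in all_ids:
        for line, sample in (
            ("HCT116like", REFERENCE_SAMPLE),
            ("DKOlike", DEMETHYLATED_SAMPLE),
        ):
            mean = config.baseline_expression
            if sample == DEMETHYLATED_SAMPLE and mid in lost:
                mean *= config.expression_silencing_factor
            noise = _replicate_noise(rng, config.replicate_cv, n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "mirna_id": mid,
                        "sample": f"{line}_r{rep + 1}",
                        "cell_line": line,
                        "replicate": rep + 1,
                        "value": mean * noise[rep],
                    }
                )
    return pd.DataFrame(
        rows, columns=["mirna_id", "sample", "cell_line", "replicate", "value"]
    )


def generate_qpcr(
    manifest: TruthManifest,
    config: WorldConfig,
    n_replicates: int = 3,
    cell_lines: tuple[str, ...] = CELL_LINES,
) -> pd.DataFrame:
    """Ct tables for pri-miRNA and host-gene drug-response assays.

    Layout (tidy): target, reference, cell_line, condition, replicate,
    ct_target, ct_reference.  Ct values follow
    ``Ct = Ct_ref + dCt + noise`` with ``dCt`` dropping by
    ``log2(aza_fold)`` after treatment for planted responders.  Planted
    responders are the regulated and host-driven miRNAs (in every cell
    line); host genes of host-driven miRNAs respond concordantly, hosts
    of independent miRNAs do not.
    """
    rng = _rng(config, "qpcr")
    responders = set(manifest.regulated_mirnas) | set(manifest.coregulated_mirnas)
    responding_hosts = {
        manifest.host_by_mirna[m]
        for m in manifest.coregulated_mirnas
        if m in manifest.host_by_mirna
    }
    shift = float(np.log2(config.aza_fold))
    base_ref_ct, base_dct = 15.0, 10.0

    rows = []

    def emit(target: str, reference: str, responds: bool) -> None:
        for line in cell_lines:
            for condition in ("untreated", "treated"):
                dct = base_dct - (shift if (responds and condition == "treated") else 0.0)
                for rep in range(n_replicates):
                    ref_ct = base_ref_ct + rng.normal(0, config.qpcr_ct_sd)
                    rows.append(
                        {
                            "target": target,
                            "reference": reference,
                            "cell_line": line,
                            "condition": condition,
                            "replicate": rep + 1,
                            "ct_target": ref_ct + dct + rng.normal(0, config.qpcr_ct_sd),
                            "ct_reference": ref_ct,
                        }
                    )

    for mid in sorted(manifest.region_by_mirna):
        emit(f"pri-{mid}", "GAPDH", mid in responders)
    for gene in sorted(set(manifest.host_by_mirna.values())):
        emit(gene, "GAPDH", gene in responding_hosts)
    return pd.DataFrame(
        rows,
        columns=[
            "target", "reference", "cell_line", "condition", "replicate",
            "ct_target", "ct_reference",
        ],
    )


def generate_bisulfite(
    manifest: TruthManifest,
    config: WorldConfig,
    amplicons: dict[str, str],
    samples: tuple[str, ...] = (
        REFERENCE_SAMPLE,
        DEMETHYLATED_SAMPLE,
        AZA_TREATED_SAMPLE,
    ),
) -> dict[str, dict[str, list[str]]]:
    """Bisulfite clone sequences per locus and sample.

    Per clone, each CpG is methylated independently with the planted
    per-locus, per-sample probability; the clone is then passed through
    the in-silico converter at the configured conversion rate.  Returns
    ``{locus: {sample: [clone sequences]}}``.
    """
    rng = _rng(config, "bisulfite")
    positions = amplicon_cpg_positions()
    out: dict[str, dict[str, list[str]]] = {}
    for locus in sorted(amplicons):
        reference = amplicons[locus]
        out[locus] = {}
        for sample in samples:
            p = manifest.per_cpg_methylation[locus][sample]
            clones = []
            for _ in range(config.n_clones):
                states = rng.random(len(positions)) < p
                clones.append(
                    in_silico_convert(
                        reference,
                        states,
                        config.bisulfite_conversion_rate,
                        rng=rng,
                        cpg_positions=positions,
                    )
                )
            out[locus][sample] = clones
    return out


def generate_phenotype(config: WorldConfig) -> dict[str, pd.DataFrame]:
    """Phenotype assay tables with planted group effects.

    Groups: mock, negative_control and one miRNA mimic that suppresses
    proliferation and migration.  Wound widths in micrometres, BrdU and
    DAPI nucleus counts over 4 fields, transwell counts over 9 fields,
    and a two-timepoint growth table.
    """
    rng = _rng(config, "phenotype")
    groups = {"mock": 1.0, "negative_control": 1.0, "mimic": 0.5}

    wound_rows = []
    for group, effect in groups.items():
        for rep in range(6):
            w0 = 100.0 * (1 + rng.normal(0, 0.03))
            closed = 0.5 * effect * (1 + rng.normal(0, 0.05))
            wound_rows.append(
                {
                    "assay": "wound",
                    "group": group,
                    "replicate": rep + 1,
                    "width_0h_um": w0,
                    "width_16h_um": w0 * (1 - closed),
                }
            )

    brdu_rows = []
    for group, effect in groups.items():
        for rep in range(3):
            total = int(rng.integers(620, 700))
            positive = rng.binomial(total, 0.45 * effect)
            brdu_rows.append(
                {
                    "assay": "brdu",
                    "group": group,
                    "replicate": rep + 1,
                    "brdu_positive": int(positive),
                    "dapi_total": total,
                    "n_fields": 4,
                }
            )

    transwell_rows = []
    for group, effect in groups.items():
        for rep in range(3):
            for fld in range(9):
                transwell_rows.append(
                    {
                        "assay": "transwell",
                        "group": group,
                        "replicate": rep + 1,
                        "field": fld + 1,
                        "cells": int(rng.poisson(60 * effect)),
                    }
                )

    growth_rows = []
    for group, effect in groups.items():
        for t, base in ((48, 2.0e5), (96, 6.0e5)):
            for rep in range(3):
                growth_rows.append(
                    {
                        "assay": "growth",
                        "group": group,
                        "timepoint": t,
                        "replicate": rep + 1,
                        "value": base * effect * (1 + rng.normal(0, 0.05)),
                    }
                )

    return {
        "wound": pd.DataFrame(wound_rows),
        "brdu": pd.DataFrame(brdu_rows),
        "transwell": pd.DataFrame(transwell_rows),
        "growth": pd.DataFrame(growth_rows),
    }
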