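"""Proximity screen: miRNAs within 500 bp of significant methylation.

A miRNA stem-loop is a candidate when a significant methylated region
lies within ``max_dist`` bases of its annotated position in the
reference (methylated) cell line; the demethylated derivative's profile
is consulted only to record whether methylation is retained there.
Distances are gaps between half-open intervals, measured from the
stem-loop boundary, strand-ignored, with the boundary itself included
(gap <= 500 qualifies under the default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from mirmeth.intervals import GenomicInterval, gap_distance
from mirmeth.methylome import MethylomeProfile

DEFAULT_MAX_DIST = 500


@dataclass(frozen=True)
class MiRNAAnnotation:
    """A miRNA stem-loop annotation with screening flags.

    ``known_methylation_regulated`` marks miRNAs already reported as
    DNA-methylation targets; ``imprinted_cluster`` marks members of
    imprinted domains (e.g. DLK1-GTL2) silenced by parent-of-origin
    methylation.  Both are excluded later by the funnel, not here.
    """

    mirna_id: str
    stemloop: GenomicInterval
    known_methylation_regulated: bool = False
    imprinted_cluster: bool = False


@dataclass(frozen=True)
class ProximityCall:
    mirna_id: str
    methylated_in_reference: bool
    distance_reference: float
    methylated_in_demethylated: bool
    nearest_region: GenomicInterval | None = field(compare=False, default=None)


def _nearest(
    iv: GenomicInterval, profile: MethylomeProfile
) -> tuple[float, GenomicInterval | None]:
    """Minimum gap to any region; ties broken by lower region start."""
    best_d = math.inf
    best: GenomicInterval | None = None
    for region in profile.intervals():
        d = gap_distance(iv, region)
        if d < best_d or (d == best_d and best is not None and region.start < best.start):
            best_d, best = d, region
    return best_d, best


def screen_candidates(
    mirnas: list[MiRNAAnnotation],
    ref_profile: MethylomeProfile,
    demeth_profile: MethylomeProfile,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[ProximityCall]:
    """One :class:`ProximityCall` per miRNA methylated in the reference.

    Candidacy requires reference-line methylation within ``max_dist``;
    the retention flag is true when the demethylated profile also shows
    a region within ``max_dist``.  Output is sorted by ``mirna_id`` and
    is a deterministic, order-insensitive function of the inputs.

    Raises :class:`ValueError` when annotations name chromosomes absent
    from the profiles' genome (guards against genome-build mixups).
    """
    known_chroms = set(ref_profile.chroms) | set(demeth_profile.chroms)
    if known_chroms:
        bad = sorted({m.stemloop.chrom for m in mirnas} - known_chroms)
        if bad:
            raise ValueError(
                "annotation chromosomes not present in methylome profiles: "
                + ", ".join(bad)
            )
    seen: set[str] = set()
    for m in mirnas:
        if m.mirna_id in seen:
            raise ValueError(f"duplicate miRNA id {m.mirna_id!r}")
        seen.add(m.mirna_id)

    calls = []
    for m in mirnas:
        d_ref, nearest = _nearest(m.stemloop, ref_profile)
        if d_ref > max_dist:
            continue
        d_dem, _ = _nearest(m.stemloop, demeth_profile)
        calls.append(
            ProximityCall(
                mirna_id=m.mirna_id,
                methylated_in_reference=True,
                distance_reference=d_ref,
                methylated_in_demethylated=d_dem <= max_dist,
                nearest_region=nearest,
            )
        )
    return sorted(calls, key=lambda c: c.mirna_id)
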