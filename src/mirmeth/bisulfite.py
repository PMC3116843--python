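"""Bisulfite clone scoring against a reference amplicon.

Bisulfite treatment converts unmethylated cytosines to uracil (read as
T after PCR) while methylated cytosines are protected.  Sequencing
individual cloned PCR products therefore reads out the methylation
state of every CpG on a single DNA molecule: C at a CpG position means
methylated, T means unmethylated.  This module scores clone sequences
against the untreated reference amplicon, summarises per-CpG methylated
fractions across clones, renders the classic lollipop grid (filled
circle = methylated, open circle = unmethylated), and compares
summaries between conditions.

Clones are assumed to share the reference coordinate frame exactly
(equal length, no indels); scoring indel-containing clones would
require an aligner and is out of scope.  Only the bisulfite-converted
top strand is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

METHYLATED_GLYPH = "●"  # ●
UNMETHYLATED_GLYPH = "○"  # ○
AMBIGUOUS_GLYPH = "?"

DEFAULT_MIN_CLONES = 8


class CpGCall(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Amplicon:
    """Reference sequence of one bisulfite PCR amplicon."""

    locus_id: str
    sequence: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        for pos in self.cpg_positions:
            if seq[pos : pos + 2] != "CG":
                raise ValueError(
                    f"{self.locus_id}: no CpG at reference position {pos} "
                    f"(found {seq[pos:pos + 2]!r})"
                )

    @classmethod
    def from_reference(cls, locus_id: str, sequence: str) -> "Amplicon":
        """Locate every CG dinucleotide in the reference automatically."""
        seq = sequence.upper()
        positions = tuple(
            i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
        )
        return cls(locus_id=locus_id, sequence=seq, cpg_positions=positions)


@dataclass(frozen=True)
class CloneCalls:
    locus_id: str
    clone_id: str
    calls: tuple[CpGCall, ...]


@dataclass
class LocusSummary:
    locus_id: str
    n_clones: int
    per_cpg_fraction: np.ndarray
    overall_percent: float
    below_minimum: bool
    lollipop: str


def in_silico_convert(
    reference: str,
    methylation_state,
    conversion_rate: float,
    rng: np.random.Generator | None = None,
    cpg_positions: tuple[int, ...] | None = None,
) -> str:
    """Simulate bisulfite conversion of the top strand.

    Unmethylated cytosines (all non-CpG Cs, plus CpG Cs whose planted
    state is unmethylated) convert C -> T independently with probability
    ``conversion_rate``; methylated CpG cytosines are never converted.
    """
    seq = list(reference.upper())
    for ch in seq:
        if ch not in "ACGTN":
            raise ValueError(f"invalid DNA base {ch!r}")
    if cpg_positions is None:
        cpg_positions = tuple(
            i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
    state = dict(zip(cpg_positions, methylation_state))
    if len(state) != len(cpg_positions):
        raise ValueError("methylation_state length must match CpG count")
    rng = rng if rng is not None else np.random.default_rng()
    for i, ch in enumerate(seq):
        if ch != "C":
            continue
        if state.get(i, False):
            continue  # methylated CpG cytosine is protected
        if rng.random() < conversion_rate:
            seq[i] = "T"
    return "".join(seq)


def call_clone(amplicon: Amplicon, clone: str, clone_id: str = "clone") -> CloneCalls:
    """Read per-CpG methylation calls off one clone sequence.

    At each reference CpG position: C -> methylated, T -> unmethylated,
    anything else -> ambiguous.  The clone must match the reference
    length exactly (coordinate-frame anchoring).
    """
    clone = clone.upper()
    if len(clone) != len(amplicon.sequence):
        raise ValueError(
            f"{amplicon.locus_id}/{clone_id}: clone length {len(clone)} != "
            f"reference length {len(amplicon.sequence)}"
        )
    calls = []
    for pos in amplicon.cpg_positions:
        base = clone[pos]
        if base == "C":
            calls.append(CpGCall.METHYLATED)
        elif base == "T":
            calls.append(CpGCall.UNMETHYLATED)
        else:
            calls.append(CpGCall.AMBIGUOUS)
    return CloneCalls(
        locus_id=amplicon.locus_id, clone_id=clone_id, calls=tuple(calls)
    )


def _lollipop_row(calls: tuple[CpGCall, ...]) -> str:
    glyphs = {
        CpGCall.METHYLATED: METHYLATED_GLYPH,
        CpGCall.UNMETHYLATED: UNMETHYLATED_GLYPH,
        CpGCall.AMBIGUOUS: AMBIGUOUS_GLYPH,
    }
    return " ".join(glyphs[c] for c in calls)


def locus_summary(
    clones: list[CloneCalls], min_clones: int = DEFAULT_MIN_CLONES
) -> LocusSummary:
    """Per-CpG methylated fractions and the lollipop grid for one locus.

    Ambiguous calls are excluded from both numerator and denominator of
    the per-CpG fractions.  Clone counts below ``min_clones`` produce a
    warning flag in the summary, not a failure.
    """
    if not clones:
        raise ValueError("need at least one clone")
    locus_ids = {c.locus_id for c in clones}
    if len(locus_ids) > 1:
        raise ValueError(f"inconsistent locus ids: {sorted(locus_ids)}")
    n_cpgs = {len(c.calls) for c in clones}
    if len(n_cpgs) > 1:
        raise ValueError("clones disagree on CpG count")
    n = n_cpgs.pop()
    meth = np.zeros(n)
    informative = np.zeros(n)
    for clone in clones:
        for j, call in enumerate(clone.calls):
            if call == CpGCall.AMBIGUOUS:
                continue
            informative[j] += 1
            if call == CpGCall.METHYLATED:
                meth[j] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(informative > 0, meth / np.maximum(informative, 1), np.nan)
    overall = float(100.0 * np.nanmean(frac)) if n else float("nan")
    grid = "\n".join(
        f"{c.clone_id}\t{_lollipop_row(c.calls)}" for c in clones
    )
    return LocusSummary(
        locus_id=clones[0].locus_id,
        n_clones=len(clones),
        per_cpg_fraction=frac,
        overall_percent=overall,
        below_minimum=len(clones) < min_clones,
        lollipop=grid,
    )


def demethylation_compare(
    baseline: LocusSummary, treated: LocusSummary
) -> tuple[np.ndarray, float]:
    """Per-CpG and overall change in methylated fraction, treated - baseline.

    Negative values indicate demethylation (the expected direction
    after demethylating-drug treatment).
    """
    if baseline.locus_id != treated.locus_id:
        raise ValueError(
            f"locus mismatch: {baseline.locus_id!r} vs {treated.locus_id!r}"
        )
    if baseline.per_cpg_fraction.shape != treated.per_cpg_fraction.shape:
        raise ValueError("CpG count mismatch between conditions")
    delta = treated.per_cpg_fraction - baseline.per_cpg_fraction
    return delta, float(np.nanmean(delta))
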