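"""Quantification of phenotype-assay readouts.

Raw measurements (wound widths in micrometres, BrdU/DAPI nucleus
counts, transwell cell counts per field, absorbances) are consumed as
numbers; image acquisition and segmentation are upstream of this
module.  Group effects are tested with the two-sided pooled-variance
Student t test at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

BRDU_MIN_NUCLEI = 600
BRDU_MIN_FIELDS = 4
TRANSWELL_MIN_FIELDS = 9


@dataclass
class BrdUResult:
    percent_positive: float
    under_count: bool
    under_fields: bool


def wound_closure(width_0h: float, width_16h: float) -> float:
    """Fraction of the wound width closed between 0 h and 16 h.

    (width_0h - width_16h) / width_0h.  Negative when the wound
    widened; negative values are reported, not clipped.  Scale-
    invariant: multiplying both widths by c > 0 leaves it unchanged.
    """
    if width_0h <= 0:
        raise ValueError("initial wound width must be positive")
    if width_16h < 0:
        raise ValueError("wound width cannot be negative")
    return (width_0h - width_16h) / width_0h


def normalize_to_mock(group_values, mock_values) -> float:
    """Group mean expressed relative to the mock-transfected mean."""
    mock_mean = float(np.mean(mock_values))
    if mock_mean == 0:
        raise ValueError("mock group mean is zero; cannot normalize")
    return float(np.mean(group_values)) / mock_mean


def brdu_fraction(
    brdu_positive: int, dapi_total: int, n_fields: int
) -> BrdUResult:
    """Percentage of BrdU-positive nuclei among DAPI-stained nuclei.

    QC flags (not failures) are raised when fewer than 600 nuclei or
    fewer than 4 microscope fields were counted.
    """
    if dapi_total == 0:
        raise ValueError("no DAPI-stained nuclei counted")
    if brdu_positive < 0 or dapi_total < brdu_positive:
        raise ValueError("need 0 <= BrdU-positive <= DAPI total")
    return BrdUResult(
        percent_positive=100.0 * brdu_positive / dapi_total,
        under_count=dapi_total < BRDU_MIN_NUCLEI,
        under_fields=n_fields < BRDU_MIN_FIELDS,
    )


def migration_change(
    group_counts, mock_counts
) -> tuple[float, bool]:
    """Transwell migration relative to mock: mean group / mean mock counts.

    Returns the normalized ratio and a QC flag set when fewer than the
    customary nine fields were counted in either group.
    """
    group = np.asarray(group_counts, dtype=float)
    mock = np.asarray(mock_counts, dtype=float)
    if group.size < 1 or mock.size < 1:
        raise ValueError("need at least one field per group")
    ratio = normalize_to_mock(group, mock)
    under_fields = group.size < TRANSWELL_MIN_FIELDS or mock.size < TRANSWELL_MIN_FIELDS
    return ratio, under_fields


def group_compare(a, b, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided pooled-variance Student t test between two groups.

    Returns (t, p, significant at ``alpha``).  Degenerate zero-variance
    groups follow the same conventions as the expression-stage Welch
    test: identical constants give p = 1, differing constants p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), bool(p < alpha)


def growth_summary(table) -> "object":
    """Per-timepoint, per-group mean and SD for growth / MTT curves.

    ``table`` is a tidy DataFrame with columns group, timepoint, value.
    No curve fitting: raw means with SD error bars are the readout.
    """
    return (
        table.groupby(["group", "timepoint"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
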