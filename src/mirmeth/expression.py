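"""Expression-concordance filtering between cell lines.

Candidates whose proximal methylation is lost in the demethylated line
should re-express there (fold >= 1.5, FDR-significant by Welch's t
test); candidates whose methylation is retained should stay silenced.
Either pattern is "consistent" with methylation-mediated regulation;
anything else is inconsistent and drops out of the default funnel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirmeth.proximity import ProximityCall

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_Q_THRESHOLD = 0.05


class Concordance(str, Enum):
    CONSISTENT_UPREGULATED = "consistent_upregulated"
    CONSISTENT_RETAINED_SILENCED = "consistent_retained_silenced"
    INCONSISTENT = "inconsistent"
    UNTESTED = "untested"


@dataclass
class ExpressionMatrix:
    """miRNA-by-sample intensity grid with per-sample cell-line labels.

    ``values``: DataFrame indexed by miRNA id, one column per sample.
    ``sample_meta``: DataFrame indexed by sample id with a ``cell_line``
    column (and optionally ``replicate``).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    normalized_by: str | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("negative intensities are not allowed")

    def samples_for(self, cell_line: str) -> list[str]:
        hits = self.sample_meta.index[self.sample_meta["cell_line"] == cell_line]
        return [s for s in self.values.columns if s in set(hits)]


@dataclass
class DifferentialResult:
    mirna_id: str
    mean_ref: float
    mean_demeth: float
    fold_change: float
    t_stat: float
    df: float
    p_value: float
    q_value: float = float("nan")


def normalize_matrix(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-scale every sample to the grand median.

    Each sample column is multiplied by ``grand_median / sample_median``
    so that all per-sample medians agree afterwards.  Monotone within a
    sample, and a fixed point when the medians already agree.  The
    method name is recorded in ``normalized_by`` for provenance.
    """
    if raw.values.shape[1] < 1:
        raise ValueError("need at least one sample")
    medians = raw.values.median(axis=0)
    zero = medians.index[medians == 0].tolist()
    if zero:
        raise ValueError(f"cannot median-scale all-zero sample(s): {zero}")
    grand = float(np.median(raw.values.values))
    scaled = raw.values * (grand / medians)
    return ExpressionMatrix(
        values=scaled, sample_meta=raw.sample_meta, normalized_by="median_scaling"
    )


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of
    freedom and a two-sided p-value.  Degenerate zero-variance inputs
    follow the conventions: identical constant groups give ``p = 1``;
    constant groups with different means give ``p = 0`` (a formally
    infinite t statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two replicates")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), float(
            x.size + y.size - 2
        ), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / x.size, vy / y.size
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    return float(t), float(df), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    ref_line: str,
    demeth_line: str,
    mirna_ids: list[str] | None = None,
) -> dict[str, DifferentialResult]:
    """Welch test per miRNA between the two cell lines, BH-adjusted.

    Fold change is ``mean_demeth / mean_ref`` on the normalized linear
    scale.  FDR adjustment is computed over all tested miRNAs.
    """
    ref_cols = matrix.samples_for(ref_line)
    dem_cols = matrix.samples_for(demeth_line)
    if len(ref_cols) < 2 or len(dem_cols) < 2:
        raise ValueError(
            f"need >= 2 replicates per line, got {len(ref_cols)} for "
            f"{ref_line!r} and {len(dem_cols)} for {demeth_line!r}"
        )
    ids = list(mirna_ids) if mirna_ids is not None else list(matrix.values.index)
    results = {}
    for mid in ids:
        if mid not in matrix.values.index:
            continue
        x = matrix.values.loc[mid, ref_cols].to_numpy(dtype=float)
        y = matrix.values.loc[mid, dem_cols].to_numpy(dtype=float)
        t, df, p = welch_test(x, y)
        mean_ref, mean_dem = float(x.mean()), float(y.mean())
        fold = mean_dem / mean_ref if mean_ref > 0 else float("inf")
        results[mid] = DifferentialResult(
            mirna_id=mid,
            mean_ref=mean_ref,
            mean_demeth=mean_dem,
            fold_change=fold,
            t_stat=t,
            df=df,
            p_value=p,
        )
    qs = fdr_adjust([r.p_value for r in results.values()])
    for r, q in zip(results.values(), qs):
        r.q_value = float(q)
    return results


def classify_concordance(
    call: ProximityCall,
    dr: DifferentialResult | None,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    sig_threshold: float = DEFAULT_Q_THRESHOLD,
    use_fdr: bool = False,
) -> Concordance:
    """Concordance of an expression change with methylation status.

    - methylation lost in the demethylated line AND fold >= threshold
      (inclusive) with a significant Welch test -> consistent_upregulated;
    - methylation retained AND fold < threshold -> consistent_retained_silenced;
    - otherwise inconsistent.

    The 1.5-fold rule is the decisive gate; the significance gate
    defaults to the raw Welch p-value at 0.05 (``use_fdr=True`` gates
    on the BH q-value instead, which with triplicate designs and a
    mostly-null candidate matrix is markedly more conservative).  A
    candidate with no expression row is marked untested rather than
    silently dropped.
    """
    if dr is None:
        return Concordance.UNTESTED
    if call.mirna_id != dr.mirna_id:
        raise ValueError(
            f"mismatched ids: proximity {call.mirna_id!r} vs expression {dr.mirna_id!r}"
        )
    sig_value = dr.q_value if use_fdr else dr.p_value
    retained = call.methylated_in_demethylated
    if not retained and dr.fold_change >= fold_threshold and sig_value < sig_threshold:
        return Concordance.CONSISTENT_UPREGULATED
    if retained and dr.fold_change < fold_threshold:
        return Concordance.CONSISTENT_RETAINED_SILENCED
    return Concordance.INCONSISTENT
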