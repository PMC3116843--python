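"""Relative quantification of re-expression by the 2^-ddCt method.

Each target (a primary miRNA or its putative host gene) is measured by
qRT-PCR against a reference gene (U6 for mature miRNAs, GAPDH for
primary miRNAs and host genes) before and after demethylating-drug
treatment.  Per replicate, dCt = Ct_target - Ct_reference; the
between-condition difference ddCt = mean(dCt_treated) -
mean(dCt_untreated) gives fold = 2^(-ddCt), with the untreated
condition normalized to 1.  Significance of re-expression is a
two-sided Student t test on the replicate dCt values, and the call is
directional: a target counts as re-expressed only when fold > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

UNTREATED = "untreated"
TREATED = "treated"


@dataclass(frozen=True)
class QPCRMeasurement:
    """Replicate Ct values for one target/reference pair in one condition."""

    target_id: str
    reference_id: str
    cell_line: str
    condition: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.target_ct) != len(self.reference_ct):
            raise ValueError(
                f"{self.target_id}/{self.cell_line}/{self.condition}: target and "
                "reference wells must pair up"
            )
        if len(self.target_ct) == 0:
            raise ValueError(
                f"reference wells missing for target {self.target_id!r} "
                f"({self.cell_line}, {self.condition})"
            )
        for ct in (*self.target_ct, *self.reference_ct):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"{self.target_id}: Ct values must be finite and positive"
                )

    @property
    def delta_ct(self) -> np.ndarray:
        """Per-replicate dCt = Ct_target - Ct_reference."""
        return np.asarray(self.target_ct) - np.asarray(self.reference_ct)


@dataclass
class ReexpressionResult:
    target_id: str
    cell_line: str
    fold: float
    p_value: float
    significant: bool


def delta_delta_ct(
    treated: QPCRMeasurement, untreated: QPCRMeasurement
) -> tuple[float, float]:
    """Fold change 2^(-ddCt) of treated over untreated, plus ddCt.

    The untreated condition is the calibrator (fold 1 by construction).
    A one-cycle drop of the target Ct with a constant reference gives
    fold 2 exactly.  Adding a constant to every Ct of one replicate
    (a plate shift) cancels through the reference.
    """
    if (treated.target_id, treated.reference_id) != (
        untreated.target_id,
        untreated.reference_id,
    ):
        raise ValueError(
            f"target/reference mismatch: {treated.target_id}/{treated.reference_id} "
            f"vs {untreated.target_id}/{untreated.reference_id}"
        )
    ddct = float(treated.delta_ct.mean() - untreated.delta_ct.mean())
    return float(2.0 ** (-ddct)), ddct


def reexpression_test(
    treated: QPCRMeasurement,
    untreated: QPCRMeasurement,
    alpha: float = 0.05,
) -> ReexpressionResult:
    """Student t test of re-expression after demethylating treatment.

    The statistic is computed on the replicate dCt values (the
    approximately normal scale), unpaired, equal-variance, two-sided.
    The significance flag additionally requires fold > 1: re-expression
    is a directional claim, so a significant *decrease* is not flagged.
    """
    dct_t = treated.delta_ct
    dct_u = untreated.delta_ct
    if dct_t.size < 3 or dct_u.size < 3:
        raise ValueError(
            f"{treated.target_id}: need >= 3 replicates per condition"
        )
    fold, _ = delta_delta_ct(treated, untreated)
    vt, vu = dct_t.var(ddof=1), dct_u.var(ddof=1)
    if vt == 0 and vu == 0:
        p = 1.0 if dct_t.mean() == dct_u.mean() else 0.0
    else:
        _, p = stats.ttest_ind(dct_t, dct_u, equal_var=True)
        p = float(p)
    return ReexpressionResult(
        target_id=treated.target_id,
        cell_line=treated.cell_line,
        fold=fold,
        p_value=p,
        significant=bool(p < alpha and fold > 1.0),
    )


def confirm_across_lines(
    results: list[ReexpressionResult],
    primary_line: str,
    validation_lines: list[str],
) -> tuple[set[str], dict[str, set[str]]]:
    """Cross-cell-line confirmation of re-expression.

    A target is confirmed when it is significant in the primary line
    and in every validation line for which it was tested.  Targets
    significant in the primary line but not everywhere are returned as
    partial confirmations (target -> set of significant lines), never
    silently dropped.
    """
    by_target: dict[str, dict[str, ReexpressionResult]] = {}
    for r in results:
        by_target.setdefault(r.target_id, {})[r.cell_line] = r
    confirmed: set[str] = set()
    partial: dict[str, set[str]] = {}
    for target, lines in by_target.items():
        prim = lines.get(primary_line)
        if prim is None or not prim.significant:
            continue
        tested = [ln for ln in validation_lines if ln in lines]
        if all(lines[ln].significant for ln in tested):
            confirmed.add(target)
        else:
            partial[target] = {
                ln for ln, r in lines.items() if r.significant
            }
    return confirmed, partial
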