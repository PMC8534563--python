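"""Rubric-revision experiments: score a cohort under two criteria variants
and report per-case reclassification.

Raising a deficiency cutoff (e.g. CD7 from <10% to <22.5%) can only add
immunopathologic points, so for nested criteria the per-case totals are
monotone and cases can only move toward the early-MF classification.

Sensitivity/specificity under the second rubric are reported twice: against
the fixed reference labels, and against revised reference labels in which
the cases that moved from non-MF to early MF are treated as re-diagnosed
(their reference label updated).  The two readings differ whenever the
revision is interpreted as correcting the reference standard itself rather
than merely changing the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort_model import CaseRecord, CriteriaConfig, Label, Marker, ValidationError
from .iscl_scoring import score_case

__all__ = ["ReclassificationReport", "compare_criteria", "cutoff_capture_fraction"]


def _sens_spec(pred_mf: pd.Series, ref: pd.Series) -> dict[str, Optional[float]]:
    ref_mf = ref == Label.EARLY_MF.value
    ref_non = ref == Label.NON_MF.value
    tp = int((pred_mf & ref_mf).sum())
    fn = int((~pred_mf & ref_mf).sum())
    fp = int((pred_mf & ref_non).sum())
    tn = int((~pred_mf & ref_non).sum())
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
    }


@dataclass
class ReclassificationReport:
    config_a: str
    config_b: str
    table: pd.DataFrame
    n_moved: int
    moved_to_early_mf: int
    moved_to_non_mf: int
    metrics_a: dict
    metrics_b_fixed_reference: dict
    metrics_b_revised_reference: dict

    def to_report(self) -> dict:
        return {
            "config_a": self.config_a,
            "config_b": self.config_b,
            "n_moved": self.n_moved,
            "moved_to_early_mf": self.moved_to_early_mf,
            "moved_to_non_mf": self.moved_to_non_mf,
            "metrics_a": self.metrics_a,
            "metrics_b_fixed_reference": self.metrics_b_fixed_reference,
            "metrics_b_revised_reference": self.metrics_b_revised_reference,
            "cases": self.table,
        }


def compare_criteria(
    cases: Sequence[CaseRecord],
    config_a: CriteriaConfig,
    config_b: CriteriaConfig,
) -> ReclassificationReport:
    """Score every case under both rubrics and tabulate the moves."""
    if len(cases) == 0:
        raise ValidationError("cohort is empty")
    rows = []
    for case in cases:
        sa = score_case(case, config_a)
        sb = score_case(case, config_b)
        rows.append(
            {
                "case_id": case.case_id,
                "reference_label": case.reference_label.value,
                "total_a": sa.total,
                "classification_a": sa.classification.value,
                "total_b": sb.total,
                "classification_b": sb.classification.value,
                "moved": sa.classification is not sb.classification,
            }
        )
    table = pd.DataFrame(rows, columns=list(rows[0]))
    pred_a = table["classification_a"] == Label.EARLY_MF.value
    pred_b = table["classification_b"] == Label.EARLY_MF.value
    to_mf = ~pred_a & pred_b
    to_non = pred_a & ~pred_b

    ref = table["reference_label"]
    revised_ref = ref.where(~(to_mf & (ref == Label.NON_MF.value)), Label.EARLY_MF.value)

    return ReclassificationReport(
        config_a=config_a.name,
        config_b=config_b.name,
        table=table,
        n_moved=int(table["moved"].sum()),
        moved_to_early_mf=int(to_mf.sum()),
        moved_to_non_mf=int(to_non.sum()),
        metrics_a=_sens_spec(pred_a, ref),
        metrics_b_fixed_reference=_sens_spec(pred_b, ref),
        metrics_b_revised_reference=_sens_spec(pred_b, revised_ref),
    )


def cutoff_capture_fraction(
    cases: Sequence[CaseRecord],
    marker: Union[Marker, str],
    cutoff: float,
    group_label: Union[Label, str],
) -> float:
    """Fraction of cases in ``group_label`` whose epidermal expression of
    ``marker`` lies strictly below ``cutoff``."""
    marker = Marker(marker)
    group_label = Label(group_label)
    selected = [c for c in cases if c.reference_label is group_label]
    if not selected:
        raise ValidationError(f"no cases with reference label {group_label.value!r}")
    values = []
    for case in selected:
        v = case.panel[marker].epidermal_pct
        if v is None:
            raise ValidationError(
                f"case {case.case_id}: {marker.value} epidermal expression missing"
            )
        values.append(v)
    return sum(v < cutoff for v in values) / len(values)
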