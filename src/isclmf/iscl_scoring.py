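"""The ISCL diagnostic scoring algorithm for early mycosis fungoides.

The rubric awards up to 2 clinical points, 2 histopathologic points, 1
molecular/biologic point (TCR clonality) and 1 immunopathologic point
(pan-T-cell marker deficiency or epidermal discordance); a total of at least
4 points classifies a case as early MF.  For both the clinical and the
histopathologic domain the basic criterion gates the domain: with the basic
criterion present, one additional criterion earns 1 point and two or more
earn 2; without it the domain scores 0.  The ancillary (molecular and
immunopathologic) points are withheld entirely when neither clinical nor
histopathologic points were earned.

Two rubric presets are bundled:

``iscl-original``
    50% deficiency cutoff for CD2/CD3/CD5, 10% for CD7, all four markers and
    all three TCR loci count.
``revised``
    CD5/CD7 only with cutoffs 92.5% and 22.5%, TCR-gamma and -beta only.
    These cutoffs maximize Youden's index on the validation cohort; the
    92.5% CD5 cutoff is high enough that deficiency may be hard to tell from
    a reactive pattern, which is why it is a preset, not a hard-coded truth.

Deficiency uses a strict ``<`` (a value exactly at the cutoff is not
deficient); the discordance delta uses ``>=`` (a 30-point difference
qualifies).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort_model import (
    CaseRecord,
    ClinicalFindings,
    ClonalityResult,
    Clonality,
    CriteriaConfig,
    HistoFindings,
    IHCPanel,
    ISCLScore,
    Label,
    Marker,
    MarkerMeasurement,
    ValidationError,
)

__all__ = [
    "DiscordanceReason",
    "DiscordanceCall",
    "PointResult",
    "clinical_points",
    "histo_points",
    "is_deficient",
    "is_discordant",
    "immuno_point",
    "molecular_point",
    "score_case",
    "score_cohort",
    "CohortScores",
    "PRESETS",
    "get_preset",
]


class DiscordanceReason(str, Enum):
    DELTA = "delta_rule"
    COMPLETE_LOSS = "complete_loss_rule"
    NONE = "none"


@dataclass(frozen=True)
class DiscordanceCall:
    """Outcome of the epidermal-discordance evaluation for one marker."""

    marker: Marker
    discordant: bool
    reason: DiscordanceReason

    def __post_init__(self) -> None:
        if (self.reason is DiscordanceReason.NONE) != (not self.discordant):
            raise ValidationError("reason must be 'none' exactly when not discordant")


@dataclass(frozen=True)
class PointResult:
    """An ancillary point with an evaluability flag and warnings."""

    points: int
    evaluable: bool = True
    warnings: tuple[str, ...] = ()


def clinical_points(findings: ClinicalFindings) -> int:
    """Clinical domain points (0-2)."""
    if not findings.persistent_progressive_patches:
        return 0
    return min(sum(findings.additional), 2)


def histo_points(findings: HistoFindings) -> int:
    """Histopathologic domain points (0-2)."""
    if not findings.superficial_lymphoid_infiltrate:
        return 0
    return min(sum(findings.additional), 2)


def is_deficient(measurement: MarkerMeasurement, config: CriteriaConfig) -> Optional[bool]:
    """Whether epidermal expression is deficient under ``config``.

    Returns ``None`` ("not evaluable") when the epidermal percentage is
    missing.  A marker outside ``config.immuno_markers`` is never deficient.
    """
    if measurement.epidermal_pct is None:
        return None
    if measurement.marker not in config.immuno_markers:
        return False
    return measurement.epidermal_pct < config.deficiency_cutoff(measurement.marker)


def is_discordant(measurement: MarkerMeasurement, config: CriteriaConfig) -> Optional[DiscordanceCall]:
    """Epidermal/dermal discordance call for one marker.

    Discordant with reason ``delta_rule`` when the compartments differ by at
    least ``config.discordance_delta_pct`` percentage points; otherwise, among
    low-expressing markers (both compartments below
    ``config.discordance_low_expression_pct``), complete loss of expression in
    exactly one compartment also counts (``complete_loss_rule``).  Both
    compartments at 0 is concordant absence, not discordance.  Returns
    ``None`` when either compartment is missing.
    """
    e, d = measurement.epidermal_pct, measurement.dermal_pct
    if e is None or d is None:
        return None
    if abs(e - d) >= config.discordance_delta_pct:
        return DiscordanceCall(measurement.marker, True, DiscordanceReason.DELTA)
    low = config.discordance_low_expression_pct
    if e < low and d < low and (e == 0.0) != (d == 0.0):
        return DiscordanceCall(measurement.marker, True, DiscordanceReason.COMPLETE_LOSS)
    return DiscordanceCall(measurement.marker, False, DiscordanceReason.NONE)


def immuno_point(panel: IHCPanel, config: CriteriaConfig) -> PointResult:
    """Immunopathologic point: 1 iff any configured marker is deficient or
    discordant.  When no configured marker is evaluable the point is 0 with a
    warning flag."""
    any_evaluable = False
    hit = False
    for marker in sorted(config.immuno_markers, key=lambda m: m.value):
        meas = panel[marker]
        deficient = is_deficient(meas, config)
        discordance = is_discordant(meas, config)
        if deficient is not None or discordance is not None:
            any_evaluable = True
        if deficient:
            hit = True
        if discordance is not None and discordance.discordant:
            hit = True
    if not any_evaluable:
        return PointResult(0, evaluable=False, warnings=("immunopathologic criteria not evaluable: no configured marker has measurements",))
    return PointResult(1 if hit else 0)


def molecular_point(clonality: ClonalityResult, config: CriteriaConfig) -> PointResult:
    """Molecular/biologic point: 1 iff any configured TCR locus is clonal.

    Untested loci contribute nothing; when every configured locus is untested
    the point is 0 with a warning flag.
    """
    statuses = [clonality.status(locus) for locus in sorted(config.molecular_loci)]
    if all(s is Clonality.NOT_TESTED for s in statuses):
        return PointResult(0, evaluable=False, warnings=("molecular criterion not evaluable: no configured TCR locus tested",))
    return PointResult(1 if any(s is Clonality.CLONAL for s in statuses) else 0)


def score_case(case: CaseRecord, config: CriteriaConfig) -> ISCLScore:
    """Score one case under a criteria configuration."""
    cp = clinical_points(case.clinical)
    hp = histo_points(case.histo)
    mol = molecular_point(case.clonality, config)
    imm = immuno_point(case.panel, config)
    warnings = mol.warnings + imm.warnings
    mp, ip = mol.points, imm.points
    if cp + hp == 0 and (mp or ip):
        mp = ip = 0
        warnings += ("ancillary points withheld: no clinical or histopathologic criteria fulfilled",)
    total = cp + hp + mp + ip
    classification = Label.EARLY_MF if total >= config.classification_threshold else Label.NON_MF
    return ISCLScore(
        clinical_pts=cp,
        histo_pts=hp,
        molecular_pts=mp,
        immuno_pts=ip,
        total=total,
        classification=classification,
        warnings=warnings,
    )


@dataclass
class CohortScores:
    """Per-case score table plus the confusion summary against reference labels."""

    config_name: str
    table: pd.DataFrame
    n_early_mf: int
    n_non_mf: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]

    def to_report(self) -> dict:
        return {
            "config": self.config_name,
            "n_cases": int(len(self.table)),
            "n_classified_early_mf": self.n_early_mf,
            "n_classified_non_mf": self.n_non_mf,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cases": self.table,
        }


def score_cohort(cases: Sequence[CaseRecord], config: CriteriaConfig) -> CohortScores:
    """Score every case and tabulate classifications against reference labels.

    Sensitivity/specificity are ``None`` when the corresponding reference
    group is empty (no division-by-zero on degenerate cohorts).
    """
    if len(cases) == 0:
        raise ValidationError("cohort is empty")
    rows = []
    for case in cases:
        s = score_case(case, config)
        rows.append(
            {
                "case_id": case.case_id,
                "reference_label": case.reference_label.value,
                "clinical_pts": s.clinical_pts,
                "histo_pts": s.histo_pts,
                "molecular_pts": s.molecular_pts,
                "immuno_pts": s.immuno_pts,
                "total": s.total,
                "classification": s.classification.value,
            }
        )
    table = pd.DataFrame(rows, columns=list(rows[0]))
    pred_mf = table["classification"] == Label.EARLY_MF.value
    ref_mf = table["reference_label"] == Label.EARLY_MF.value
    ref_non = table["reference_label"] == Label.NON_MF.value
    tp = int((pred_mf & ref_mf).sum())
    fn = int((~pred_mf & ref_mf).sum())
    fp = int((pred_mf & ref_non).sum())
    tn = int((~pred_mf & ref_non).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    return CohortScores(
        config_name=config.name,
        table=table,
        n_early_mf=int(pred_mf.sum()),
        n_non_mf=int((~pred_mf).sum()),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sensitivity,
        specificity=specificity,
    )


#: Bundled rubric presets.
PRESETS: dict[str, CriteriaConfig] = {
    "iscl-original": CriteriaConfig(
        name="iscl-original",
        pan_t_deficiency_cutoff_pct=50.0,
        cd7_deficiency_cutoff_pct=10.0,
        discordance_delta_pct=30.0,
        discordance_low_expression_pct=30.0,
        immuno_markers=frozenset(Marker),
        molecular_loci=frozenset(("gamma", "delta", "beta")),
        classification_threshold=4,
    ),
    "revised": CriteriaConfig(
        name="revised",
        pan_t_deficiency_cutoff_pct=92.5,
        cd7_deficiency_cutoff_pct=22.5,
        discordance_delta_pct=30.0,
        discordance_low_expression_pct=30.0,
        immuno_markers=frozenset((Marker.CD5, Marker.CD7)),
        molecular_loci=frozenset(("gamma", "beta")),
        classification_threshold=4,
    ),
}


def get_preset(name: str) -> CriteriaConfig:
    """Return a bundled :class:`CriteriaConfig` preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
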