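"""Scoring-engine rules, discordance/deficiency evaluation, and rubric
equivalence against a brute-force enumeration oracle."""

from __future__ import annotations

import itertools

import pytest

from isclmf import (
    ClinicalFindings,
    ClonalityResult,
    CriteriaConfig,
    DiscordanceReason,
    HistoFindings,
    IHCPanel,
    Label,
    Marker,
    MarkerMeasurement,
    ValidationError,
    clinical_points,
    get_preset,
    histo_points,
    immuno_point,
    is_deficient,
    is_discordant,
    molecular_point,
    score_case,
    score_cohort,
)
from conftest import make_case
from oracles import brute_force_total


# ---------------------------------------------------------------------------
# Domain points
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "basic,extras,expected",
    [
        (True, (True, False, True), 2),
        (True, (False, True, False), 1),
        (True, (True, True, True), 2),
        (True, (False, False, False), 0),
        (False, (True, True, True), 0),
    ],
)
def test_clinical_points_rubric(basic, extras, expected):
    findings = ClinicalFindings(basic, *extras)
    assert clinical_points(findings) == expected


@pytest.mark.parametrize(
    "basic,extras,expected",
    [(True, (True, True), 2), (True, (False, True), 1), (True, (False, False), 0), (False, (True, True), 0)],
)
def test_histo_points_rubric(basic, extras, expected):
    assert histo_points(HistoFindings(basic, *extras)) == expected


# ---------------------------------------------------------------------------
# Deficiency and discordance
# ---------------------------------------------------------------------------


def test_cd7_deficiency_under_original_and_revised(original, revised):
    nine = MarkerMeasurement(Marker.CD7, 9, 50)
    seventeen = MarkerMeasurement(Marker.CD7, 17, 40)
    assert is_deficient(nine, original) is True
    assert is_deficient(seventeen, original) is False
    assert is_deficient(seventeen, revised) is True


def test_deficiency_cutoff_is_strict(original):
    assert is_deficient(MarkerMeasurement(Marker.CD5, 50.0, 60), original) is False
    assert is_deficient(MarkerMeasurement(Marker.CD5, 49.999, 60), original) is True


def test_deficiency_missing_value_not_evaluable(original):
    assert is_deficient(MarkerMeasurement(Marker.CD7, None, 50), original) is None


def test_unconfigured_marker_is_never_deficient(revised):
    # CD2 at 40% would be deficient under the original 50% rule, but the
    # revised rubric only evaluates CD5 and CD7.
    assert is_deficient(MarkerMeasurement(Marker.CD2, 40, 60), revised) is False


@pytest.mark.parametrize(
    "epi,derm,discordant,reason",
    [
        (80, 40, True, DiscordanceReason.DELTA),
        (40, 80, True, DiscordanceReason.DELTA),
        (50, 30, False, DiscordanceReason.NONE),
        (0, 20, True, DiscordanceReason.COMPLETE_LOSS),
        (20, 0, True, DiscordanceReason.COMPLETE_LOSS),
        (0, 0, False, DiscordanceReason.NONE),
        (0, 35, True, DiscordanceReason.DELTA),
        (50, 20.0, True, DiscordanceReason.DELTA),  # delta of exactly 30 qualifies
        (5, 25, False, DiscordanceReason.NONE),
    ],
)
def test_discordance_rules(original, epi, derm, discordant, reason):
    call = is_discordant(MarkerMeasurement(Marker.CD7, epi, derm), original)
    assert call.discordant is discordant
    assert call.reason is reason


def test_discordance_missing_compartment_not_evaluable(original):
    assert is_discordant(MarkerMeasurement(Marker.CD7, 50, None), original) is None


# ---------------------------------------------------------------------------
# Ancillary points
# ---------------------------------------------------------------------------


def test_single_deficient_marker_earns_immuno_point(original):
    panel = IHCPanel.of(cd2=(90, 90), cd3=(90, 90), cd5=(95, 95), cd7=(5, 50))
    assert immuno_point(panel, original).points == 1


def test_normal_concordant_panel_earns_nothing(original):
    panel = IHCPanel.of(cd2=(90, 90), cd3=(90, 90), cd5=(95, 95), cd7=(60, 60))
    assert immuno_point(panel, original).points == 0


def test_revised_config_ignores_cd2_deficiency(original, revised):
    panel = IHCPanel.of(cd2=(40, 50), cd3=(90, 90), cd5=(95, 95), cd7=(60, 60))
    assert immuno_point(panel, original).points == 1
    assert immuno_point(panel, revised).points == 0


def test_immuno_not_evaluable_when_no_configured_marker_measured(revised):
    panel = IHCPanel.of(cd2=(90, 90), cd3=(90, 90), cd5=(None, None), cd7=(None, None))
    result = immuno_point(panel, revised)
    assert result.points == 0 and not result.evaluable and result.warnings


@pytest.mark.parametrize(
    "clonality,loci,expected",
    [
        (("C", "P", "P"), ("gamma", "delta", "beta"), 1),
        (("P", "C", "P"), ("gamma", "beta"), 0),  # delta-only clonality, revised loci
        (("P", "P", "P"), ("gamma", "delta", "beta"), 0),
        (("NT", "NT", "C"), ("gamma", "beta"), 1),
    ],
)
def test_molecular_point(clonality, loci, expected):
    config = CriteriaConfig(name="t", molecular_loci=frozenset(loci))
    assert molecular_point(ClonalityResult(*clonality), config).points == expected


def test_molecular_not_evaluable_when_all_loci_untested(original):
    result = molecular_point(ClonalityResult("NT", "NT", "NT"), original)
    assert result.points == 0 and not result.evaluable and result.warnings


# ---------------------------------------------------------------------------
# Whole-case scoring
# ---------------------------------------------------------------------------


def test_score_case_sums_and_classifies(original):
    case = make_case(
        clinical=ClinicalFindings(True, True, True, False),
        histo=HistoFindings(True, True, False),
        panel=IHCPanel.of(cd2=(90, 90), cd3=(90, 90), cd5=(95, 95), cd7=(5, 50)),
        clonality=ClonalityResult("C", "P", "P"),
    )
    s = score_case(case, original)
    assert (s.clinical_pts, s.histo_pts, s.molecular_pts, s.immuno_pts) == (2, 1, 1, 1)
    assert s.total == 5 and s.classification is Label.EARLY_MF

    s3 = score_case(
        make_case(clonality=ClonalityResult("P", "P", "P")), original
    )
    assert s3.total == 3 and s3.classification is Label.NON_MF


def test_ancillary_points_gated_without_major_criteria(original):
    case = make_case(
        clinical=ClinicalFindings(False, True, True, True),
        histo=HistoFindings(False, True, True),
        panel=IHCPanel.of(cd2=(90, 90), cd3=(90, 90), cd5=(95, 95), cd7=(0, 80)),
        clonality=ClonalityResult("C", "C", "C"),
    )
    s = score_case(case, original)
    assert s.total == 0
    assert s.molecular_pts == 0 and s.immuno_pts == 0
    assert any("withheld" in w for w in s.warnings)


_CD7_STATES = {
    "deficient": (5, 20),
    "discordant": (60, 95),
    "both": (2, 40),
    "normal": (80, 85),
    "missing": (None, None),
}
_CD5_STATES = {"deficient": (40, 60), "complete_loss": (0, 20), "normal": (95, 90)}


def test_scoring_matches_brute_force_over_discrete_lattice(original, revised):
    """Exhaustive equivalence with an independently-coded rubric evaluator
    over all boolean findings x marker states x clonality states."""
    clin_space = list(itertools.product([False, True], repeat=4))
    histo_space = list(itertools.product([False, True], repeat=3))
    for config in (original, revised):
        for clin, histo, cd7, cd5, gamma, beta in itertools.product(
            clin_space,
            histo_space,
            _CD7_STATES.values(),
            _CD5_STATES.values(),
            ["C", "P", "NT"],
            ["C", "P"],
        ):
            case = make_case(
                clinical=ClinicalFindings(*clin),
                histo=HistoFindings(*histo),
                panel=IHCPanel.of(cd2=(90, 88), cd3=(92, 90), cd5=cd5, cd7=cd7),
                clonality=ClonalityResult(gamma, "P", beta),
            )
            score = score_case(case, config)
            total, label = brute_force_total(case, config)
            assert score.total == total, (clin, histo, cd7, cd5, gamma, beta, config.name)
            assert score.classification.value == label


def test_adding_a_satisfied_criterion_never_decreases_total(original, study_cohort):
    """Monotonicity: flipping any absent finding to present, or any
    polyclonal locus to clonal, never lowers the total."""
    import dataclasses

    for case in study_cohort[::5]:
        base = score_case(case, original).total
        for f in dataclasses.fields(case.clinical):
            if not getattr(case.clinical, f.name):
                bumped = dataclasses.replace(
                    case, clinical=dataclasses.replace(case.clinical, **{f.name: True})
                )
                assert score_case(bumped, original).total >= base
        for f in dataclasses.fields(case.histo):
            if not getattr(case.histo, f.name):
                bumped = dataclasses.replace(
                    case, histo=dataclasses.replace(case.histo, **{f.name: True})
                )
                assert score_case(bumped, original).total >= base
        for locus in ("gamma", "delta", "beta"):
            bumped = dataclasses.replace(
                case, clonality=dataclasses.replace(case.clonality, **{locus: "C"})
            )
            assert score_case(bumped, original).total >= base


def test_raising_cd7_cutoff_is_monotone_in_immuno_points(study_cohort, original):
    counts = []
    for cutoff in (5.0, 10.0, 22.5, 40.0, 80.0):
        config = CriteriaConfig(
            name=f"cd7-{cutoff}",
            cd7_deficiency_cutoff_pct=cutoff,
        )
        scores = score_cohort(study_cohort, config)
        counts.append(int(scores.table["immuno_pts"].sum()))
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# Cohort scoring
# ---------------------------------------------------------------------------


def test_cohort_sensitivity_one_when_all_score_high(original):
    cases = [
        make_case(
            case_id=f"c{i}",
            clonality=ClonalityResult("C", "P", "P"),
            label=Label.EARLY_MF,
        )
        for i in range(4)
    ]
    scores = score_cohort(cases, original)
    assert scores.sensitivity == 1.0
    assert scores.specificity is None  # no non-MF reference cases: no division


def test_unlabeled_cohort_has_no_confusion_metrics(original):
    scores = score_cohort([make_case()], original)
    assert scores.sensitivity is None and scores.specificity is None


def test_empty_cohort_rejected(original):
    with pytest.raises(ValidationError):
        score_cohort([], original)


def test_study_preset_cohort_reproduces_group_split(study_cohort, original):
    scores = score_cohort(study_cohort, original)
    assert (scores.n_early_mf, scores.n_non_mf) == (38, 22)
    assert scores.sensitivity == 1.0 and scores.specificity == 1.0
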