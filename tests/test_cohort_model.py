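"""Domain-type validation and case-table / report round-trips."""

from __future__ import annotations

import json

import pytest
from hypothesis import given, settings, strategies as st

from isclmf import (
    CaseRecord,
    ClinicalFindings,
    Clonality,
    ClonalityResult,
    CriteriaConfig,
    HistoFindings,
    IHCPanel,
    ISCLScore,
    Label,
    Marker,
    MarkerMeasurement,
    Sex,
    ValidationError,
    load_criteria_config,
    read_cases,
    save_criteria_config,
    write_cases,
    write_report,
)
from conftest import make_case


# ---------------------------------------------------------------------------
# Type invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("epi,derm", [(-1, 50), (120, 50), (50, 101), (float("nan"), 0)])
def test_measurement_rejects_out_of_range_percentages(epi, derm):
    with pytest.raises(ValidationError):
        MarkerMeasurement(Marker.CD7, epi, derm)


def test_measurement_missing_is_not_zero():
    m = MarkerMeasurement(Marker.CD7, None, 0.0)
    assert m.epidermal_pct is None
    assert m.dermal_pct == 0.0


def test_panel_requires_all_four_markers_without_duplicates():
    with pytest.raises(ValidationError, match="missing"):
        IHCPanel(tuple(MarkerMeasurement(m, 50, 50) for m in [Marker.CD2, Marker.CD3]))
    with pytest.raises(ValidationError, match="duplicate"):
        IHCPanel(tuple(MarkerMeasurement(Marker.CD2, 50, 50) for _ in range(4)))


def test_criteria_config_invariants():
    with pytest.raises(ValidationError):
        CriteriaConfig(name="bad", classification_threshold=0)
    with pytest.raises(ValidationError):
        CriteriaConfig(name="bad", immuno_markers=frozenset())
    with pytest.raises(ValidationError):
        CriteriaConfig(name="bad", molecular_loci=frozenset({"epsilon"}))
    with pytest.raises(ValidationError):
        CriteriaConfig(name="bad", cd7_deficiency_cutoff_pct=130)


def test_score_total_invariant_enforced():
    with pytest.raises(ValidationError):
        ISCLScore(2, 2, 1, 1, total=5, classification=Label.EARLY_MF)


# ---------------------------------------------------------------------------
# Case-table round-trip
# ---------------------------------------------------------------------------

_pct = st.one_of(st.none(), st.floats(min_value=0, max_value=100, allow_nan=False))
_clon = st.sampled_from(list(Clonality))


@st.composite
def _case(draw, index: int = 0):
    panel = IHCPanel(
        tuple(MarkerMeasurement(m, draw(_pct), draw(_pct)) for m in Marker)
    )
    return CaseRecord(
        case_id=f"case-{index}-{draw(st.integers(0, 999))}",
        clinical=ClinicalFindings(*(draw(st.booleans()) for _ in range(4))),
        histo=HistoFindings(*(draw(st.booleans()) for _ in range(3))),
        panel=panel,
        clonality=ClonalityResult(draw(_clon), draw(_clon), draw(_clon)),
        reference_label=draw(st.sampled_from(list(Label))),
        age_years=draw(st.one_of(st.none(), st.floats(0, 100, allow_nan=False))),
        sex=draw(st.one_of(st.none(), st.sampled_from(list(Sex)))),
    )


@st.composite
def _cohort(draw):
    n = draw(st.integers(1, 6))
    return [draw(_case(i)) for i in range(n)]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(cohort=_cohort())
def test_case_table_round_trip(cohort, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "cases.csv"
    write_cases(cohort, path)
    again = read_cases(path)
    assert again == cohort
    path2 = path.with_name("cases2.csv")
    write_cases(again, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_read_two_row_file(tmp_path, study_cohort):
    path = tmp_path / "two.csv"
    write_cases(study_cohort[:2], path)
    assert len(read_cases(path)) == 2


@pytest.mark.parametrize(
    "column,value,message",
    [
        ("cd7_epi", "120", "cd7_epi"),
        ("cd7_epi", "abc", "cd7_epi"),
        ("clin_basic", "2", "clin_basic"),
        ("tcr_gamma", "X", "tcr_gamma"),
    ],
)
def test_malformed_row_names_row_and_field(tmp_path, study_cohort, column, value, message):
    path = tmp_path / "bad.csv"
    write_cases(study_cohort[:1], path)
    header, row = path.read_text().splitlines()
    cells = row.split(",")
    cells[header.split(",").index(column)] = value
    path.write_text(header + "\n" + ",".join(cells) + "\n")
    with pytest.raises(ValidationError, match="row 2") as exc:
        read_cases(path)
    assert message in str(exc.value)


def test_duplicate_case_ids_rejected(tmp_path, study_cohort):
    path = tmp_path / "dup.csv"
    write_cases([study_cohort[0], study_cohort[0]], path)
    with pytest.raises(ValidationError, match="duplicate"):
        read_cases(path)


def test_header_mismatch_rejected(tmp_path):
    path = tmp_path / "hdr.csv"
    path.write_text("a,b,c\n1,2,3\n")
    with pytest.raises(ValidationError, match="header"):
        read_cases(path)


def test_missing_percentage_round_trips_as_missing(tmp_path):
    case = make_case(panel=IHCPanel.of(cd2=(None, None), cd3=(90, 90), cd5=(95, 95), cd7=(0, 50)))
    path = tmp_path / "miss.csv"
    write_cases([case], path)
    back = read_cases(path)[0]
    assert back.panel[Marker.CD2].epidermal_pct is None
    assert back.panel[Marker.CD7].epidermal_pct == 0.0


# ---------------------------------------------------------------------------
# Reports and criteria configs
# ---------------------------------------------------------------------------


def test_report_serialization_is_deterministic(tmp_path):
    report = {"b": 1, "a": {"nested": [1, 2, {"x": 0.5}]}, "label": Label.EARLY_MF}
    p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
    write_report(report, p1)
    write_report(report, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert json.loads(p1.read_text())["label"] == "early_MF"


def test_report_round_trips_through_json(tmp_path, study_cohort, original):
    from isclmf import score_cohort

    report = score_cohort(study_cohort, original).to_report()
    path = tmp_path / "scores.json"
    write_report(report, path)
    parsed = json.loads(path.read_text())
    assert parsed["n_classified_early_mf"] == report["n_classified_early_mf"]
    assert parsed["confusion"] == report["confusion"]
    assert len(parsed["cases"]) == len(study_cohort)


def test_empty_counts_report_is_valid(tmp_path):
    write_report({"n_cases": 0, "cases": []}, tmp_path / "empty.json")
    assert json.loads((tmp_path / "empty.json").read_text()) == {"n_cases": 0, "cases": []}


def test_markdown_report(tmp_path):
    path = tmp_path / "r.md"
    write_report({"auc": 0.84, "youden": {"cutoff": 22.5}}, path)
    text = path.read_text()
    assert "auc" in text and "22.5" in text


def test_criteria_config_yaml_round_trip(tmp_path, revised):
    path = tmp_path / "revised.yaml"
    save_criteria_config(revised, path)
    assert load_criteria_config(path) == revised
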