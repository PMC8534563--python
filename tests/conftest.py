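from __future__ import annotations

import pytest

from isclmf import (
    CaseRecord,
    ClinicalFindings,
    ClonalityResult,
    HistoFindings,
    IHCPanel,
    Label,
    default_study_config,
    generate_cohort,
    get_preset,
)


def make_case(
    case_id: str = "case-1",
    clinical: ClinicalFindings | None = None,
    histo: HistoFindings | None = None,
    panel: IHCPanel | None = None,
    clonality: ClonalityResult | None = None,
    label: Label = Label.UNKNOWN,
) -> CaseRecord:
    """A fully-specified case with innocuous defaults, overridable per test."""
    return CaseRecord(
        case_id=case_id,
        clinical=clinical
        if clinical is not None
        else ClinicalFindings(True, True, True, False),
        histo=histo if histo is not None else HistoFindings(True, True, False),
        panel=panel
        if panel is not None
        else IHCPanel.of(cd2=(90, 90), cd3=(90, 90), cd5=(95, 95), cd7=(60, 60)),
        clonality=clonality if clonality is not None else ClonalityResult("P", "P", "P"),
        reference_label=label,
    )


@pytest.fixture(scope="session")
def original():
    return get_preset("iscl-original")


@pytest.fixture(scope="session")
def revised():
    return get_preset("revised")


@pytest.fixture(scope="session")
def study_cohort():
    """One deterministic study-structured synthetic cohort (38 MF / 22 non-MF)."""
    return generate_cohort(default_study_config(seed=11))
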