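"""Domain model and file I/O for early mycosis fungoides (MF) diagnostic cohorts.

Early MF at the patch/thin-plaque stage is diagnosed with a 4-point rubric
combining clinical findings, histopathology, T-cell receptor (TCR) clonality,
and an immunohistochemistry (IHC) panel of the pan-T-cell antigens CD2, CD3,
CD5 and CD7.  This module defines the per-case record types, the configurable
rubric (:class:`CriteriaConfig`), the per-case score container
(:class:`ISCLScore`), and plain-text readers/writers for case tables
(delimited text), criteria configurations (YAML/JSON) and analysis reports
(JSON/markdown).

Percentages are stored on the 0-100 scale throughout.  Missing IHC values are
``None`` (an empty CSV field), which is deliberately distinguishable from a
measured 0%: absence of staining data is not absence of staining.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "ValidationError",
    "Marker",
    "Clonality",
    "Sex",
    "Label",
    "LOCI",
    "MarkerMeasurement",
    "IHCPanel",
    "ClonalityResult",
    "ClinicalFindings",
    "HistoFindings",
    "CaseRecord",
    "CriteriaConfig",
    "ISCLScore",
    "CASE_COLUMNS",
    "read_cases",
    "write_cases",
    "write_report",
    "load_criteria_config",
    "save_criteria_config",
]


class ValidationError(ValueError):
    """A record, table or configuration violates a domain invariant."""


class Marker(str, Enum):
    """Pan-T-cell antigens assessed by IHC."""

    CD2 = "CD2"
    CD3 = "CD3"
    CD5 = "CD5"
    CD7 = "CD7"


class Clonality(str, Enum):
    """Per-locus TCR clonality call.

    ``CLONAL`` covers both monoclonal and oligoclonal banding patterns; both
    indicate a clonal T-cell population for the molecular criterion.
    """

    CLONAL = "C"
    POLYCLONAL = "P"
    NOT_TESTED = "NT"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Label(str, Enum):
    """Reference diagnosis label for a case."""

    EARLY_MF = "early_MF"
    NON_MF = "non_MF"
    UNKNOWN = "unknown"


#: TCR loci assayed by PCR, in canonical order.
LOCI = ("gamma", "delta", "beta")


def _check_pct(value: Optional[float], what: str) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    if not math.isfinite(v) or not 0.0 <= v <= 100.0:
        raise ValidationError(f"{what}={value!r}: must be a percentage in [0, 100]")
    return v


@dataclass(frozen=True)
class MarkerMeasurement:
    """Epidermal and dermal positivity percentages for one IHC marker.

    Either compartment may be ``None`` (not assessed / not evaluable).
    """

    marker: Marker
    epidermal_pct: Optional[float] = None
    dermal_pct: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", Marker(self.marker))
        object.__setattr__(
            self, "epidermal_pct", _check_pct(self.epidermal_pct, f"{self.marker.value} epidermal_pct")
        )
        object.__setattr__(
            self, "dermal_pct", _check_pct(self.dermal_pct, f"{self.marker.value} dermal_pct")
        )


@dataclass(frozen=True)
class IHCPanel:
    """Exactly one :class:`MarkerMeasurement` per marker in {CD2, CD3, CD5, CD7}.

    A marker that was not stained must still be present, with both
    percentages ``None``.
    """

    measurements: tuple[MarkerMeasurement, ...]

    def __post_init__(self) -> None:
        ms = tuple(self.measurements)
        object.__setattr__(self, "measurements", ms)
        markers = [m.marker for m in ms]
        if len(set(markers)) != len(markers):
            raise ValidationError("duplicate marker in IHC panel")
        missing = set(Marker) - set(markers)
        if missing:
            names = ", ".join(sorted(m.value for m in missing))
            raise ValidationError(
                f"IHC panel missing marker(s) {names}; encode unstained markers "
                "as measurements with no percentages"
            )

    def __getitem__(self, marker: Marker) -> MarkerMeasurement:
        marker = Marker(marker)
        for m in self.measurements:
            if m.marker is marker:
                return m
        raise KeyError(marker)  # pragma: no cover - unreachable after validation

    @classmethod
    def of(
        cls,
        cd2: tuple[Optional[float], Optional[float]] = (None, None),
        cd3: tuple[Optional[float], Optional[float]] = (None, None),
        cd5: tuple[Optional[float], Optional[float]] = (None, None),
        cd7: tuple[Optional[float], Optional[float]] = (None, None),
    ) -> "IHCPanel":
        """Build a panel from ``(epidermal, dermal)`` pairs."""
        pairs = {Marker.CD2: cd2, Marker.CD3: cd3, Marker.CD5: cd5, Marker.CD7: cd7}
        return cls(tuple(MarkerMeasurement(m, e, d) for m, (e, d) in pairs.items()))


@dataclass(frozen=True)
class ClonalityResult:
    """Tri-state TCR clonality calls for the gamma, delta and beta loci."""

    gamma: Clonality = Clonality.NOT_TESTED
    delta: Clonality = Clonality.NOT_TESTED
    beta: Clonality = Clonality.NOT_TESTED

    def __post_init__(self) -> None:
        for locus in LOCI:
            object.__setattr__(self, locus, Clonality(getattr(self, locus)))

    def status(self, locus: str) -> Clonality:
        if locus not in LOCI:
            raise ValidationError(f"unknown TCR locus {locus!r}; expected one of {LOCI}")
        return getattr(self, locus)


@dataclass(frozen=True)
class ClinicalFindings:
    """Clinical criteria: the basic criterion plus three additional criteria.

    The basic criterion (persistent and/or progressive patches or thin
    plaques) gates the clinical points; the additional criteria are only
    counted when it is present, but remain representable regardless.
    """

    persistent_progressive_patches: bool = False
    non_sun_exposed: bool = False
    size_shape_variation: bool = False
    poikiloderma: bool = False

    def __post_init__(self) -> None:
        for f in (
            "persistent_progressive_patches",
            "non_sun_exposed",
            "size_shape_variation",
            "poikiloderma",
        ):
            object.__setattr__(self, f, bool(getattr(self, f)))

    @property
    def additional(self) -> tuple[bool, bool, bool]:
        return (self.non_sun_exposed, self.size_shape_variation, self.poikiloderma)


@dataclass(frozen=True)
class HistoFindings:
    """Histopathologic criteria: superficial lymphoid infiltrate (basic) plus
    epidermotropism without spongiosis and lymphoid atypia (additional)."""

    superficial_lymphoid_infiltrate: bool = False
    epidermotropism_without_spongiosis: bool = False
    lymphoid_atypia: bool = False

    def __post_init__(self) -> None:
        for f in (
            "superficial_lymphoid_infiltrate",
            "epidermotropism_without_spongiosis",
            "lymphoid_atypia",
        ):
            object.__setattr__(self, f, bool(getattr(self, f)))

    @property
    def additional(self) -> tuple[bool, bool]:
        return (self.epidermotropism_without_spongiosis, self.lymphoid_atypia)


@dataclass(frozen=True)
class CaseRecord:
    """One patient's findings, IHC panel, clonality calls and reference label."""

    case_id: str
    clinical: ClinicalFindings
    histo: HistoFindings
    panel: IHCPanel
    clonality: ClonalityResult
    reference_label: Label = Label.UNKNOWN
    age_years: Optional[float] = None
    sex: Optional[Sex] = None

    def __post_init__(self) -> None:
        if not str(self.case_id):
            raise ValidationError("case_id must be a non-empty string")
        object.__setattr__(self, "case_id", str(self.case_id))
        object.__setattr__(self, "reference_label", Label(self.reference_label))
        if self.sex is not None:
            object.__setattr__(self, "sex", Sex(self.sex))
        if self.age_years is not None:
            a = float(self.age_years)
            if not math.isfinite(a) or a < 0:
                raise ValidationError(f"age_years={self.age_years!r}: must be nonnegative")
            object.__setattr__(self, "age_years", a)


@dataclass(frozen=True)
class CriteriaConfig:
    """A named variant of the diagnostic rubric.

    Parameters
    ----------
    pan_t_deficiency_cutoff_pct
        Epidermal positivity below this percentage counts CD2/CD3/CD5 as
        deficient (strict ``<``).
    cd7_deficiency_cutoff_pct
        Deficiency cutoff for CD7 (strict ``<``).
    discordance_delta_pct
        An epidermal-dermal difference of at least this many percentage
        points defines epidermal discordance (``>=``).
    discordance_low_expression_pct
        When both compartments express below this level, complete loss
        (exactly one compartment at 0%) also counts as discordance.
    immuno_markers
        Markers whose deficiency/discordance can earn the immunopathologic
        point.
    molecular_loci
        TCR loci whose clonality can earn the molecular/biologic point.
    classification_threshold
        Total points at or above which a case is classified early MF.
    """

    name: str
    pan_t_deficiency_cutoff_pct: float = 50.0
    cd7_deficiency_cutoff_pct: float = 10.0
    discordance_delta_pct: float = 30.0
    discordance_low_expression_pct: float = 30.0
    immuno_markers: frozenset[Marker] = frozenset(Marker)
    molecular_loci: frozenset[str] = frozenset(LOCI)
    classification_threshold: int = 4

    def __post_init__(self) -> None:
        for f in (
            "pan_t_deficiency_cutoff_pct",
            "cd7_deficiency_cutoff_pct",
            "discordance_delta_pct",
            "discordance_low_expression_pct",
        ):
            v = _check_pct(getattr(self, f), f)
            object.__setattr__(self, f, v)
        markers = frozenset(Marker(m) for m in self.immuno_markers)
        loci = frozenset(str(l) for l in self.molecular_loci)
        if not markers:
            raise ValidationError("immuno_markers must be non-empty")
        if not loci:
            raise ValidationError("molecular_loci must be non-empty")
        unknown = loci - set(LOCI)
        if unknown:
            raise ValidationError(f"unknown TCR loci {sorted(unknown)}; expected subset of {LOCI}")
        object.__setattr__(self, "immuno_markers", markers)
        object.__setattr__(self, "molecular_loci", loci)
        thr = int(self.classification_threshold)
        if not 1 <= thr <= 6:
            raise ValidationError(f"classification_threshold={thr}: must be in [1, 6]")
        object.__setattr__(self, "classification_threshold", thr)

    def deficiency_cutoff(self, marker: Marker) -> float:
        marker = Marker(marker)
        if marker is Marker.CD7:
            return self.cd7_deficiency_cutoff_pct
        return self.pan_t_deficiency_cutoff_pct

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "pan_t_deficiency_cutoff_pct": self.pan_t_deficiency_cutoff_pct,
            "cd7_deficiency_cutoff_pct": self.cd7_deficiency_cutoff_pct,
            "discordance_delta_pct": self.discordance_delta_pct,
            "discordance_low_expression_pct": self.discordance_low_expression_pct,
            "immuno_markers": sorted(m.value for m in self.immuno_markers),
            "molecular_loci": sorted(self.molecular_loci, key=LOCI.index),
            "classification_threshold": self.classification_threshold,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CriteriaConfig":
        allowed = {
            "name",
            "pan_t_deficiency_cutoff_pct",
            "cd7_deficiency_cutoff_pct",
            "discordance_delta_pct",
            "discordance_low_expression_pct",
            "immuno_markers",
            "molecular_loci",
            "classification_threshold",
        }
        unknown = set(data) - allowed
        if unknown:
            raise ValidationError(f"unknown criteria fields: {sorted(unknown)}")
        return cls(**dict(data))


@dataclass(frozen=True)
class ISCLScore:
    """Per-domain points, total, and classification for one case."""

    clinical_pts: int
    histo_pts: int
    molecular_pts: int
    immuno_pts: int
    total: int
    classification: Label
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f, hi in (("clinical_pts", 2), ("histo_pts", 2), ("molecular_pts", 1), ("immuno_pts", 1)):
            v = int(getattr(self, f))
            if not 0 <= v <= hi:
                raise ValidationError(f"{f}={v}: must be in [0, {hi}]")
            object.__setattr__(self, f, v)
        if self.total != self.clinical_pts + self.histo_pts + self.molecular_pts + self.immuno_pts:
            raise ValidationError("total must equal the sum of per-domain points")
        object.__setattr__(self, "classification", Label(self.classification))
        if self.classification is Label.UNKNOWN:
            raise ValidationError("classification must be early_MF or non_MF")


# ---------------------------------------------------------------------------
# Case-table CSV I/O
# ---------------------------------------------------------------------------

#: Fixed column order of the case table.
CASE_COLUMNS = [
    "case_id",
    "age",
    "sex",
    "clin_basic",
    "clin_nonsun",
    "clin_sizeshape",
    "clin_poikiloderma",
    "histo_basic",
    "histo_epidermotropism",
    "histo_atypia",
    "cd2_epi",
    "cd2_derm",
    "cd3_epi",
    "cd3_derm",
    "cd5_epi",
    "cd5_derm",
    "cd7_epi",
    "cd7_derm",
    "tcr_gamma",
    "tcr_delta",
    "tcr_beta",
    "reference_label",
]


def _fmt_number(v: Optional[float]) -> str:
    if v is None:
        return ""
    v = float(v)
    if v.is_integer():
        return str(int(v))
    return repr(v)


def _fmt_bool(v: bool) -> str:
    return "1" if v else "0"


def _parse_pct_field(text: str, name: str) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    try:
        v = float(text)
    except ValueError:
        raise ValidationError(f"field {name!r}: {text!r} is not a number") from None
    return _check_pct(v, f"field {name!r}")


def _parse_bool_field(text: str, name: str) -> bool:
    text = text.strip()
    if text == "0":
        return False
    if text == "1":
        return True
    raise ValidationError(f"field {name!r}: expected 0 or 1, got {text!r}")


def _parse_clonality_field(text: str, name: str) -> Clonality:
    token = text.strip().upper()
    if token == "":
        return Clonality.NOT_TESTED
    try:
        return Clonality(token)
    except ValueError:
        raise ValidationError(
            f"field {name!r}: expected C, P or NT, got {text!r}"
        ) from None


def _row_to_case(row: Mapping[str, str]) -> CaseRecord:
    age_text = row["age"].strip()
    age = None
    if age_text:
        try:
            age = float(age_text)
        except ValueError:
            raise ValidationError(f"field 'age': {age_text!r} is not a number") from None
    sex_text = row["sex"].strip()
    sex = Sex(sex_text) if sex_text else None

    clinical = ClinicalFindings(
        persistent_progressive_patches=_parse_bool_field(row["clin_basic"], "clin_basic"),
        non_sun_exposed=_parse_bool_field(row["clin_nonsun"], "clin_nonsun"),
        size_shape_variation=_parse_bool_field(row["clin_sizeshape"], "clin_sizeshape"),
        poikiloderma=_parse_bool_field(row["clin_poikiloderma"], "clin_poikiloderma"),
    )
    histo = HistoFindings(
        superficial_lymphoid_infiltrate=_parse_bool_field(row["histo_basic"], "histo_basic"),
        epidermotropism_without_spongiosis=_parse_bool_field(
            row["histo_epidermotropism"], "histo_epidermotropism"
        ),
        lymphoid_atypia=_parse_bool_field(row["histo_atypia"], "histo_atypia"),
    )
    panel = IHCPanel.of(
        cd2=(_parse_pct_field(row["cd2_epi"], "cd2_epi"), _parse_pct_field(row["cd2_derm"], "cd2_derm")),
        cd3=(_parse_pct_field(row["cd3_epi"], "cd3_epi"), _parse_pct_field(row["cd3_derm"], "cd3_derm")),
        cd5=(_parse_pct_field(row["cd5_epi"], "cd5_epi"), _parse_pct_field(row["cd5_derm"], "cd5_derm")),
        cd7=(_parse_pct_field(row["cd7_epi"], "cd7_epi"), _parse_pct_field(row["cd7_derm"], "cd7_derm")),
    )
    clonality = ClonalityResult(
        gamma=_parse_clonality_field(row["tcr_gamma"], "tcr_gamma"),
        delta=_parse_clonality_field(row["tcr_delta"], "tcr_delta"),
        beta=_parse_clonality_field(row["tcr_beta"], "tcr_beta"),
    )
    label_text = row["reference_label"].strip()
    label = Label(label_text) if label_text else Label.UNKNOWN
    return CaseRecord(
        case_id=row["case_id"].strip(),
        clinical=clinical,
        histo=histo,
        panel=panel,
        clonality=clonality,
        reference_label=label,
        age_years=age,
        sex=sex,
    )


def _case_to_row(case: CaseRecord) -> list[str]:
    p = case.panel
    return [
        case.case_id,
        _fmt_number(case.age_years),
        case.sex.value if case.sex is not None else "",
        _fmt_bool(case.clinical.persistent_progressive_patches),
        _fmt_bool(case.clinical.non_sun_exposed),
        _fmt_bool(case.clinical.size_shape_variation),
        _fmt_bool(case.clinical.poikiloderma),
        _fmt_bool(case.histo.superficial_lymphoid_infiltrate),
        _fmt_bool(case.histo.epidermotropism_without_spongiosis),
        _fmt_bool(case.histo.lymphoid_atypia),
        _fmt_number(p[Marker.CD2].epidermal_pct),
        _fmt_number(p[Marker.CD2].dermal_pct),
        _fmt_number(p[Marker.CD3].epidermal_pct),
        _fmt_number(p[Marker.CD3].dermal_pct),
        _fmt_number(p[Marker.CD5].epidermal_pct),
        _fmt_number(p[Marker.CD5].dermal_pct),
        _fmt_number(p[Marker.CD7].epidermal_pct),
        _fmt_number(p[Marker.CD7].dermal_pct),
        case.clonality.gamma.value,
        case.clonality.delta.value,
        case.clonality.beta.value,
        case.reference_label.value,
    ]


def read_cases(path: Union[str, Path], delimiter: str = ",") -> list[CaseRecord]:
    """Read a case table into a list of :class:`CaseRecord`.

    Raises :class:`ValidationError` naming the row number and field for any
    malformed value; percentages outside [0, 100] are rejected.
    """
    import csv

    path = Path(path)
    cases: list[CaseRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header != CASE_COLUMNS:
            raise ValidationError(
                f"{path}: header does not match the case-table schema; "
                f"expected {CASE_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(CASE_COLUMNS):
                raise ValidationError(
                    f"{path} row {lineno}: expected {len(CASE_COLUMNS)} fields, got {len(row)}"
                )
            try:
                case = _row_to_case(dict(zip(CASE_COLUMNS, row)))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {lineno}: {exc}") from None
            if case.case_id in seen:
                raise ValidationError(f"{path} row {lineno}: duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)
            cases.append(case)
    return cases


def write_cases(cases: Iterable[CaseRecord], path: Union[str, Path], delimiter: str = ",") -> None:
    """Write cases to a delimited text table (deterministic formatting)."""
    import csv

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(CASE_COLUMNS)
        for case in cases:
            writer.writerow(_case_to_row(case))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    """Convert report structures (enums, numpy scalars, frames) to JSON types."""
    import numpy as np
    import pandas as pd

    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, Mapping):
        return {str(_jsonable(k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_jsonable(v) for v in obj]
        if isinstance(obj, (set, frozenset)):
            items = sorted(items, key=str)
        return items
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _markdown_lines(obj: Any, level: int) -> list[str]:
    lines: list[str] = []
    if isinstance(obj, Mapping):
        for key in sorted(obj, key=str):
            value = obj[key]
            if isinstance(value, (Mapping, list)):
                lines.append(f"{'#' * min(level, 6)} {key}")
                lines.append("")
                lines.extend(_markdown_lines(value, level + 1))
            else:
                lines.append(f"- **{key}:** {value}")
        if lines and lines[-1] != "":
            lines.append("")
    elif isinstance(obj, list):
        for item in obj:
            if isinstance(item, (Mapping, list)):
                lines.append("- " + json.dumps(_jsonable(item), sort_keys=True))
            else:
                lines.append(f"- {item}")
        lines.append("")
    else:
        lines.append(str(obj))
        lines.append("")
    return lines


def write_report(report: Mapping[str, Any], path: Union[str, Path], fmt: Optional[str] = None) -> None:
    """Serialize an analysis report deterministically.

    ``fmt`` is ``"json"`` or ``"markdown"``; when omitted it is inferred from
    the file suffix (``.json`` / ``.md``).  Identical inputs always produce
    identical bytes (keys are sorted).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"": "json", ".json": "json", ".md": "markdown", ".markdown": "markdown"}.get(suffix)
        if fmt is None:
            raise ValidationError(f"cannot infer report format from suffix {suffix!r}")
    data = _jsonable(report)
    if fmt == "json":
        text = json.dumps(data, sort_keys=True, indent=2) + "\n"
    elif fmt == "markdown":
        text = "\n".join(["# Report", ""] + _markdown_lines(data, 2)).rstrip() + "\n"
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
    path.write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# Criteria configuration I/O
# ---------------------------------------------------------------------------


def load_criteria_config(path: Union[str, Path]) -> CriteriaConfig:
    """Load a :class:`CriteriaConfig` from a YAML or JSON file."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: expected a mapping of criteria fields")
    return CriteriaConfig.from_dict(data)


def save_criteria_config(config: CriteriaConfig, path: Union[str, Path]) -> None:
    """Write a :class:`CriteriaConfig` as YAML (or JSON for ``.json`` paths)."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
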