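"""Synthetic two-group cohorts with the statistical structure of a published
early-MF validation study.

The generator emulates a case-control cohort of 38 early MF and 22 non-MF
biopsies:

* epidermal marker expression is drawn from truncated normal distributions
  on [0, 100] whose POST-truncation mean and SD are moment-matched to the
  published group summaries (SD recovered from SEM as SEM*sqrt(n));
* dermal expression is generated so that each marker's epidermal-discordance
  frequency matches its configured probability exactly in expectation
  (discordant cases have a >=30-point compartment difference injected;
  concordant cases get an offset drawn inside the concordance region);
* per-locus TCR clonality (gamma, delta, beta) is assigned via a latent
  any-locus "clonal case" indicator so that both the per-locus rates and the
  union rate are realized (independent Bernoulli draws cannot hit both);
* clinical and histopathologic point distributions are realized exactly by
  quota, and quotas are paired/assigned so that every generated case scores
  consistently with its group label under the construction rubric.  This
  mirrors how the study cohort was assembled in the first place: the groups
  were DEFINED by ISCL score >= 4 versus < 4, so a faithful simulator must
  reproduce that selection, not merely the marginals.

A feasibility subtlety: a truncated normal on [0, 100] cannot realize every
(mean, SD) pair.  As sigma grows, the family's limiting shapes are
exponentially tilted uniforms, whose SD at a given mean is the supremum of
achievable SDs.  :func:`max_truncnorm_sd` computes that envelope, the solver
rejects infeasible targets naming the bound, and
:func:`default_study_config` clamps the (three) published pairs that exceed
it to 98% of the envelope while keeping the published means (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort_model import (
    CaseRecord,
    ClinicalFindings,
    Clonality,
    ClonalityResult,
    CriteriaConfig,
    HistoFindings,
    IHCPanel,
    Label,
    LOCI,
    Marker,
    MarkerMeasurement,
    Sex,
    ValidationError,
)
from .iscl_scoring import get_preset, is_discordant, score_case

__all__ = [
    "InfeasibleMomentsError",
    "GenerationError",
    "TruncNormParams",
    "MomentTarget",
    "GroupSpec",
    "SyntheticConfig",
    "max_truncnorm_sd",
    "solve_truncnorm_params",
    "default_study_config",
    "generate_cohort",
]


class InfeasibleMomentsError(ValidationError):
    """The requested (mean, SD) pair is unattainable by a truncated normal."""


class GenerationError(RuntimeError):
    """The generator could not realize a cohort consistent with its config."""


@dataclass(frozen=True)
class TruncNormParams:
    """Location/scale of a normal truncated to [lower, upper]."""

    mu: float
    sigma: float
    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValidationError("sigma must be positive and finite")
        if not self.lower < self.upper:
            raise ValidationError("lower must be below upper")

    def distribution(self):
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)


@dataclass(frozen=True)
class MomentTarget:
    """Post-truncation mean and SD targeted on the [0, 100] support."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 100.0:
            raise ValidationError(f"mean={self.mean}: must be inside (0, 100)")
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ValidationError("sd must be positive and finite")


def _tilt_moments(t: float, width: float) -> tuple[float, float]:
    """Mean and variance of the density proportional to exp(t*x/width) on
    [0, width] — the sigma->infinity envelope of the truncated-normal family."""
    if t < 0:
        m, v = _tilt_moments(-t, width)
        return width - m, v
    if t < 1e-8:
        return width / 2.0, width**2 / 12.0
    mean = width * (1.0 / (-math.expm1(-t)) - 1.0 / t)
    sinh_term = 1.0 / (4.0 * math.sinh(t / 2.0) ** 2) if t < 700.0 else 0.0
    var = width**2 * (1.0 / t**2 - sinh_term)
    return mean, var


def max_truncnorm_sd(mean: float, lower: float = 0.0, upper: float = 100.0) -> float:
    """Supremum of the post-truncation SD attainable at ``mean``.

    The supremum is approached (never attained) as sigma -> infinity, where
    the truncated normal tends to an exponentially tilted uniform.
    """
    width = upper - lower
    m = mean - lower
    if not 0.0 < m < width:
        raise ValidationError(f"mean={mean}: must be inside ({lower}, {upper})")
    f = lambda t: _tilt_moments(t, width)[0] - m
    t = optimize.brentq(f, -1e7, 1e7, xtol=1e-12, rtol=8.9e-16)
    return math.sqrt(_tilt_moments(t, width)[1])


def _truncnorm_moments(mu: float, sigma: float, lower: float, upper: float) -> tuple[float, float]:
    d = TruncNormParams(mu, sigma, lower, upper).distribution()
    return float(d.mean()), float(d.std())


@lru_cache(maxsize=256)
def _solve_cached(mean: float, sd: float, lower: float, upper: float) -> TruncNormParams:
    def resid(x: np.ndarray) -> list[float]:
        mu, log_sigma = x
        sigma = math.exp(min(max(log_sigma, -7.0), 14.0))
        m, s = _truncnorm_moments(mu, sigma, lower, upper)
        return [m - mean, s - sd]

    starts = [(mean, sd)]
    for c in (1, 2, 4, 8, 16, 32):
        starts.append((mean - c * sd, sd * (1 + c / 2)))
        starts.append((mean + c * sd, sd * (1 + c / 2)))
    for mu0, sigma0 in starts:
        sol = optimize.root(resid, [mu0, math.log(sigma0)], method="hybr")
        r = resid(sol.x)
        if sol.success and max(abs(r[0]), abs(r[1])) < 1e-6:
            return TruncNormParams(
                float(sol.x[0]), math.exp(min(max(float(sol.x[1]), -7.0), 14.0)), lower, upper
            )
    raise InfeasibleMomentsError(
        f"no truncated-normal parameters found for mean={mean}, sd={sd} on [{lower}, {upper}]"
    )


def solve_truncnorm_params(
    target_mean: float,
    target_sd: float,
    lower: float = 0.0,
    upper: float = 100.0,
) -> TruncNormParams:
    """Find (mu, sigma) whose truncated normal on [lower, upper] has the given
    POST-truncation mean and SD (within 1e-6), by two-dimensional root finding
    on the closed-form truncated-normal moments.

    Raises :class:`InfeasibleMomentsError` naming the feasibility bound when
    the pair is unattainable.
    """
    width = upper - lower
    m = target_mean - lower
    if not 0.0 < m < width:
        raise ValidationError(f"target_mean={target_mean}: must be inside ({lower}, {upper})")
    if not target_sd > 0:
        raise ValidationError("target_sd must be positive")
    # Any distribution on [lower, upper] with this mean obeys var <= m*(width-m).
    hard = math.sqrt(m * (width - m))
    sup = max_truncnorm_sd(target_mean, lower, upper)
    if target_sd >= sup * (1 - 1e-9):
        raise InfeasibleMomentsError(
            f"target sd {target_sd:.6g} is not attainable at mean {target_mean:.6g} on "
            f"[{lower:g}, {upper:g}]: the truncated-normal supremum there is {sup:.6g} "
            f"(hard bound for any distribution: {hard:.6g})"
        )
    return _solve_cached(float(target_mean), float(target_sd), float(lower), float(upper))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Generation targets for one reference group.

    ``clonality_prob``/``clonality_union_prob`` are per-case probabilities;
    the union (any-locus) probability must be at least the largest single
    locus probability and at most their sum, or no joint assignment exists.
    ``clinical_point_counts``/``histo_point_counts`` are exact per-point
    quotas (counts of cases scoring 0/1/2) and must sum to ``n``.
    """

    n: int
    marker_moments: Mapping[Marker, MomentTarget]
    discordance_prob: Mapping[Marker, float]
    clonality_prob: Mapping[str, float]
    clonality_union_prob: float
    clinical_point_counts: tuple[int, int, int]
    histo_point_counts: tuple[int, int, int]
    sex_counts: tuple[int, int]
    age_moments: MomentTarget

    def __post_init__(self) -> None:
        if int(self.n) < 1:
            raise ValidationError("group size n must be positive")
        object.__setattr__(self, "n", int(self.n))
        mm = {Marker(k): v for k, v in self.marker_moments.items()}
        dp = {Marker(k): float(v) for k, v in self.discordance_prob.items()}
        if set(mm) != set(Marker) or set(dp) != set(Marker):
            raise ValidationError("marker_moments and discordance_prob must cover CD2, CD3, CD5, CD7")
        object.__setattr__(self, "marker_moments", mm)
        object.__setattr__(self, "discordance_prob", dp)
        cp = {str(k): float(v) for k, v in self.clonality_prob.items()}
        if set(cp) != set(LOCI):
            raise ValidationError(f"clonality_prob must cover loci {LOCI}")
        object.__setattr__(self, "clonality_prob", cp)
        for name, p in [("clonality_union_prob", float(self.clonality_union_prob))] + [
            (f"discordance_prob[{m.value}]", v) for m, v in dp.items()
        ] + [(f"clonality_prob[{l}]", v) for l, v in cp.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p}: probability must be in [0, 1]")
        union = float(self.clonality_union_prob)
        if union < max(cp.values()) - 1e-12:
            raise ValidationError("clonality_union_prob must be >= every single-locus probability")
        if union > sum(cp.values()) + 1e-12:
            raise ValidationError("clonality_union_prob cannot exceed the sum of locus probabilities")
        object.__setattr__(self, "clonality_union_prob", union)
        for name in ("clinical_point_counts", "histo_point_counts"):
            counts = tuple(int(c) for c in getattr(self, name))
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValidationError(f"{name} must be three nonnegative counts")
            if sum(counts) != self.n:
                raise ValidationError(f"{name} sums to {sum(counts)}, expected group size {self.n}")
            object.__setattr__(self, name, counts)
        sexes = tuple(int(c) for c in self.sex_counts)
        if len(sexes) != 2 or any(c < 0 for c in sexes) or sum(sexes) != self.n:
            raise ValidationError("sex_counts must be (male, female) summing to n")
        object.__setattr__(self, "sex_counts", sexes)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration: one :class:`GroupSpec` per group, the
    concordant dermal-offset limit, and the seed."""

    early_mf: GroupSpec
    non_mf: GroupSpec
    concordant_offset_limit: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < float(self.concordant_offset_limit) <= 100:
            raise ValidationError("concordant_offset_limit must be in (0, 100]")

    def group(self, label: Label) -> GroupSpec:
        if label is Label.EARLY_MF:
            return self.early_mf
        if label is Label.NON_MF:
            return self.non_mf
        raise ValidationError("group label must be early_MF or non_MF")


def _feasible_sd(mean: float, sd: float) -> float:
    """Clamp an SD target to 98% of the truncated-normal envelope at ``mean``."""
    return min(sd, 0.98 * max_truncnorm_sd(mean))


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The study preset: group sizes 38/22, published marker moments
    (SD = SEM*sqrt(n), clamped to the truncated-normal feasibility envelope
    where the published pair exceeds it), per-marker discordance counts,
    per-locus clonality rates with their any-locus union, and exact
    clinical/histopathologic point quotas."""
    s38, s22 = math.sqrt(38.0), math.sqrt(22.0)

    def moments(mean: float, sem: float, sqrt_n: float) -> MomentTarget:
        return MomentTarget(mean, _feasible_sd(mean, sem * sqrt_n))

    early = GroupSpec(
        n=38,
        marker_moments={
            Marker.CD2: moments(84.08, 3.155, s38),
            Marker.CD3: moments(91.84, 1.722, s38),
            Marker.CD5: moments(81.18, 3.438, s38),
            Marker.CD7: moments(17.45, 2.648, s38),
        },
        discordance_prob={Marker.CD2: 0.0, Marker.CD3: 0.0, Marker.CD5: 2 / 38, Marker.CD7: 15 / 38},
        clonality_prob={"gamma": 33 / 38, "delta": 6 / 38, "beta": 16 / 38},
        clonality_union_prob=36 / 38,
        clinical_point_counts=(1, 7, 30),
        histo_point_counts=(3, 15, 20),
        sex_counts=(22, 16),
        age_moments=moments(43.13, 2.858, s38),
    )
    non = GroupSpec(
        n=22,
        marker_moments={
            Marker.CD2: moments(92.27, 1.174, s22),
            Marker.CD3: moments(93.41, 0.764, s22),
            Marker.CD5: moments(92.50, 1.175, s22),
            Marker.CD7: moments(42.95, 4.763, s22),
        },
        discordance_prob={m: 0.0 for m in Marker},
        # gamma alone is 4/22, which forces the any-locus union to at least
        # 4/22 even though the union is elsewhere quoted as 3/22.
        clonality_prob={"gamma": 4 / 22, "delta": 3 / 22, "beta": 0.0},
        clonality_union_prob=4 / 22,
        clinical_point_counts=(9, 8, 5),
        histo_point_counts=(5, 12, 5),
        sex_counts=(10, 12),
        age_moments=moments(51.91, 3.896, s22),
    )
    return SyntheticConfig(early_mf=early, non_mf=non, seed=seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _quota(p: float, n: int, rng: np.random.Generator) -> int:
    """Randomized-rounding count: exact for p = k/n, unbiased otherwise."""
    x = p * n
    k = int(math.floor(x + 1e-9))
    frac = x - k
    if frac > 1e-9 and rng.random() < frac:
        k += 1
    return min(k, n)


def _paired_points(spec: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pair clinical points (ascending) with histo points (descending).

    This rearrangement maximizes the minimum clinical+histo sum, which makes
    the label-consistency constraints satisfiable for both groups (early MF
    cases need high floors; non-MF cases need low ceilings)."""
    clin = np.repeat([0, 1, 2], spec.clinical_point_counts)
    histo = np.repeat([2, 1, 0], spec.histo_point_counts[::-1])
    return clin, histo


def _assign_clonality(
    spec: GroupSpec,
    sums: np.ndarray,
    rng: np.random.Generator,
) -> tuple[set[int], dict[str, set[int]]]:
    """Latent-union clonality assignment.

    The any-locus union quota is assigned to the cases with the lowest
    clinical+histo sums (random among ties); locus quotas are then placed
    within the union, covering not-yet-clonal union members first so every
    union case is clonal at >= 1 locus.
    """
    n = spec.n
    u = _quota(spec.clonality_union_prob, n, rng)
    order = np.lexsort((rng.random(n), sums))
    union = [int(i) for i in order[:u]]
    counts = {locus: min(_quota(spec.clonality_prob[locus], n, rng), u) for locus in LOCI}
    if sum(counts.values()) < u:
        raise GenerationError(
            "locus quotas cannot cover the any-locus union: "
            f"sum {sum(counts.values())} < union {u}"
        )
    uncovered = [union[i] for i in rng.permutation(len(union))]
    assigned: dict[str, set[int]] = {locus: set() for locus in LOCI}
    for locus in sorted(LOCI, key=lambda l: -counts[l]):
        k = counts[locus]
        take = uncovered[: min(k, len(uncovered))]
        uncovered = uncovered[len(take):]
        chosen = set(take)
        if k > len(take):
            pool = [i for i in union if i not in chosen]
            extra = rng.choice(len(pool), size=k - len(take), replace=False)
            chosen |= {pool[int(j)] for j in extra}
        assigned[locus] = chosen
    return set(union), assigned


def _inject_discordant(
    marker: Marker, epidermal: float, criteria: CriteriaConfig, rng: np.random.Generator
) -> float:
    """Dermal value making the pair discordant under the delta rule.

    Dermal expression is kept when possible (epidermal loss with preserved
    dermal staining is the biological pattern being emulated)."""
    delta = criteria.discordance_delta_pct
    if 100.0 - epidermal >= delta:
        return float(rng.uniform(epidermal + delta, 100.0))
    if epidermal >= delta:
        return float(rng.uniform(0.0, epidermal - delta))
    # Only reachable for delta > 50: fall back to complete loss.
    dermal = 0.0
    call = is_discordant(MarkerMeasurement(marker, epidermal, dermal), criteria)
    if call is None or not call.discordant:
        raise GenerationError(
            f"cannot inject discordance at epidermal={epidermal} with delta={delta}"
        )
    return dermal


def _draw_concordant(
    marker: Marker,
    epidermal: float,
    criteria: CriteriaConfig,
    offset_limit: float,
    rng: np.random.Generator,
) -> float:
    """Dermal value concordant with the epidermal one: a uniform offset inside
    (-offset_limit, offset_limit), clipped to [0, 100] and re-drawn if the
    clipping lands in the complete-loss discordance region."""
    for _ in range(200):
        dermal = float(np.clip(epidermal + rng.uniform(-offset_limit, offset_limit), 0.0, 100.0))
        call = is_discordant(MarkerMeasurement(marker, epidermal, dermal), criteria)
        if call is not None and not call.discordant:
            return dermal
    return epidermal  # equal compartments are always concordant


def _findings_from_points(
    clin_pts: int, histo_pts: int, rng: np.random.Generator
) -> tuple[ClinicalFindings, HistoFindings]:
    clin_kwargs = dict.fromkeys(
        ("non_sun_exposed", "size_shape_variation", "poikiloderma"), False
    )
    if clin_pts > 0:
        chosen = rng.choice(3, size=clin_pts, replace=False)
        for j in chosen:
            clin_kwargs[list(clin_kwargs)[int(j)]] = True
    clinical = ClinicalFindings(persistent_progressive_patches=clin_pts > 0, **clin_kwargs)
    histo_kwargs = dict.fromkeys(("epidermotropism_without_spongiosis", "lymphoid_atypia"), False)
    if histo_pts > 0:
        chosen = rng.choice(2, size=histo_pts, replace=False)
        for j in chosen:
            histo_kwargs[list(histo_kwargs)[int(j)]] = True
    histo = HistoFindings(superficial_lymphoid_infiltrate=histo_pts > 0, **histo_kwargs)
    return clinical, histo


def _generate_group(
    label: Label,
    spec: GroupSpec,
    config: SyntheticConfig,
    criteria: CriteriaConfig,
    rng: np.random.Generator,
    prefix: str,
) -> list[CaseRecord]:
    n = spec.n
    thr = criteria.classification_threshold
    clin, histo = _paired_points(spec)
    sums = clin + histo

    union, loci_assigned = _assign_clonality(spec, sums, rng)
    mol = np.array(
        [
            1
            if sums[i] > 0
            and any(i in loci_assigned[locus] for locus in criteria.molecular_loci)
            else 0
            for i in range(n)
        ]
    )

    # Epidermal draws per marker.
    epi: dict[Marker, np.ndarray] = {}
    for marker in Marker:
        target = spec.marker_moments[marker]
        params = solve_truncnorm_params(target.mean, target.sd)
        epi[marker] = params.distribution().rvs(size=n, random_state=rng)

    # Discordance flags. Early-MF cases still short of the classification
    # threshold by exactly the immuno point are covered first; non-MF
    # discordance (if configured) goes to the lowest-scoring cases.
    need = (
        {i for i in range(n) if clin[i] + histo[i] + mol[i] == thr - 1}
        if label is Label.EARLY_MF
        else set()
    )
    remaining_need = set(need)
    disc: dict[Marker, np.ndarray] = {m: np.zeros(n, dtype=bool) for m in Marker}
    for marker in sorted(Marker, key=lambda m: -spec.discordance_prob[m]):
        d = _quota(spec.discordance_prob[marker], n, rng)
        if d == 0:
            continue
        if label is Label.EARLY_MF:
            first = [remaining_need.pop() for _ in range(min(d, len(remaining_need)))]
            pool = [i for i in range(n) if i not in first]
            extra = rng.choice(len(pool), size=d - len(first), replace=False)
            chosen = first + [pool[int(j)] for j in extra]
        else:
            order = np.lexsort((rng.random(n), clin + histo + mol))
            chosen = [int(i) for i in order[:d]]
        disc[marker][chosen] = True

    # Any early-MF case still needing the immuno point gets the group's
    # smallest CD7 draws by swapping (the marginal distribution is unchanged).
    if remaining_need:
        order = np.argsort(epi[Marker.CD7])
        targets_sorted = sorted(remaining_need)
        for rank, i in enumerate(targets_sorted):
            j = int(order[rank])
            epi[Marker.CD7][[i, j]] = epi[Marker.CD7][[j, i]]

    derm: dict[Marker, np.ndarray] = {m: np.empty(n) for m in Marker}
    for marker in Marker:
        for i in range(n):
            e = float(epi[marker][i])
            if disc[marker][i]:
                derm[marker][i] = _inject_discordant(marker, e, criteria, rng)
            else:
                derm[marker][i] = _draw_concordant(
                    marker, e, criteria, config.concordant_offset_limit, rng
                )

    sexes = np.array(
        [Sex.MALE] * spec.sex_counts[0] + [Sex.FEMALE] * spec.sex_counts[1], dtype=object
    )
    rng.shuffle(sexes)
    age_params = solve_truncnorm_params(spec.age_moments.mean, spec.age_moments.sd)
    ages = age_params.distribution().rvs(size=n, random_state=rng)

    cases: list[CaseRecord] = []
    case_order = rng.permutation(n)
    for serial, i in enumerate(case_order, start=1):
        i = int(i)
        clinical, histopath = _findings_from_points(int(clin[i]), int(histo[i]), rng)
        panel = IHCPanel(
            tuple(
                MarkerMeasurement(m, float(epi[m][i]), float(derm[m][i])) for m in Marker
            )
        )
        clonality = ClonalityResult(
            **{
                locus: Clonality.CLONAL if i in loci_assigned[locus] else Clonality.POLYCLONAL
                for locus in LOCI
            }
        )
        cases.append(
            CaseRecord(
                case_id=f"{prefix}-{serial:03d}",
                clinical=clinical,
                histo=histopath,
                panel=panel,
                clonality=clonality,
                reference_label=label,
                age_years=round(float(ages[serial - 1]), 1),
                sex=sexes[serial - 1],
            )
        )
    return cases


def generate_cohort(
    config: SyntheticConfig,
    construction_criteria: Optional[CriteriaConfig] = None,
) -> list[CaseRecord]:
    """Generate a deterministic synthetic cohort from ``config``.

    ``construction_criteria`` is the rubric under which every generated case
    must score consistently with its reference label (default: the
    ``iscl-original`` preset, the rubric the study used to define its
    groups).  A configuration that cannot be realized raises
    :class:`GenerationError` rather than silently emitting an inconsistent
    cohort.
    """
    criteria = construction_criteria if construction_criteria is not None else get_preset("iscl-original")
    rng = np.random.default_rng(config.seed)
    cases = _generate_group(Label.EARLY_MF, config.early_mf, config, criteria, rng, "MF")
    cases += _generate_group(Label.NON_MF, config.non_mf, config, criteria, rng, "NM")
    for case in cases:
        score = score_case(case, criteria)
        if score.classification is not case.reference_label:
            raise GenerationError(
                f"case {case.case_id} scores {score.total} "
                f"({score.classification.value}) under {criteria.name!r} but is "
                f"labeled {case.reference_label.value}; the configuration cannot "
                "be realized consistently"
            )
    return cases
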