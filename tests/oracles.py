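"""Independent oracles used by the test suite.

Each oracle re-derives its quantity from first principles (exhaustive
enumeration, exact rational arithmetic, or pair counting) without touching
the implementation paths it is used to check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from isclmf.cohort_model import CaseRecord, Clonality, CriteriaConfig, Label, Marker


def brute_force_total(case: CaseRecord, config: CriteriaConfig) -> tuple[int, str]:
    """Re-evaluate the diagnostic rubric by direct enumeration of its rules."""
    # clinical domain
    extras = sum(
        [
            case.clinical.non_sun_exposed,
            case.clinical.size_shape_variation,
            case.clinical.poikiloderma,
        ]
    )
    if not case.clinical.persistent_progressive_patches:
        cp = 0
    elif extras >= 2:
        cp = 2
    elif extras == 1:
        cp = 1
    else:
        cp = 0
    # histopathologic domain
    hextras = sum(
        [case.histo.epidermotropism_without_spongiosis, case.histo.lymphoid_atypia]
    )
    if not case.histo.superficial_lymphoid_infiltrate:
        hp = 0
    elif hextras >= 2:
        hp = 2
    elif hextras == 1:
        hp = 1
    else:
        hp = 0
    # molecular domain
    mp = 0
    for locus in config.molecular_loci:
        if getattr(case.clonality, locus) is Clonality.CLONAL:
            mp = 1
    # immunopathologic domain
    ip = 0
    for marker in config.immuno_markers:
        meas = case.panel[marker]
        e, d = meas.epidermal_pct, meas.dermal_pct
        cutoff = (
            config.cd7_deficiency_cutoff_pct
            if marker is Marker.CD7
            else config.pan_t_deficiency_cutoff_pct
        )
        if e is not None and e < cutoff:
            ip = 1
        if e is not None and d is not None:
            if abs(e - d) >= config.discordance_delta_pct:
                ip = 1
            elif (
                e < config.discordance_low_expression_pct
                and d < config.discordance_low_expression_pct
                and (e == 0) != (d == 0)
            ):
                ip = 1
    # ancillary gating
    if cp + hp == 0:
        mp = ip = 0
    total = cp + hp + mp + ip
    label = (
        Label.EARLY_MF.value
        if total >= config.classification_threshold
        else Label.NON_MF.value
    )
    return total, label


def fisher_two_sided_exact(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact rational
    arithmetic (sum of hypergeometric probabilities <= the observed one)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in support}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def auc_by_pair_counting(pos, neg, lower_predicts_positive=True) -> float:
    """AUC as the fraction of correctly ordered positive/negative pairs
    (ties counted half)."""
    wins = 0.0
    for p in pos:
        for q in neg:
            sp, sq = (-p, -q) if lower_predicts_positive else (p, q)
            if sp > sq:
                wins += 1.0
            elif sp == sq:
                wins += 0.5
    return wins / (len(pos) * len(neg))
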