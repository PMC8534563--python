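# Methods

## The diagnostic rubric

A case is scored on four domains. The clinical and histopathologic domains
share one structure: a *basic* criterion gates the domain, and the number
of *additional* criteria determines the points (1 additional → 1 point,
≥ 2 → 2 points, none → 0). The molecular point is earned when any
configured TCR locus (γ, δ, β) is clonal — oligoclonal patterns count as
clonal, since both indicate a clonal T-cell population; untested loci
contribute nothing, and a case with every configured locus untested is
flagged "not evaluable" rather than silently scored 0-with-confidence.
The immunopathologic point is earned when any configured marker is
*deficient* (epidermal positivity strictly `<` its cutoff — the rubric's
cutoffs are written as "<50%", "<10%", "<22.5%", so a value exactly at the
cutoff does not qualify) or *epidermally discordant*: an
epidermal–dermal difference `>=` 30 percentage points ("at least 30"
includes 30), or, among low-expressing markers (both compartments < 30%),
complete loss of expression in exactly one compartment. Both compartments
at 0% is concordant absence, not discordance. The low-expression clause is
read as applying to both compartments; the single-compartment reading
would make any (0%, 29%) pair discordant twice over and is subsumed by the
delta rule in most of its range.

Ancillary gating: when clinical + histopathologic points are 0, the
molecular and immunopathologic points are withheld (recorded in the score's
warnings), reflecting that ancillary findings are not applicable without a
major criterion. Classification is early MF iff the total reaches the
configured threshold (4 in both presets).

The `revised` preset (CD5/CD7 only, cutoffs 92.5% / 22.5%, loci γ/β only)
encodes the cutoffs that maximize Youden's index on the validation cohort.
It is deliberately a *preset*, not a recommendation baked into the code:
a 92.5% CD5 cutoff is high enough that "deficiency" becomes difficult to
distinguish from a reactive pattern, so both rubrics are exposed as equal
citizens of `CriteriaConfig`.

## Statistics

- **Fisher exact (2×2), two-sided** — sum of the hypergeometric
  probabilities of all tables with the observed margins that are no more
  probable than the observed table (relative tolerance 1e-7), accumulated
  in log space with `gammaln`/`logsumexp`. The sum-of-small-P convention is
  what mainstream packages print; tail-doubling gives visibly different
  values on asymmetric tables. Degenerate margins return p = 1 with a flag.
- **Pearson χ² (R×C)** — Σ(O−E)²/E with df = (R−1)(C−1); no continuity
  correction by default (the Yates correction is a flag, 2×2 only), so the
  same code serves R×C point-distribution tables.
- **Unpaired t from summaries** — t = (m_a − m_b)/√(sem_a² + sem_b²) with
  Welch–Satterthwaite df (default), or the classical pooled-variance test
  with per-group SD recovered as SEM·√n. Both variants are exposed because
  "unpaired t-test" underdetermines the variant; no variant is privileged.

## ROC and cutoff selection

Candidate cutoffs are midpoints between consecutive distinct observed
values plus sentinels beyond the extremes — on percentages scored on a 5%
grid this is exactly why optimal cutoffs come out as half-integers like
22.5. With `lower_predicts_positive`, sensitivity at cutoff c is the
fraction of positive values `< c` and specificity the fraction of negative
values `>= c`. The AUC is the trapezoid over the full curve, which with
midpoint cutoffs equals the rank statistic (concordant pairs + ½ ties) /
(n₊ n₋); the test suite checks that identity exhaustively. The AUC
standard error is DeLong's placement-variance estimator by default
(a Hanley–McNeil SE is an option), with a normal 95% CI clipped to [0, 1].

Youden's J = sensitivity + specificity − 1 picks the operating point. Ties
are broken toward higher specificity, then toward the cutoff nearest the
positive-class median — determinism requires *some* rule, and reporting
the perfect-specificity optimum first matches how such cutoffs are
conventionally quoted. Every other point with J within a configurable
margin (default 0.05) is returned as an alternative, so a slightly
sub-optimal but higher-sensitivity cutoff (the situation that motivates
raising a CD7 cutoff from its Youden optimum to a rounder, more sensitive
value) stays visible rather than being swallowed by an argmax.

Muller bands are the 0.1-grid qualitative labels, half-open and closed on
the left: fail < 0.6 ≤ poor < 0.7 ≤ fair < 0.8 ≤ good < 0.9 ≤ excellent.
This is the unique 0.1-grid consistent with the four published (AUC, band)
pairs (0.531 fail, 0.669 poor, 0.718 fair, 0.837 good).

## Synthetic cohort generator

The generator emulates the validation study's structure: 38 early MF and
22 non-MF cases with

- **marker expression**: epidermal percentages drawn from truncated
  normals on [0, 100] whose *post-truncation* mean and SD match the
  published group summaries (SD = SEM·√n). The (μ, σ) pair is found by 2-D
  root finding on the closed-form truncated-normal moments (residuals
  < 1e-6), with multi-start to handle the far-tail regime where the
  solution has |μ| of hundreds.
- **a feasibility envelope**: a truncated normal cannot realize every
  (mean, SD) pair — as σ → ∞ the family tends to exponentially tilted
  uniforms, whose SD at a given mean is the supremum of what is
  attainable. `max_truncnorm_sd` computes that envelope and the solver
  rejects infeasible targets naming the bound. Three published pairs
  (early-MF CD2 84.08 ± SD 19.45, CD3 91.84 ± 10.62, CD5 81.18 ± 21.19)
  exceed their envelopes (15.48, 8.16, 17.83) — the real data are more
  skewed than any truncated normal — so the study preset keeps those means
  and clamps the SDs to 0.98× the envelope. CD7, the marker that carries
  the discriminative signal and every headline quantity, is feasible and
  matched exactly (early MF 17.45 ± 16.32; non-MF 42.95 ± 22.34).
- **dermal values**: discordant cases get a ≥ 30-point offset injected
  (dermal kept higher when possible — epidermal loss with preserved dermal
  staining is the pattern being emulated); concordant cases draw a uniform
  offset inside (−30, 30), clipped to [0, 100] and re-drawn if clipping
  lands in the complete-loss region. Discordance frequencies are realized
  as quotas (CD5 2/38 and CD7 15/38 in early MF; none in non-MF).
- **clonality**: a latent any-locus "clonal case" quota is assigned first
  (36/38 early MF; 4/22 non-MF), then per-locus quotas (γ 33/38 & 4/22,
  δ 6/38 & 3/22, β 16/38 & 0/22) are placed inside it, covering
  not-yet-clonal union members first. Independent per-locus Bernoullis
  cannot hit both the margins and the union, hence the coupling. The
  non-MF union is set to 4/22 because γ alone is 4/22, which forces the
  union to at least that value.
- **clinical/histo points**: realized exactly by quota (early MF 1/7/30
  and 3/15/20 cases at 0/1/2 points; non-MF 9/8/5 and 5/12/5), then paired
  ascending-vs-descending across the two domains. This rearrangement
  maximizes the minimum clinical+histo sum within a group (and thereby
  minimizes the maximum for the low-scoring group), which is what makes
  the next constraint satisfiable.
- **label consistency**: the study's groups were *defined* by ISCL score
  ≥ 4 vs < 4, so a faithful simulator must reproduce that selection, not
  just the marginals. Clonality quotas go to the lowest-scoring cases
  first; discordance quotas cover early-MF cases still exactly one point
  short of the threshold; if any remain, they receive the group's smallest
  CD7 draws by swapping (which leaves the marginal distribution
  untouched). Every generated cohort is then verified case-by-case under
  the construction rubric (`iscl-original` by default) and generation
  fails loudly (`GenerationError`) rather than emitting an inconsistent
  cohort. A consequence worth knowing: non-MF totals stay ≤ 3 under both
  bundled presets, so the study preset yields zero non-MF → early-MF
  reclassifications; revised-rubric gains must be studied with custom
  configurations or real data.
- **ages** are drawn from moment-matched truncated normals on [0, 100]
  (the published 2.858/3.896 are treated as SEMs — as SDs they would imply
  implausibly homogeneous ages); sexes are exact quotas (22:16, 10:12).
  Neither enters the score.

What passing tests on this generator do **not** show: the truncated-normal
shape is only moment-matched, so shape-sensitive quantities (e.g. the
fraction of early-MF cases below 10% CD7, or a single cohort's realized
SD) can differ from the empirical cohort's; markers are drawn
independently, so joint-loss structure (CD5–CD7 co-loss) is absent; and
reference labels are score-consistent by construction, so the preset
cannot probe rubric *disagreement* with an external gold standard.

## Problem sizes and numerical choices

The replicate analyses use 1000 study-preset cohorts in
`scripts/acceptance.py` and 250–400 in the test suite — enough for the
Monte-Carlo SE of the mean CD7 AUC (single-cohort SD ≈ 0.058 at n = 38/22)
to be ≈ 0.002, i.e. negligible against the quantities compared. The moment
solver targets 1e-6 residuals; Fisher probabilities are compared with a
1e-7 relative tolerance; report serialization sorts keys so identical
inputs give identical bytes. Degenerate inputs are handled explicitly:
empty margins (Fisher p = 1 flagged; χ² raises naming the dimension),
single-class ROC inputs raise, an all-identical value vector degenerates
to a single warned cutoff, and empty confusion cells yield `None` metrics
rather than dividing by zero.
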