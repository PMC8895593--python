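"""Seeded synthetic cohorts with the structure of a large midlife survey.

The generator draws, for each woman, a latent reproductive history — baseline
age, age at natural menopause, interventions and their ages — and then
produces the questionnaire responses that history would induce, including
the masking that motivates the derivation algorithm: a hysterectomy before
the final menstrual period, or MHT begun before periods stopped, removes the
bleeding signal, so masked women answer "not sure" with probability
``p_not_sure_given_masked`` instead of reporting their latent state.
Bilateral oophorectomy induces menopause at the surgery age (the latent
state changes); hysterectomy and MHT never change the latent state, only
its reporting. Missing responses, missing event ages and internally
inconsistent ages are injected at configurable rates.

The latent truth (state at baseline, menopause age, masking) is returned
alongside the records but never stored in them, so classifier recovery can
be scored against ground truth that the classifier cannot see.

Default parameters emulate the published cohort: baseline ages with median
59.9 and IQR 52.8-69.0 (two-piece normal, truncated to >= 45), age at
natural menopause with median 50 (truncated normal, location 50, scale 3.7,
support 35-60), 46.9% of women with no interventions, and 2% current
hormonal-contraceptive users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .consolidate import ConsolidatedStatus
from .detailed import ClassificationResult
from .interventions import InterventionCategory
from .io import AlignmentError
from .records import MenopauseResponse, MHTUse, ParticipantRecord, YesNoMissing

#: Latent state labels.
PRE, PERI, POST = "pre", "peri", "post"

_INTERVENTION_CATEGORIES = [
    c
    for c in InterventionCategory
    if c not in (InterventionCategory.NONE, InterventionCategory.INCOMPLETE)
]

_CAT_HYST = {c for c in _INTERVENTION_CATEGORIES if c.value.startswith("hyst")}
_CAT_OOPH = {c for c in _INTERVENTION_CATEGORIES if "ooph" in c.value}
_CAT_MHT_FORMER = {c for c in _INTERVENTION_CATEGORIES if "mht_former" in c.value}
_CAT_MHT_CURRENT = {c for c in _INTERVENTION_CATEGORIES if "mht_current" in c.value}


@dataclass(frozen=True, slots=True)
class GeneratorParams:
    """Cohort-generator parameters (defaults emulate the published cohort)."""

    n: int = 10_000
    seed: int = 0
    # baseline age: two-piece normal matched to median / IQR, truncated
    baseline_age_median: float = 59.9
    baseline_age_iqr: tuple[float, float] = (52.8, 69.0)
    baseline_age_support: tuple[float, float] = (45.0, 100.0)
    # age at natural menopause: truncated normal (median ~50)
    menopause_age_loc: float = 50.0
    menopause_age_scale: float = 3.7
    menopause_age_support: tuple[float, float] = (35.0, 60.0)
    # interventions
    p_no_intervention: float = 0.469
    intervention_mix: Optional[dict[InterventionCategory, float]] = None
    # reporting behaviour and corruption
    p_not_sure_given_masked: float = 0.6
    missing_core_rate: float = 0.03
    missing_event_age_rate: float = 0.05
    inconsistency_rate: float = 0.01
    p_oc_current: float = 0.02
    peri_window_years: float = 2.0

    def resolved_mix(self) -> dict[InterventionCategory, float]:
        """Absolute probabilities of the 11 intervention combinations.

        Defaults to a uniform split of ``1 - p_no_intervention`` (per-category
        frequencies of the source cohort are not published).
        """
        if self.intervention_mix is None:
            share = (1.0 - self.p_no_intervention) / len(_INTERVENTION_CATEGORIES)
            return {c: share for c in _INTERVENTION_CATEGORIES}
        unknown = set(self.intervention_mix) - set(_INTERVENTION_CATEGORIES)
        if unknown:
            raise ValueError(f"intervention_mix has invalid categories: {unknown}")
        mix = {c: self.intervention_mix.get(c, 0.0) for c in _INTERVENTION_CATEGORIES}
        if any(v < 0 for v in mix.values()):
            raise ValueError("intervention_mix probabilities must be >= 0")
        total = sum(mix.values()) + self.p_no_intervention
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"intervention_mix + p_no_intervention must sum to 1 (got {total})"
            )
        return mix

    def __post_init__(self) -> None:
        for name in (
            "p_no_intervention",
            "p_not_sure_given_masked",
            "missing_core_rate",
            "missing_event_age_rate",
            "inconsistency_rate",
            "p_oc_current",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        lo, hi = self.baseline_age_support
        if not lo < hi or lo < 0:
            raise ValueError("invalid baseline_age_support")
        if not self.menopause_age_support[0] < self.menopause_age_support[1]:
            raise ValueError("invalid menopause_age_support")
        self.resolved_mix()  # validates the simplex eagerly


@dataclass(slots=True)
class SyntheticCohort:
    """Generated records plus the latent truth they were generated from.

    ``truth`` has one row per record: ``participant_id``, ``latent_state``
    (pre/peri/post at baseline), ``latent_menopause_age`` and ``masked``.
    """

    records: list[ParticipantRecord]
    truth: pd.DataFrame
    params: GeneratorParams


def _two_piece_normal(rng, n, median, iqr, support):
    """Two-piece normal via per-side truncated half-normals.

    Each side keeps probability 1/2, so the median is exact; the side scales
    are fitted to the quartiles (truncation at the support compresses the
    tails slightly).
    """
    z75 = ndtri(0.75)
    sigma_lo = (median - iqr[0]) / z75
    sigma_hi = (iqr[1] - median) / z75
    lo, hi = support
    zmax_lo = max((median - lo) / sigma_lo, 1e-9)
    zmax_hi = max((hi - median) / sigma_hi, 1e-9)
    upper = rng.random(n) < 0.5
    u = rng.random(n)
    z_lo = ndtri(0.5 + u * (ndtr(zmax_lo) - 0.5))
    z_hi = ndtri(0.5 + u * (ndtr(zmax_hi) - 0.5))
    return np.where(upper, median + sigma_hi * z_hi, median - sigma_lo * z_lo)


def generate_cohort(params: GeneratorParams) -> SyntheticCohort:
    """Generate exactly ``params.n`` records, deterministically in the seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    ids = [f"S{i + 1:06d}" for i in range(n)]

    baseline = np.round(
        _two_piece_normal(
            rng, n, params.baseline_age_median, params.baseline_age_iqr,
            params.baseline_age_support,
        ),
        1,
    )
    a, b = (
        (params.menopause_age_support[0] - params.menopause_age_loc) / params.menopause_age_scale,
        (params.menopause_age_support[1] - params.menopause_age_loc) / params.menopause_age_scale,
    )
    natural_age = stats.truncnorm.ppf(
        rng.random(n), a, b, loc=params.menopause_age_loc, scale=params.menopause_age_scale
    )

    mix = params.resolved_mix()
    labels = [InterventionCategory.NONE] + _INTERVENTION_CATEGORIES
    probs = np.array([params.p_no_intervention] + [mix[c] for c in _INTERVENTION_CATEGORIES])
    probs = probs / probs.sum()  # guard rounding
    cat_idx = rng.choice(len(labels), size=n, p=probs)

    def _label_flags(members: set) -> np.ndarray:
        return np.array([c in members for c in labels], dtype=bool)[cat_idx]

    has_hyst = _label_flags(_CAT_HYST)
    has_ooph = _label_flags(_CAT_OOPH)
    mht_former = _label_flags(_CAT_MHT_FORMER)
    mht_current = _label_flags(_CAT_MHT_CURRENT)
    has_mht = mht_former | mht_current

    # intervention ages: surgeries uniform over adult pre-baseline years; MHT
    # initiation clusters around the (latent) final menstrual period
    ooph_age = rng.uniform(35.0, baseline)
    hyst_age = rng.uniform(35.0, baseline)
    latent_meno = np.where(has_ooph, np.minimum(natural_age, ooph_age), natural_age)
    mht_start = np.clip(latent_meno + rng.uniform(-5.0, 5.0, size=n), 30.0, baseline)

    latent_post = baseline >= latent_meno
    latent_peri = (~latent_post) & (latent_meno - baseline <= params.peri_window_years)
    latent_state = np.where(latent_post, POST, np.where(latent_peri, PERI, PRE))

    masked = (
        (has_hyst & (hyst_age < latent_meno))
        | mht_current
        | (has_mht & (mht_start < latent_meno))
    )

    report = np.empty(n, dtype=object)
    report[latent_post] = MenopauseResponse.YES
    report[latent_peri] = MenopauseResponse.IRREGULAR
    report[~latent_post & ~latent_peri] = MenopauseResponse.NO
    not_sure = masked & (rng.random(n) < params.p_not_sure_given_masked)
    report[not_sure] = MenopauseResponse.NOT_SURE

    oc_current = rng.random(n) < params.p_oc_current

    # reported event ages (one decimal, as if computed from dates)
    meno_age_rep: list[Optional[float]] = [
        round(float(latent_meno[i]), 1) if report[i] is MenopauseResponse.YES else None
        for i in range(n)
    ]
    hyst_age_rep = [round(float(hyst_age[i]), 1) if has_hyst[i] else None for i in range(n)]
    ooph_age_rep = [round(float(ooph_age[i]), 1) if has_ooph[i] else None for i in range(n)]
    mht_age_rep = [round(float(mht_start[i]), 1) if has_mht[i] else None for i in range(n)]

    # corruption: missing event ages
    drop = rng.random((4, n)) < params.missing_event_age_rate
    for i in range(n):
        if drop[0, i]:
            meno_age_rep[i] = None
        if drop[1, i]:
            hyst_age_rep[i] = None
        if drop[2, i]:
            ooph_age_rep[i] = None
        if drop[3, i]:
            mht_age_rep[i] = None

    # corruption: missing core responses. Mostly the menopause response, so
    # that the empirical intervention-category mix still recovers
    # p_no_intervention; a minority blanks an intervention response, which
    # exercises the INCOMPLETE category.
    core_missing = rng.random(n) < params.missing_core_rate
    blank_menopause = rng.random(n) < 0.8
    which_intervention = rng.integers(0, 3, size=n)

    # corruption: internally inconsistent event age (beyond baseline + slack)
    inject = rng.random(n) < params.inconsistency_rate

    records: list[ParticipantRecord] = []
    for i in range(n):
        menopause = report[i]
        mht = (
            MHTUse.CURRENT if mht_current[i]
            else MHTUse.FORMER if mht_former[i]
            else MHTUse.NEVER
        )
        hyst = YesNoMissing.YES if has_hyst[i] else YesNoMissing.NO
        ooph = YesNoMissing.YES if has_ooph[i] else YesNoMissing.NO
        if core_missing[i]:
            if blank_menopause[i]:
                menopause = MenopauseResponse.MISSING
            elif which_intervention[i] == 0:
                mht = MHTUse.MISSING
            elif which_intervention[i] == 1:
                hyst = YesNoMissing.MISSING
            else:
                ooph = YesNoMissing.MISSING
        ages = {
            "age_at_menopause": meno_age_rep[i],
            "age_at_hysterectomy": hyst_age_rep[i],
            "age_at_oophorectomy": ooph_age_rep[i],
            "age_started_mht": mht_age_rep[i],
        }
        if inject[i]:
            bad = round(float(baseline[i]) + 5.0, 1)
            for key in ages:  # corrupt the first present event age
                if ages[key] is not None:
                    ages[key] = bad
                    break
        records.append(
            ParticipantRecord(
                participant_id=ids[i],
                age_at_baseline=float(baseline[i]),
                menopause=menopause,
                mht=mht,
                hysterectomy=hyst,
                oophorectomy=ooph,
                oc_current=YesNoMissing.YES if oc_current[i] else YesNoMissing.NO,
                **ages,
            )
        )

    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "latent_state": latent_state,
            "latent_menopause_age": np.round(latent_meno, 3),
            "masked": masked,
        }
    )
    return SyntheticCohort(records=records, truth=truth, params=params)


@dataclass(slots=True)
class TruthComparison:
    """Confusion of latent state against consolidated derived status."""

    table: pd.DataFrame  # latent_state x consolidated status counts
    post_sensitivity: Optional[float]  # P(derived post | latent post); None if undefined
    n: int


def truth_confusion(
    cohort: SyntheticCohort, results: Sequence[ClassificationResult]
) -> TruthComparison:
    """Cross-tabulate latent state against the consolidated derived status.

    ``post_sensitivity`` is the share of latent post-menopausal women the
    derivation recovers as post-menopause; it is reported as ``None`` when
    no woman is latently post-menopausal (degenerate denominator).
    """
    if len(results) != len(cohort.records):
        raise AlignmentError(f"{len(cohort.records)} records vs {len(results)} results")
    derived = []
    for record, result in zip(cohort.records, results):
        if record.participant_id != result.participant_id:
            raise AlignmentError(
                f"record {record.participant_id!r} paired with result "
                f"{result.participant_id!r}"
            )
        derived.append("" if result.consolidated is None else result.consolidated.value)
    frame = pd.DataFrame(
        {"latent_state": cohort.truth["latent_state"].to_numpy(), "derived": derived}
    )
    table = pd.crosstab(frame["latent_state"], frame["derived"])
    n_post = int((frame["latent_state"] == POST).sum())
    if n_post == 0:
        sensitivity = None
    else:
        hits = int(
            (
                (frame["latent_state"] == POST)
                & (frame["derived"] == ConsolidatedStatus.POST_MENOPAUSE.value)
            ).sum()
        )
        sensitivity = hits / n_post
    return TruthComparison(table=table, post_sensitivity=sensitivity, n=len(frame))


def self_report_post_sensitivity(cohort: SyntheticCohort) -> Optional[float]:
    """Share of latent post-menopausal women who directly self-report menopause.

    The raw-questionnaire baseline against which the derived status is judged.
    """
    latent_post = cohort.truth["latent_state"].to_numpy() == POST
    n_post = int(latent_post.sum())
    if n_post == 0:
        return None
    yes = np.array(
        [r.menopause is MenopauseResponse.YES for r in cohort.records], dtype=bool
    )
    return float((latent_post & yes).sum() / n_post)
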