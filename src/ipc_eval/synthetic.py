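"""Synthetic longitudinal cohorts with the structure the analysis assumes.

The study enrolled 97 young and middle-aged hypertensive patients, 96 of
whom were followed over four questionnaires at months 0/3/6/12, with one
patient dropping out during the third questionnaire.  The raw data are not
deposited, so this module generates cohorts that emulate the published
summary structure: sex-stratified baselines for age, blood pressure and
questionnaire total score, a ~-13/-7 mmHg SBP/DBP intervention effect from
month 3 on, and a ~+15-point questionnaire improvement realised by month 12
through a designated subset of items.

Item scores come from a latent-trait model: each patient carries a latent
adherence level, correlated across timepoints; each item adds independent
noise and the sum is discretised to the 1-5 Likert grid.  The latent item
mean is calibrated numerically so that the *discretised* item mean matches
its target, which keeps cohort-level total-score means on the configured
values despite rounding and clipping.  Items are generated on the adjusted
(higher-is-better) scale and reverse-coded items are mapped back to raw
scores via x -> 6 - x, so an injected improvement lowers the raw score of
Q1 and Q6-Q13 while raising the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import ITEMS, REVERSE_ITEMS

__all__ = [
    "CohortConfig",
    "QuestionnaireRecord",
    "generate_cohort",
    "generate_completion_times",
    "write_fixture",
    "read_fixture",
    "cohort_to_frame",
]

#: Score improvement realised at each timepoint, as a fraction of the
#: 12-month effect (linear ramp over the follow-up year).
SCORE_EFFECT_RAMP = (0.0, 1 / 3, 2 / 3, 1.0)

#: Blood-pressure effect is fully realised from month 3 on and then stable.
BP_EFFECT_RAMP = (0.0, 1.0, 1.0, 1.0)

#: Default set of items carrying the injected improvement: ten items,
#: three of them reverse-coded, mirroring the ten questions reported as
#: improved (their identities are not machine-readable in the source).
DEFAULT_IMPROVED_ITEMS = (
    "Q1", "Q6", "Q7", "Q15", "Q16", "Q17", "Q18", "Q19", "Q20", "Q21",
)


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One patient x timepoint row of raw (un-adjusted) questionnaire data."""

    patient_id: str
    sex: str
    age: float
    timepoint: int
    item_scores: dict[str, int]
    completion_time: float
    sbp: float
    dbp: float

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.timepoint not in (1, 2, 3, 4):
            raise ValueError(f"timepoint must be 1..4, got {self.timepoint}")
        for item in ITEMS:
            v = self.item_scores.get(item)
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"item {item} out of range: {v!r}")
        if self.completion_time < 0:
            raise ValueError("completion_time must be >= 0")
        if not self.sbp > self.dbp > 0:
            raise ValueError(f"need sbp > dbp > 0, got ({self.sbp}, {self.dbp})")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the published cohort: 96 patients (49 male /
    47 female), baseline means and SDs per sex, a -13/-7 mmHg SBP/DBP
    effect from month 3 and a +15-point questionnaire effect at month 12
    carried by ``improved_items``, with one dropout missing the last two
    questionnaires.
    """

    n_patients: int = 96
    n_male: int = 49
    n_female: int = 47
    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 45.84, "female": 47.33})
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"male": 9.62, "female": 10.84})
    sbp_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 143.04, "female": 133.66})
    sbp_sd: Mapping[str, float] = field(
        default_factory=lambda: {"male": 16.41, "female": 16.63})
    dbp_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 94.71, "female": 88.77})
    dbp_sd: Mapping[str, float] = field(
        default_factory=lambda: {"male": 12.71, "female": 12.81})
    score_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 93.78, "female": 99.02})
    score_sd: Mapping[str, float] = field(
        default_factory=lambda: {"male": 12.90, "female": 15.17})
    sbp_effect_3mo: float = -13.0
    dbp_effect_3mo: float = -7.0
    score_effect_12mo: float = 15.0
    improved_items: tuple[str, ...] = DEFAULT_IMPROVED_ITEMS
    dropout_count: int = 1
    timepoints: tuple[int, ...] = (0, 3, 6, 12)
    completion_mean: tuple[float, ...] = (1.95, 6.25, 5.03, 4.20)
    completion_sd: tuple[float, ...] = (2.55, 3.19, 2.66, 3.07)
    #: Correlation of the patient latent trait across repeated
    #: questionnaires (not reported by the study; exposed as a knob).
    within_patient_corr: float = 0.7
    #: Within-patient SD of a single item around the latent trait, in
    #: adjusted-score points.
    item_noise_sd: float = 0.8
    #: Measurement noise of repeated BP readings, mmHg.
    bp_noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_male + self.n_female != self.n_patients:
            raise ValueError(
                f"n_male + n_female = {self.n_male + self.n_female} "
                f"!= n_patients = {self.n_patients}")
        for name in ("age_sd", "sbp_sd", "dbp_sd", "score_sd"):
            for sex, sd in getattr(self, name).items():
                if sd <= 0:
                    raise ValueError(f"{name}[{sex}] must be > 0, got {sd}")
        if any(sd < 0 for sd in self.completion_sd):
            raise ValueError("completion_sd entries must be >= 0")
        if any(m < 0 for m in self.completion_mean):
            raise ValueError("completion_mean entries must be >= 0")
        if not 0 <= self.dropout_count < self.n_patients:
            raise ValueError("dropout_count must be in [0, n_patients)")
        bad = set(self.improved_items) - set(ITEMS)
        if bad:
            raise ValueError(f"improved_items not in Q1..Q25: {sorted(bad)}")
        if self.score_effect_12mo != 0 and not self.improved_items:
            raise ValueError(
                "improved_items must be nonempty when score_effect_12mo != 0")
        if not -1 < self.within_patient_corr < 1:
            raise ValueError("within_patient_corr must be in (-1, 1)")
        if len(self.completion_mean) != len(self.timepoints) or \
                len(self.completion_sd) != len(self.timepoints):
            raise ValueError("completion parameters must match timepoints")


# ---------------------------------------------------------------------------
# Likert discretisation calibration
# ---------------------------------------------------------------------------

def _discretised_mean(mu: float, sigma: float) -> float:
    """E[clip(round(mu + sigma*Z), 1, 5)] for Z ~ N(0, 1)."""
    if sigma == 0:
        return float(np.clip(round(mu), 1, 5))
    cuts = np.array([1.5, 2.5, 3.5, 4.5])
    upper = stats.norm.cdf((cuts - mu) / sigma)
    probs = np.diff(np.concatenate([[0.0], upper, [1.0]]))
    return float(np.dot(np.arange(1, 6), probs))


@lru_cache(maxsize=4096)
def _latent_item_mean(target: float, sigma: float) -> float:
    """Latent mean whose discretised Likert mean equals ``target``."""
    target = float(np.clip(target, 1.0 + 1e-9, 5.0 - 1e-9))
    return float(optimize.brentq(
        lambda m: _discretised_mean(m, sigma) - target, -6.0, 12.0, xtol=1e-10))


def _latent_sds(cfg: CohortConfig, sex: str) -> tuple[float, float]:
    """(patient-level, item-level) latent SDs approximating the total-score SD.

    Var(total) ~ (25*sigma_z)^2 + 25*(sigma_e^2 + 1/12), ignoring clipping;
    the 1/12 term is the rounding variance.  Falls back to a small floor
    when the configured SD is smaller than the discretisation noise alone.
    """
    sigma_e = cfg.item_noise_sd
    var_total = cfg.score_sd[sex] ** 2
    var_z = (var_total - 25 * (sigma_e**2 + 1 / 12)) / 625
    return float(np.sqrt(max(var_z, 1e-4))), sigma_e


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_completion_times(
    config: CohortConfig, timepoint: int, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Completion times (minutes) for every patient at one timepoint.

    Drawn from a zero-truncated normal re-parametrised so that the mean of
    the *truncated* distribution equals the configured mean (a plain
    truncation would bias short questionnaires upward).  ``sd = 0``
    degenerates to a point mass at the mean.
    """
    if timepoint not in (1, 2, 3, 4):
        raise ValueError(f"timepoint must be 1..4, got {timepoint}")
    mean = config.completion_mean[timepoint - 1]
    sd = config.completion_sd[timepoint - 1]
    if mean < 0:
        raise ValueError(f"completion-time mean must be >= 0, got {mean}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1000 + timepoint)
    n = config.n_patients
    if sd == 0:
        return np.full(n, float(mean))

    if mean == 0:
        # a zero-truncated normal cannot have mean exactly 0
        return np.zeros(n)

    def trunc_mean(mu: float) -> float:
        a = (0.0 - mu) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    # trunc_mean is increasing in mu and > 0 everywhere; expand the lower
    # bracket until it undershoots the target (short means need mu << 0).
    lo, hi = mean - 10 * sd, mean + sd
    while trunc_mean(lo) > mean and lo > mean - 1e4 * sd:
        lo -= 10 * sd
    mu = float(optimize.brentq(lambda m: trunc_mean(m) - mean, lo, hi, xtol=1e-9))
    a = (0.0 - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[QuestionnaireRecord]:
    """Generate one cohort of patient x timepoint questionnaire records.

    Deterministic for a fixed config (including its seed).  Dropout
    patients are missing timepoints 3 and 4.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_tp = len(config.timepoints)
    sexes = ["male"] * config.n_male + ["female"] * config.n_female
    n_improved = max(len(config.improved_items), 1)

    dropouts = set(
        rng.choice(config.n_patients, size=config.dropout_count, replace=False))

    completion = {
        tp: generate_completion_times(config, tp, rng) for tp in range(1, n_tp + 1)
    }

    rho = config.within_patient_corr
    records: list[QuestionnaireRecord] = []
    for i, sex in enumerate(sexes):
        pid = f"P{i + 1:03d}"
        age = float(rng.normal(config.age_mean[sex], config.age_sd[sex]))
        age = float(np.clip(age, 18.0, 65.0))  # enrollment criterion

        # Baseline BP: DBP plus an independent pulse-pressure so SBP > DBP.
        dbp0 = float(stats.truncnorm.rvs(
            (40.0 - config.dbp_mean[sex]) / config.dbp_sd[sex], np.inf,
            loc=config.dbp_mean[sex], scale=config.dbp_sd[sex], random_state=rng))
        pp_var = config.sbp_sd[sex] ** 2 - config.dbp_sd[sex] ** 2
        pp_sd = float(np.sqrt(pp_var)) if pp_var > 1.0 else 1.0
        pp0 = float(max(rng.normal(
            config.sbp_mean[sex] - config.dbp_mean[sex], pp_sd), 5.0))

        sigma_z, sigma_e = _latent_sds(config, sex)
        z_base = rng.standard_normal()

        for t in range(1, n_tp + 1):
            if i in dropouts and t >= 3:
                continue
            # latent adherence, exchangeably correlated across timepoints
            z = rho * z_base + np.sqrt(1 - rho**2) * rng.standard_normal()

            score_shift = config.score_effect_12mo * SCORE_EFFECT_RAMP[t - 1]
            base_item_mean = config.score_mean[sex] / 25.0
            adjusted = {}
            for item in ITEMS:
                target = base_item_mean
                if item in config.improved_items:
                    target += score_shift / n_improved
                mu = _latent_item_mean(target, np.hypot(sigma_z, sigma_e))
                val = mu + sigma_z * z + sigma_e * rng.standard_normal()
                adjusted[item] = int(np.clip(round(val), 1, 5))
            raw = {
                item: (6 - v) if item in REVERSE_ITEMS else v
                for item, v in adjusted.items()
            }

            bp_ramp = BP_EFFECT_RAMP[t - 1]
            dbp = dbp0 + config.dbp_effect_3mo * bp_ramp \
                + config.bp_noise_sd * rng.standard_normal()
            dbp = float(max(dbp, 40.0))
            pp = pp0 + (config.sbp_effect_3mo - config.dbp_effect_3mo) * bp_ramp \
                + config.bp_noise_sd * rng.standard_normal()
            sbp = dbp + float(max(pp, 5.0))

            rec = QuestionnaireRecord(
                patient_id=pid, sex=sex, age=round(age, 1), timepoint=t,
                item_scores=raw,
                completion_time=round(float(completion[t][i]), 2),
                sbp=round(sbp, 1), dbp=round(dbp, 1),
            )
            rec.validate()
            records.append(rec)
    return records


def null_config(config: CohortConfig | None = None, **kwargs) -> CohortConfig:
    """A copy of ``config`` with every intervention effect set to zero."""
    cfg = config or CohortConfig(**kwargs)
    return replace(cfg, sbp_effect_3mo=0.0, dbp_effect_3mo=0.0,
                   score_effect_12mo=0.0)


# ---------------------------------------------------------------------------
# CSV fixtures
# ---------------------------------------------------------------------------

FIXTURE_COLUMNS = (
    ["patient_id", "sex", "age", "timepoint"]
    + list(ITEMS)
    + ["completion_time_min", "sbp", "dbp"]
)


class FixtureError(ValueError):
    """Malformed cohort CSV; message carries the row number and field."""


def cohort_to_frame(records: Sequence[QuestionnaireRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "sex": r.sex, "age": r.age,
               "timepoint": r.timepoint}
        row.update({item: r.item_scores[item] for item in ITEMS})
        row.update({"completion_time_min": r.completion_time,
                    "sbp": r.sbp, "dbp": r.dbp})
        rows.append(row)
    return pd.DataFrame(rows, columns=FIXTURE_COLUMNS)


def write_fixture(records: Sequence[QuestionnaireRecord], path) -> None:
    """Write records as CSV, one row per patient x timepoint."""
    cohort_to_frame(records).to_csv(path, index=False)


def read_fixture(path) -> list[QuestionnaireRecord]:
    """Read a cohort CSV back into records, validating every row."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FixtureError(f"cannot parse {path}: {exc}") from exc
    missing = set(FIXTURE_COLUMNS) - set(df.columns)
    if missing:
        raise FixtureError(f"missing columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        try:
            items = {}
            for item in ITEMS:
                v = row[item]
                if not float(v).is_integer() or not 1 <= int(v) <= 5:
                    raise FixtureError(
                        f"row {rownum}, field {item}: invalid score {v!r}")
                items[item] = int(v)
            rec = QuestionnaireRecord(
                patient_id=str(row["patient_id"]), sex=str(row["sex"]),
                age=float(row["age"]), timepoint=int(row["timepoint"]),
                item_scores=items,
                completion_time=float(row["completion_time_min"]),
                sbp=float(row["sbp"]), dbp=float(row["dbp"]),
            )
            rec.validate()
        except FixtureError:
            raise
        except (TypeError, ValueError) as exc:
            raise FixtureError(f"row {rownum}: {exc}") from exc
        records.append(rec)
    return records
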