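"""Adapted LIBRA (LIfestyle for BRAin health) weighted dementia-risk score.

The LIBRA index summarises modifiable dementia risk into a single weighted sum:
each lifestyle/health factor is dichotomised against a published cut-off and,
when present, contributes its meta-analysis-derived weight (negative weights
protect, positive weights harm).  Twelve factors carry weights; occupational or
leisure-time cognitive activity is typically unavailable in population cohorts
with this phenotyping and is treated as such by default, so attainable scores
lie in [-2.7, +12.7].

Higher score = higher dementia risk.  For analyses that need a categorical
exposure the score is split into empirical tertiles (tertile 1 = lowest risk =
reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_WEIGHTS",
    "FACTORS",
    "PROTECTIVE_FACTORS",
    "RISK_FACTORS",
    "LibraConfig",
    "LibraScoreResult",
    "load_weights",
    "dichotomize_factors",
    "dichotomize_cohort",
    "compute_libra",
    "compute_modified_libra",
    "assign_tertiles",
    "score_cohort",
]

#: Published factor weights of the adapted LIBRA index.
DEFAULT_WEIGHTS: dict[str, float] = {
    "mediterranean_diet": -1.7,
    "low_moderate_alcohol": -1.0,
    "physical_inactivity": 1.1,
    "smoking": 1.5,
    "obesity": 1.6,
    "hypertension": 1.6,
    "high_cholesterol": 1.4,
    "type2_diabetes": 1.3,
    "heart_disease": 1.0,
    "chronic_kidney_disease": 1.1,
    "depression": 2.1,
    "cognitive_activity": -3.2,
}

FACTORS: tuple[str, ...] = tuple(DEFAULT_WEIGHTS)
PROTECTIVE_FACTORS = tuple(f for f, w in DEFAULT_WEIGHTS.items() if w < 0)
RISK_FACTORS = tuple(f for f, w in DEFAULT_WEIGHTS.items() if w > 0)

# Factor states
PRESENT = "present"
ABSENT = "absent"
UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class LibraConfig:
    """Cut-offs and coding choices for factor dichotomisation.

    Attributes
    ----------
    abstainers_protective
        Whether zero alcohol intake counts as the protective
        "low-to-moderate alcohol" state.  The default (``False``) codes the
        factor present only for ``0 < intake < alcohol_max_g_week``: the
        factor rewards low-to-moderate use, not abstention.
    unavailable_factors
        Factors never assessed in the dataset; scored as contributing 0.
        Cognitive activity by default.
    """

    diet_score_min: float = 6.0          # Mediterranean diet score (0-9), >= is adherence
    alcohol_max_g_week: float = 70.0     # strict upper bound for low-to-moderate use
    abstainers_protective: bool = False
    mvpa_min_week: float = 150.0         # < this of moderate-to-vigorous activity -> inactive
    bmi_obese: float = 30.0              # >= is obesity
    sbp_max: float = 140.0               # >= is hypertensive
    dbp_max: float = 90.0                # >= is hypertensive
    cholesterol_max: float = 6.5         # mmol/L, >= is high cholesterol
    fasting_glucose_max: float = 7.0     # mmol/L, >= meets the diabetes criterion
    ogtt_glucose_max: float = 11.1       # mmol/L 2-h value, >= meets the diabetes criterion
    egfr_min: float = 60.0               # mL/min/1.73m2, < is chronic kidney disease
    phq9_min: float = 10.0               # >= is moderate-to-severe depressive symptoms
    unavailable_factors: tuple[str, ...] = ("cognitive_activity",)


def load_weights(path: str | None = None) -> dict[str, float]:
    """Load factor weights from a YAML file (the shipped defaults if ``path`` is None)."""
    if path is None:
        text = resources.files("brainpath.data").joinpath("libra_weights.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    weights = {str(k): float(v) for k, v in raw["weights"].items()}
    unknown = set(weights) - set(DEFAULT_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown LIBRA factors in weights file: {sorted(unknown)}")
    return weights


# ---------------------------------------------------------------------------
# Dichotomisation
# ---------------------------------------------------------------------------

def dichotomize_cohort(table: pd.DataFrame, config: LibraConfig | None = None) -> pd.DataFrame:
    """Dichotomise raw measurements into per-factor indicators for a whole cohort.

    Parameters
    ----------
    table
        One row per participant with the raw measurement columns
        (see :mod:`brainpath.synthetic` for the column dictionary).
    config
        Cut-offs; defaults to the published operationalisation.

    Returns
    -------
    DataFrame indexed like ``table`` with one column per LIBRA factor holding
    ``"present"`` / ``"absent"`` / ``"unavailable"``.  A missing raw field
    marks the factor unavailable for that participant and logs a warning;
    complete-case enforcement is a downstream concern.
    """
    cfg = config or LibraConfig()
    out = pd.DataFrame(index=table.index)

    def col(name: str) -> pd.Series:
        if name in table.columns:
            return table[name]
        return pd.Series(np.nan, index=table.index)

    def flag(name: str) -> pd.Series:
        return col(name).fillna(0).astype(bool)

    diet = col("diet_score")
    out["mediterranean_diet"] = _state(diet >= cfg.diet_score_min, diet.isna())

    alcohol = col("alcohol_g_week")
    if cfg.abstainers_protective:
        low_mod = alcohol < cfg.alcohol_max_g_week
    else:
        low_mod = (alcohol > 0) & (alcohol < cfg.alcohol_max_g_week)
    out["low_moderate_alcohol"] = _state(low_mod, alcohol.isna())

    mvpa = col("mvpa_min_week")
    out["physical_inactivity"] = _state(mvpa < cfg.mvpa_min_week, mvpa.isna())

    smoking = col("smoking_status")
    out["smoking"] = _state(smoking == "current", smoking.isna())

    bmi = col("bmi")
    out["obesity"] = _state(bmi >= cfg.bmi_obese, bmi.isna())

    sbp, dbp = col("sbp"), col("dbp")
    hyper = (sbp >= cfg.sbp_max) | (dbp >= cfg.dbp_max) | flag("antihypertensive_med")
    out["hypertension"] = _state(hyper, sbp.isna() & dbp.isna())

    chol = col("total_cholesterol")
    out["high_cholesterol"] = _state(chol >= cfg.cholesterol_max, chol.isna())

    # Glucose tolerance status, fasting / post-load glucose or current diabetes
    # medication; "other diabetes" status does not by itself count.
    status = col("glucose_status")
    fg, ogtt = col("fasting_glucose"), col("ogtt_glucose")
    t2dm = (
        (status == "t2dm")
        | (fg >= cfg.fasting_glucose_max)
        | (ogtt >= cfg.ogtt_glucose_max)
        | flag("diabetes_med")
    )
    out["type2_diabetes"] = _state(t2dm, status.isna() & fg.isna() & ogtt.isna())

    hd = col("heart_disease")  # self-reported history, stroke excluded upstream
    out["heart_disease"] = _state(hd.fillna(0).astype(bool), hd.isna())

    egfr = col("egfr")
    ckd = (egfr < cfg.egfr_min) | flag("albuminuria")
    out["chronic_kidney_disease"] = _state(ckd, egfr.isna() & col("albuminuria").isna())

    phq9 = col("phq9")
    depressed = flag("mini_depression") | (phq9 >= cfg.phq9_min)
    out["depression"] = _state(depressed, phq9.isna() & col("mini_depression").isna())

    out["cognitive_activity"] = UNAVAILABLE

    for factor in cfg.unavailable_factors:
        out[factor] = UNAVAILABLE

    n_missing = int((out == UNAVAILABLE).drop(columns=list(cfg.unavailable_factors)).sum().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} factor value(s) unavailable due to missing raw fields",
            stacklevel=2,
        )
    return out


def _state(present: pd.Series, missing: pd.Series) -> pd.Series:
    s = pd.Series(np.where(present.fillna(False), PRESENT, ABSENT), index=present.index)
    s[missing.fillna(True)] = UNAVAILABLE
    return s


def dichotomize_factors(record: Mapping | pd.Series, config: LibraConfig | None = None) -> dict[str, str]:
    """Dichotomise a single participant record; see :func:`dichotomize_cohort`."""
    row = pd.DataFrame([dict(record)])
    return dichotomize_cohort(row, config).iloc[0].to_dict()


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class LibraScoreResult:
    score: float
    tertile: int | None
    factors_used: list[str] = field(default_factory=list)


def compute_libra(
    profile: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> LibraScoreResult:
    """Weighted sum score over factors marked present.

    Absent and unavailable factors contribute 0; an all-unavailable profile is
    an error because no information supports any score.
    """
    w = dict(weights or DEFAULT_WEIGHTS)
    unknown = set(profile) - set(w)
    if unknown:
        raise ValueError(f"unknown LIBRA factors in profile: {sorted(unknown)}")
    used = [f for f in w if profile.get(f, UNAVAILABLE) != UNAVAILABLE]
    if not used:
        raise ValueError("all LIBRA factors are unavailable; score undefined")
    score = sum(w[f] for f in used if profile[f] == PRESENT)
    return LibraScoreResult(score=float(score), tertile=None, factors_used=used)


def compute_modified_libra(
    profile: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
    exclude: Sequence[str] = (),
) -> LibraScoreResult:
    """Score with the listed factors removed (treated as unavailable).

    Used for sensitivity analyses, e.g. excluding diabetes status from the
    score while adjusting for it separately.
    """
    w = dict(weights or DEFAULT_WEIGHTS)
    unknown = set(exclude) - set(w)
    if unknown:
        raise ValueError(f"cannot exclude unknown factors: {sorted(unknown)}")
    modified = {f: (UNAVAILABLE if f in exclude else s) for f, s in profile.items()}
    return compute_libra(modified, w)


def assign_tertiles(scores: Iterable[float]) -> np.ndarray:
    """Split scores into empirical tertiles 1/2/3 (1 = lowest risk).

    Cut-points are the empirical 1/3 and 2/3 quantiles taken at observed data
    values (lower interpolation); ties at a cut-point go to the lower tertile,
    so the observed tertile ranges are half-open from above.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("need at least three scores to form tertiles")
    if np.unique(arr[~np.isnan(arr)]).size < 3:
        raise ValueError("need at least three distinct score values to form tertiles")
    cut1, cut2 = np.nanquantile(arr, [1 / 3, 2 / 3], method="lower")
    tert = np.where(arr <= cut1, 1, np.where(arr <= cut2, 2, 3))
    return np.where(np.isnan(arr), -1, tert).astype(int)


def score_cohort(
    table: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    config: LibraConfig | None = None,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Dichotomise, score and tertile-split a whole cohort.

    Returns a frame with the factor indicator columns plus ``libra_score`` and
    ``libra_tertile``.
    """
    indicators = dichotomize_cohort(table, config)
    w = dict(weights or DEFAULT_WEIGHTS)
    for f in exclude:
        if f not in w:
            raise ValueError(f"cannot exclude unknown factor: {f}")
        indicators[f] = UNAVAILABLE
    present = (indicators[list(w)] == PRESENT).to_numpy(dtype=float)
    wvec = np.array([w[f] for f in w])
    out = indicators.copy()
    out["libra_score"] = present @ wvec
    out["libra_tertile"] = assign_tertiles(out["libra_score"])
    return out
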