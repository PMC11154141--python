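"""Whole-brain-volume brain-age modelling and brain-age-gap computation.

Brain age is predicted from a handful of whole-brain MRI scalars by ordinary
multivariable regression with calendar age as the outcome.  Model building
follows a three-step protocol:

1. candidate features are ranked by the strength (standardized beta) and
   significance (P <= 0.05) of their univariable association with age, with a
   quadratic term flagged where curvature is significant;
2. the top-ranked feature of each category (volumetric, vascular,
   connectivity) seeds a multivariable model from which non-significant terms
   are discarded (Model 1), and the remaining ranked features are then added
   step-wise (Model 2);
3. a LASSO over main effects, flagged quadratics and all pairwise
   interactions, with the penalty chosen by 10-fold cross-validation and the
   1-SE rule, yields a data-driven Model 3 (refit by OLS on the surviving
   terms to remove shrinkage bias).

The most parsimonious model within a small R^2 tolerance of the best is
selected, and each participant's brain-age gap is

    BAG = predicted brain age - calendar age,

positive values indicating an older-looking brain.  On the training sample
mean BAG is exactly zero and, whenever R^2 < 1, BAG correlates negatively
with calendar age (regression to the mean): downstream models using BAG must
therefore adjust for age, which the mediation stage does by covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "FEATURE_CATEGORIES",
    "CandidateTerm",
    "BrainAgeModelFit",
    "BagResult",
    "preprocess_features",
    "rank_candidates",
    "build_stepwise_models",
    "fit_lasso_model",
    "compare_models",
    "compute_bag",
]

#: Category membership used when seeding Model 1.
FEATURE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "volumetric": ("csf", "gm", "wm", "log_wmh"),
    "vascular": ("cmb_presence", "infarct_presence"),
    "connectivity": ("node_degree",),
}


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return np.zeros_like(x, dtype=float), mu, 0.0
    return (x - mu) / sd, mu, sd


def preprocess_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the standardized brain feature set from raw MRI scalars.

    WMH volume is log-transformed as ln(WMH + 1 mL) to tolerate zero lesion
    load, then standardized together with the CSF/GM/WM volumes (sample SD,
    n-1 denominator).  Microbleed and lacunar-infarct counts are dichotomised
    to presence.  Node degree is standardized like the volumes.  Total
    intracranial volume (sum of the four volumes, in mL) is retained
    unstandardized for reference.
    """
    required = ["csf_ml", "gm_ml", "wm_ml", "wmh_ml"]
    for colname in required:
        vals = cohort[colname].to_numpy(dtype=float)
        bad = np.flatnonzero(vals < 0 if colname == "wmh_ml" else vals <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive {colname} at row index {cohort.index[bad[0]]!r}"
            )
    out = pd.DataFrame(index=cohort.index)
    for name, colname in (("csf", "csf_ml"), ("gm", "gm_ml"), ("wm", "wm_ml")):
        z, _, sd = _zscore(cohort[colname].to_numpy(dtype=float))
        if sd == 0:
            warnings.warn(f"constant column {colname}; standardized to zeros", stacklevel=2)
        out[name] = z
    z, _, sd = _zscore(np.log1p(cohort["wmh_ml"].to_numpy(dtype=float)))
    if sd == 0:
        warnings.warn("constant column wmh_ml; standardized to zeros", stacklevel=2)
    out["log_wmh"] = z
    out["cmb_presence"] = (cohort["cmb_count"].to_numpy() >= 1).astype(float)
    out["infarct_presence"] = (cohort["lacunar_infarct_count"].to_numpy() >= 1).astype(float)
    out["node_degree"], _, _ = _zscore(cohort["node_degree"].to_numpy(dtype=float))
    out["tiv_ml"] = (
        cohort["csf_ml"] + cohort["gm_ml"] + cohort["wm_ml"] + cohort["wmh_ml"]
    ).to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# small OLS helper (classical normal-theory inference)
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray):
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return coef, se, pvals, resid, cov


@dataclass
class CandidateTerm:
    feature: str
    beta_std: float
    p_value: float
    quadratic: bool
    category: str | None = None


def rank_candidates(
    features: pd.DataFrame,
    age: Sequence[float],
    alpha: float = 0.05,
    quad_alpha: float = 0.05,
) -> list[CandidateTerm]:
    """Rank features by |standardized beta| from univariable age regressions.

    Each feature is regressed on age separately (age as outcome); features
    whose linear P exceeds ``alpha`` are excluded from the ranking.  A feature
    is additionally flagged for a quadratic term when adding its square to the
    univariable model yields a significant curvature coefficient.  Constant
    features are skipped with a warning.  The ranking is invariant to affine
    rescaling of any feature.
    """
    y = np.asarray(age, dtype=float)
    zy, _, sdy = _zscore(y)
    if sdy == 0:
        raise ValueError("age is constant")
    terms: list[CandidateTerm] = []
    cat_of = {f: c for c, fs in FEATURE_CATEGORIES.items() for f in fs}
    for name in features.columns:
        if name == "tiv_ml":
            continue
        x = features[name].to_numpy(dtype=float)
        zx, _, sdx = _zscore(x)
        if sdx == 0:
            warnings.warn(f"constant feature {name} skipped in ranking", stacklevel=2)
            continue
        X = np.column_stack([np.ones_like(zx), zx])
        coef, _, pvals, _, _ = _ols(zy, X)
        beta, p_lin = float(coef[1]), float(pvals[1])
        Xq = np.column_stack([X, zx**2])
        try:
            _, _, pq, _, _ = _ols(zy, Xq)
            quad = bool(pq[2] < quad_alpha)
        except np.linalg.LinAlgError:  # e.g. binary feature: square collinear
            quad = False
        if p_lin <= alpha:
            terms.append(CandidateTerm(name, beta, p_lin, quad, cat_of.get(name)))
    terms.sort(key=lambda t: -abs(t.beta_std))
    return terms


@dataclass
class BrainAgeModelFit:
    """A fitted brain-age regression: terms, age-scale coefficients, fit metrics."""

    label: str
    terms: list[str]                    # design column names, intercept excluded
    coefficients: dict[str, float]      # includes "intercept"
    r2: float
    rmse: float
    n: int
    p_value: float = np.nan             # model F-test
    term_p_values: dict[str, float] = field(default_factory=dict)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "terms": self.terms,
            "coefficients": self.coefficients,
            "r2": self.r2,
            "rmse": self.rmse,
            "n": self.n,
            "p_value": self.p_value,
        }


def _design(features: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(features))]
    for t in terms:
        if t.endswith("^2"):
            base = t[:-2]
            cols.append(features[base].to_numpy(dtype=float) ** 2)
        elif ":" in t:
            a, b = t.split(":")
            cols.append(features[a].to_numpy(dtype=float) * features[b].to_numpy(dtype=float))
        else:
            cols.append(features[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _fit(label: str, terms: list[str], features: pd.DataFrame, y: np.ndarray) -> BrainAgeModelFit:
    X = _design(features, terms)
    coef, _, pvals, resid, _ = _ols(y, X)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else np.nan
    rmse = float(np.sqrt(rss / len(y)))
    n, p = X.shape
    if p > 1 and rss > 0:
        fstat = ((tss - rss) / (p - 1)) / (rss / (n - p))
        p_model = float(stats.f.sf(fstat, p - 1, n - p))
    else:
        p_model = 0.0 if rss == 0 else np.nan
    names = ["intercept"] + list(terms)
    return BrainAgeModelFit(
        label=label,
        terms=list(terms),
        coefficients=dict(zip(names, map(float, coef))),
        r2=float(r2),
        rmse=rmse,
        n=n,
        p_value=p_model,
        term_p_values=dict(zip(terms, map(float, pvals[1:]))),
    )


def _terms_for(t: CandidateTerm) -> list[str]:
    return [t.feature, f"{t.feature}^2"] if t.quadratic else [t.feature]


def _prune(terms: list[str], features: pd.DataFrame, y: np.ndarray, alpha: float) -> list[str]:
    """Backward-eliminate non-significant terms, respecting base/square hierarchy."""
    terms = list(terms)
    while True:
        fit = _fit("tmp", terms, features, y)
        droppable = [
            t for t in terms
            if fit.term_p_values[t] > alpha and f"{t}^2" not in terms  # keep base under its square
        ]
        if not droppable:
            return terms
        worst = max(droppable, key=lambda t: fit.term_p_values[t])
        terms.remove(worst)
        if not terms:
            raise ValueError("no significant feature remains after pruning")


def build_stepwise_models(
    ranking: Sequence[CandidateTerm],
    features: pd.DataFrame,
    age: Sequence[float],
    alpha: float = 0.05,
) -> list[BrainAgeModelFit]:
    """Construct Models 1 and 2 by seeded-then-stepwise term selection.

    Model 1 combines the top-ranked feature of each category (with its flagged
    quadratic) and discards non-significant terms.  Model 2 then adds the
    remaining ranked features one at a time in ranking order, retaining each
    only while significant, followed by a final pruning pass.
    """
    if not ranking:
        raise ValueError("empty candidate ranking")
    y = np.asarray(age, dtype=float)

    seeds: list[CandidateTerm] = []
    seen_cat: set[str | None] = set()
    for t in ranking:  # ranking is |beta|-ordered, so first hit per category wins
        if t.category not in seen_cat:
            seeds.append(t)
            seen_cat.add(t.category)
    seed_terms = [x for t in seeds for x in _terms_for(t)]
    model1_terms = _prune(seed_terms, features, y, alpha)
    model1 = _fit("Model 1", model1_terms, features, y)

    terms = list(model1_terms)
    for t in ranking:
        if t in seeds or t.feature in terms:
            continue
        trial = terms + _terms_for(t)
        fit = _fit("tmp", trial, features, y)
        added = [x for x in _terms_for(t) if fit.term_p_values[x] <= alpha]
        if f"{t.feature}^2" in added and t.feature not in added:
            added = [t.feature, f"{t.feature}^2"]
        terms += added
    model2_terms = _prune(terms, features, y, alpha)
    model2 = _fit("Model 2", model2_terms, features, y)
    return [model1, model2]


def fit_lasso_model(
    features: pd.DataFrame,
    age: Sequence[float],
    main_effects: Sequence[str],
    quadratics: Sequence[str] = (),
    lambda_grid: Sequence[float] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    label: str = "Model 3",
) -> BrainAgeModelFit:
    """Data-driven model: L1-penalised selection over mains, quadratics and
    pairwise interactions, cross-validated penalty (1-SE rule), OLS refit.

    The design uses the standardized main effects plus squares and products of
    them (not re-standardized, so term meanings stay interpretable).  In the
    limit of zero penalty the surviving set is the full design and the refit
    equals ordinary least squares; at very large penalties all slopes vanish
    and the model falls back to the smallest penalty retaining one term.
    """
    y = np.asarray(age, dtype=float)
    terms = list(main_effects) + [f"{q}^2" for q in quadratics]
    mains = list(main_effects)
    for i, a in enumerate(mains):
        for b in mains[i + 1:]:
            terms.append(f"{a}:{b}")
    X = _design(features, terms)[:, 1:]  # Lasso centers internally via fit_intercept
    if lambda_grid is None:
        # data-driven grid down from the smallest penalty that zeroes everything
        lam_max = float(np.max(np.abs((X - X.mean(0)).T @ (y - y.mean())))) / len(y)
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, 40)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mse = np.zeros((len(lambda_grid), n_folds))
    for j, (tr, te) in enumerate(kf.split(X)):
        for i, lam in enumerate(lambda_grid):
            model = Lasso(alpha=lam, max_iter=50_000)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            mse[i, j] = float(np.mean((y[te] - pred) ** 2))
    mean_mse = mse.mean(axis=1)
    se_mse = mse.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_mse))
    threshold = mean_mse[best] + se_mse[best]
    # largest penalty (first index in the descending grid) within one SE of the best
    chosen = int(np.flatnonzero(mean_mse <= threshold)[0])

    final = Lasso(alpha=float(lambda_grid[chosen]), max_iter=50_000)
    final.fit(X, y)
    survivors = [t for t, c in zip(terms, final.coef_) if abs(c) > 1e-10]
    if not survivors:
        warnings.warn("no survivor at the 1-SE penalty; falling back", stacklevel=2)
        for lam in lambda_grid[chosen:]:
            final = Lasso(alpha=float(lam), max_iter=50_000)
            final.fit(X, y)
            survivors = [t for t, c in zip(terms, final.coef_) if abs(c) > 1e-10]
            if survivors:
                break
        else:
            raise ValueError("no penalty in the grid retains any term")
    return _fit(label, survivors, features, y)


def compare_models(
    fits: Sequence[BrainAgeModelFit], r2_tolerance: float = 0.01
) -> BrainAgeModelFit:
    """Select the most parsimonious model within ``r2_tolerance`` of the best R^2."""
    if not fits:
        raise ValueError("no fits to compare")
    if len(fits) == 1:
        return fits[0]
    best_r2 = max(f.r2 for f in fits)
    eligible = [f for f in fits if f.r2 >= best_r2 - r2_tolerance]
    return min(eligible, key=lambda f: f.n_terms)


@dataclass
class BagResult:
    predicted_age: np.ndarray
    bag: np.ndarray
    bag_age_correlation: float  # regression-to-the-mean diagnostic

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {"predicted_age": self.predicted_age, "bag": self.bag}, index=index
        )


def compute_bag(
    fit: BrainAgeModelFit, features: pd.DataFrame, age: Sequence[float]
) -> BagResult:
    """Predicted brain age and gap (predicted - calendar) for each participant.

    On the model's own training sample the mean gap is zero by least-squares
    construction, and the gap correlates negatively with calendar age whenever
    R^2 < 1 — younger participants are predicted too old and vice versa.  The
    correlation is returned as a diagnostic; adjust for age downstream.
    """
    base = {t.split(":")[0].removesuffix("^2") for t in fit.terms} | {
        t.split(":")[-1] for t in fit.terms if ":" in t
    }
    missing = base - set(features.columns)
    if missing:
        raise ValueError(f"features missing model columns: {sorted(missing)}")
    X = _design(features, fit.terms)
    coef = np.array([fit.coefficients["intercept"]] + [fit.coefficients[t] for t in fit.terms])
    predicted = X @ coef
    y = np.asarray(age, dtype=float)
    bag = predicted - y
    if np.std(bag) > 0 and np.std(y) > 0:
        corr = float(np.corrcoef(bag, y)[0, 1])
    else:
        corr = 0.0
    return BagResult(predicted_age=predicted, bag=bag, bag_age_correlation=corr)
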