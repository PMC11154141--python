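"""Linear path analysis with serial two-mediator effect decomposition.

The engine fits a recursive linear path system by per-equation least squares
on standardized endogenous variables — numerically identical, for this class
of model, to maximum-likelihood structural equation modelling — and
decomposes the exposure→outcome association by path tracing:

    M1 = a * X            + covariates
    M2 = a2 * X + d21 * M1 + covariates
    Y  = c' * X + b1 * M1 + b2 * M2 + covariates

    indirect via M1       = a  * b1
    indirect via M2       = a2 * b2
    indirect via M1 -> M2 = a  * d21 * b2
    total                 = c' + sum of indirect components

Because every equation shares the exposure and covariate set, the total
effect recovered from the reduced-form regression of Y on X equals the sum of
the direct and indirect components *exactly* (an algebraic identity of least
squares), which the test-suite asserts to 1e-10.

Exposure handling follows common epidemiological reporting: a categorical
exposure (risk-score tertiles, reference = tertile 1) enters as 0/1 dummies
while mediators and outcome are standardized, so coefficients are
y-standardized per-tertile contrasts; a continuous exposure is standardized,
giving fully standardized coefficients.

Inference is first-order delta method on products of coefficients
(multivariate Sobel) with equation-level covariances treated as independent
across equations, or nonparametric bootstrap percentile intervals.  The
proportion mediated (PM) is indirect/total within the fitted model; an
external total may be supplied to reproduce ratios quoted against a different
model's total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathModelSpec",
    "PathEdge",
    "PathSystemFit",
    "EffectEstimate",
    "EffectDecomposition",
    "InteractionTest",
    "standardize_variables",
    "fit_path_system",
    "decompose_serial",
    "proportion_mediated",
    "delta_method_inference",
    "bootstrap_inference",
    "fit_adjusted_regressions",
    "test_group_interaction",
]


# ---------------------------------------------------------------------------
# specification & helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathModelSpec:
    """Variables and roles of a (serial) mediation model.

    ``exposure_type`` is ``"continuous"`` (standardized) or ``"tertile"``
    (values 1/2/3; dummies for 2 and 3 against reference tertile 1).
    Mediator order is causal and fixed: mediator i may affect mediator j>i,
    never the reverse.
    """

    exposure: str
    outcome: str
    mediators: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    exposure_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.exposure_type not in ("continuous", "tertile"):
            raise ValueError("exposure_type must be 'continuous' or 'tertile'")
        if not 1 <= len(self.mediators) <= 2:
            raise ValueError("one or two ordered mediators are supported")
        roles = [self.exposure, self.outcome, *self.mediators, *self.covariates]
        if len(set(roles)) != len(roles):
            raise ValueError("exposure, outcome, mediators and covariates must be distinct")


def standardize_variables(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Return a copy with the listed columns z-scored (mean 0, SD 1, n-1).

    Idempotent on already-standardized input; constant columns are an error
    because a standardized scale is undefined for them.
    """
    out = table.copy()
    for v in variables:
        x = out[v].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant variable {v!r}")
        out[v] = (x - np.nanmean(x)) / sd
    return out


def _expand_covariates(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals become 0/1 dummies."""
    cols = {}
    for c in covariates:
        s = table[c]
        if pd.api.types.is_numeric_dtype(s):
            cols[c] = s.to_numpy(dtype=float)
        else:
            levels = sorted(pd.unique(s.dropna()))
            for lev in levels[1:]:  # first level is reference
                cols[f"{c}[{lev}]"] = (s == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.index)


def _exposure_columns(table: pd.DataFrame, spec: PathModelSpec) -> pd.DataFrame:
    s = table[spec.exposure]
    if spec.exposure_type == "continuous":
        x = s.to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("constant exposure")
        return pd.DataFrame({spec.exposure: (x - x.mean()) / sd}, index=table.index)
    vals = set(pd.unique(s.dropna()))
    if not vals <= {1, 2, 3}:
        raise ValueError("tertile exposure must take values in {1, 2, 3}")
    return pd.DataFrame(
        {
            f"{spec.exposure}[T2]": (s == 2).to_numpy(dtype=float),
            f"{spec.exposure}[T3]": (s == 3).to_numpy(dtype=float),
        },
        index=table.index,
    )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        d = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(d < d.max() * 1e-10)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _ols_normal(y: np.ndarray, X: np.ndarray, names: Sequence[str]):
    """OLS with classical covariance; z and P from the standard normal."""
    _check_rank(X, names)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few complete cases for the number of parameters")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, cov


@dataclass
class PathEdge:
    source: str
    target: str
    beta: float
    se: float

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.nan

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.z)))


@dataclass
class _Equation:
    outcome: str
    names: list[str]          # design column names, intercept first
    coef: np.ndarray
    cov: np.ndarray

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class PathSystemFit:
    """Fitted recursive path system with per-edge inference."""

    spec: PathModelSpec
    exposure_terms: list[str]
    equations: dict[str, _Equation]   # keyed by endogenous variable; plus "__total__"
    edges: dict[tuple[str, str], PathEdge]
    n: int

    def edge(self, source: str, target: str) -> PathEdge:
        return self.edges[(source, target)]

    def total_effect(self, term: str) -> float:
        eq = self.equations["__total__"]
        return float(eq.coef[eq.index(term)])


def fit_path_system(spec: PathModelSpec, table: pd.DataFrame) -> PathSystemFit:
    """Fit one least-squares equation per endogenous variable.

    Complete cases only (rows with any missing spec variable are dropped).
    Mediators and outcome are standardized on the analytic sample; covariate
    dummies and tertile dummies stay 0/1.  Also fits the reduced-form
    (total-effect) equation of the outcome on exposure and covariates.
    """
    used = [spec.exposure, *spec.mediators, spec.outcome, *spec.covariates]
    data = table[used].dropna()
    data = standardize_variables(data, [*spec.mediators, spec.outcome])
    expo = _exposure_columns(data, spec)
    cov = _expand_covariates(data, spec.covariates)
    n = len(data)

    equations: dict[str, _Equation] = {}
    edges: dict[tuple[str, str], PathEdge] = {}

    def fit_eq(key: str, yname: str, predictors: pd.DataFrame) -> _Equation:
        names = ["intercept", *predictors.columns]
        X = np.column_stack([np.ones(n), predictors.to_numpy(dtype=float)])
        coef, covm = _ols_normal(data[yname].to_numpy(dtype=float), X, names)
        eq = _Equation(yname, names, coef, covm)
        equations[key] = eq
        return eq

    for j, m in enumerate(spec.mediators):
        preds = pd.concat([expo, data[list(spec.mediators[:j])], cov], axis=1)
        eq = fit_eq(m, m, preds)
        for src in [*expo.columns, *spec.mediators[:j]]:
            i = eq.index(src)
            edges[(src, m)] = PathEdge(src, m, float(eq.coef[i]), float(np.sqrt(eq.cov[i, i])))
    preds = pd.concat([expo, data[list(spec.mediators)], cov], axis=1)
    eq = fit_eq(spec.outcome, spec.outcome, preds)
    for src in [*expo.columns, *spec.mediators]:
        i = eq.index(src)
        edges[(src, spec.outcome)] = PathEdge(
            src, spec.outcome, float(eq.coef[i]), float(np.sqrt(eq.cov[i, i]))
        )
    fit_eq("__total__", spec.outcome, pd.concat([expo, cov], axis=1))

    return PathSystemFit(
        spec=spec,
        exposure_terms=list(expo.columns),
        equations=equations,
        edges=edges,
        n=n,
    )


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    estimate: float
    se: float = np.nan

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se and self.se > 0 else np.nan

    @property
    def p(self) -> float:
        z = self.z
        return float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan


@dataclass
class EffectDecomposition:
    """Total/direct/indirect decomposition for one exposure contrast."""

    exposure_term: str
    total: EffectEstimate
    direct: EffectEstimate
    indirect: dict[str, EffectEstimate]       # per pathway
    total_indirect: EffectEstimate
    proportion_mediated: dict[str, float]     # per pathway, percent
    proportion_mediated_overall: float        # percent

    def to_dict(self) -> dict:
        def rec(e: EffectEstimate) -> dict:
            return {"estimate": e.estimate, "se": e.se, "z": e.z, "p": e.p}

        return {
            "exposure_term": self.exposure_term,
            "total": rec(self.total),
            "direct": rec(self.direct),
            "indirect": {k: rec(v) for k, v in self.indirect.items()},
            "total_indirect": rec(self.total_indirect),
            "proportion_mediated_pct": self.proportion_mediated,
            "proportion_mediated_overall_pct": self.proportion_mediated_overall,
        }


def proportion_mediated(indirect: float, total: float) -> float:
    """Indirect effect as a percentage of the total effect.

    A zero total leaves the ratio undefined (NaN, with a warning) rather than
    +/-inf; opposite-signed components ("inconsistent mediation") return a
    negative percentage with a warning.
    """
    if total == 0:
        warnings.warn("total effect is zero; proportion mediated undefined", stacklevel=2)
        return np.nan
    pm = 100.0 * indirect / total
    if pm < 0:
        warnings.warn(
            "indirect and total effects have opposite signs (inconsistent mediation)",
            stacklevel=2,
        )
    return pm


def _paths_for_term(fit: PathSystemFit, term: str) -> dict[str, list[list[tuple[str, str]]]]:
    """Directed exposure->outcome paths, keyed by pathway label.

    Each path is a list of (equation key, design column) coefficient lookups
    whose product is the path contribution.
    """
    spec = fit.spec
    y = spec.outcome
    med = spec.mediators
    paths: dict[str, list[list[tuple[str, str]]]] = {
        "direct": [[(y, term)]],
        f"via_{med[0]}": [[(med[0], term), (y, med[0])]],
    }
    if len(med) == 2:
        m1, m2 = med
        paths[f"via_{m2}"] = [[(m2, term), (y, m2)]]
        paths[f"via_{m1}_{m2}"] = [[(m1, term), (m2, m1), (y, m2)]]
    return paths


def _component_value_and_grad(
    fit: PathSystemFit, pathways: list[list[tuple[str, str]]]
) -> tuple[float, dict[tuple[str, str], float]]:
    value = 0.0
    grad: dict[tuple[str, str], float] = {}
    for path in pathways:
        coefs = [float(fit.equations[eq].coef[fit.equations[eq].index(nm)]) for eq, nm in path]
        prod = float(np.prod(coefs))
        value += prod
        for k, key in enumerate(path):
            others = prod / coefs[k] if coefs[k] != 0 else float(
                np.prod([c for i, c in enumerate(coefs) if i != k])
            )
            grad[key] = grad.get(key, 0.0) + others
    return value, grad


def _delta_se(fit: PathSystemFit, grad: Mapping[tuple[str, str], float]) -> float:
    """SE of a (sum of) coefficient product(s) under block-diagonal covariance.

    Parameters from the same equation use that equation's full covariance;
    parameters from different equations are treated as independent (the
    standard multivariate-Sobel assumption for recursive systems).
    """
    var = 0.0
    by_eq: dict[str, list[tuple[str, float]]] = {}
    for (eqk, nm), g in grad.items():
        by_eq.setdefault(eqk, []).append((nm, g))
    for eqk, items in by_eq.items():
        eq = fit.equations[eqk]
        idx = [eq.index(nm) for nm, _ in items]
        g = np.array([gv for _, gv in items])
        sub = eq.cov[np.ix_(idx, idx)]
        var += float(g @ sub @ g)
    return float(np.sqrt(var))


def decompose_serial(
    fit: PathSystemFit,
    external_total: float | None = None,
) -> dict[str, EffectDecomposition]:
    """Decompose the exposure effect per exposure term (delta-method inference).

    ``external_total`` substitutes the PM denominator (the printed ratios in
    some reports divide by a different model's total); the decomposition's own
    additivity identity is unaffected.
    """
    out: dict[str, EffectDecomposition] = {}
    for term in fit.exposure_terms:
        paths = _paths_for_term(fit, term)
        comps: dict[str, EffectEstimate] = {}
        for label, pw in paths.items():
            val, grad = _component_value_and_grad(fit, pw)
            comps[label] = EffectEstimate(val, _delta_se(fit, grad))
        indirect_labels = [k for k in paths if k != "direct"]
        ind_paths = [p for k in indirect_labels for p in paths[k]]
        ti_val, ti_grad = _component_value_and_grad(fit, ind_paths)
        total_paths = ind_paths + paths["direct"]
        tot_val, tot_grad = _component_value_and_grad(fit, total_paths)
        denom = external_total if external_total is not None else tot_val
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm = {k: proportion_mediated(comps[k].estimate, denom) for k in indirect_labels}
            pm_overall = proportion_mediated(ti_val, denom)
        out[term] = EffectDecomposition(
            exposure_term=term,
            total=EffectEstimate(tot_val, _delta_se(fit, tot_grad)),
            direct=comps["direct"],
            indirect={k: comps[k] for k in indirect_labels},
            total_indirect=EffectEstimate(ti_val, _delta_se(fit, ti_grad)),
            proportion_mediated=pm,
            proportion_mediated_overall=pm_overall,
        )
    return out


def delta_method_inference(
    fit: PathSystemFit,
) -> dict[str, dict[str, tuple[float, float, float, float]]]:
    """(estimate, SE, z, P) per decomposition component and exposure term."""
    res: dict[str, dict[str, tuple[float, float, float, float]]] = {}
    for term, dec in decompose_serial(fit).items():
        rows = {"total": dec.total, "direct": dec.direct, "total_indirect": dec.total_indirect}
        rows.update(dec.indirect)
        res[term] = {k: (e.estimate, e.se, e.z, e.p) for k, e in rows.items()}
    return res


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class _FastPathData:
    """Pre-extracted numpy arrays for rapid refitting under resampling.

    Dummy expansions are computed once on the complete-case sample; only
    standardization and the least-squares solves are redone per resample.
    """

    def __init__(self, spec: PathModelSpec, table: pd.DataFrame) -> None:
        used = [spec.exposure, *spec.mediators, spec.outcome, *spec.covariates]
        data = table[used].dropna().reset_index(drop=True)
        self.spec = spec
        self.n = len(data)
        self.expo = _exposure_columns(data, spec)  # standardized if continuous
        self.expo_names = list(self.expo.columns)
        self.expo_raw = (
            data[spec.exposure].to_numpy(dtype=float)[:, None]
            if spec.exposure_type == "continuous"
            else self.expo.to_numpy(dtype=float)
        )
        self.med = data[list(spec.mediators)].to_numpy(dtype=float)
        self.y = data[spec.outcome].to_numpy(dtype=float)
        self.cov = _expand_covariates(data, spec.covariates).to_numpy(dtype=float)

    def components(self, idx: np.ndarray | None = None) -> dict[str, float]:
        """Decomposition components on the (re)sampled rows."""
        sl = slice(None) if idx is None else idx
        expo = self.expo_raw[sl]
        if self.spec.exposure_type == "continuous":
            sd = expo.std(ddof=1)
            if sd == 0:
                raise np.linalg.LinAlgError("constant exposure in resample")
            expo = (expo - expo.mean()) / sd
        med = self.med[sl]
        y = self.y[sl]
        cov = self.cov[sl]
        n = len(y)

        def std(v: np.ndarray) -> np.ndarray:
            s = v.std(ddof=1)
            if s == 0:
                raise np.linalg.LinAlgError("constant endogenous variable in resample")
            return (v - v.mean()) / s

        med = np.column_stack([std(med[:, j]) for j in range(med.shape[1])])
        y = std(y)
        ones = np.ones((n, 1))

        def solve(yv: np.ndarray, X: np.ndarray) -> np.ndarray:
            xtx = X.T @ X
            cond = np.linalg.cond(xtx)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError("degenerate design in resample")
            return np.linalg.solve(xtx, X.T @ yv)

        k_e = expo.shape[1]
        m = med.shape[1]
        a = np.empty((m, k_e))
        d21 = 0.0
        for j in range(m):
            X = np.hstack([ones, expo, med[:, :j], cov])
            cj = solve(med[:, j], X)
            a[j] = cj[1 : 1 + k_e]
            if j == 1:
                d21 = float(cj[1 + k_e])
        X = np.hstack([ones, expo, med, cov])
        cy = solve(y, X)
        direct = cy[1 : 1 + k_e]
        b = cy[1 + k_e : 1 + k_e + m]

        out: dict[str, float] = {}
        for e, term in enumerate(self.expo_names):
            ind = {f"via_{self.spec.mediators[0]}": float(a[0, e] * b[0])}
            if m == 2:
                ind[f"via_{self.spec.mediators[1]}"] = float(a[1, e] * b[1])
                ind[f"via_{self.spec.mediators[0]}_{self.spec.mediators[1]}"] = float(
                    a[0, e] * d21 * b[1]
                )
            ti = sum(ind.values())
            out[f"direct[{term}]"] = float(direct[e])
            out[f"total_indirect[{term}]"] = ti
            out[f"total[{term}]"] = float(direct[e]) + ti
            for k, v in ind.items():
                out[f"{k}[{term}]"] = v
        return out


def bootstrap_inference(
    spec: PathModelSpec,
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Nonparametric percentile bootstrap for every decomposition component.

    Rows are resampled with replacement; standardization and the full path
    system are re-estimated within each resample.  Resamples with a
    degenerate design (e.g. a constant dummy) are skipped and counted.
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    fast = _FastPathData(spec, table)
    rng = np.random.default_rng(seed)

    point = fast.components()
    draws: dict[str, list[float]] = {k: [] for k in point}
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, fast.n, fast.n)
        try:
            comp = fast.components(idx)
        except np.linalg.LinAlgError:
            skipped += 1
            continue
        for k, v in comp.items():
            draws[k].append(v)
    alpha = (1 - ci_level) / 2
    cis = {
        k: (
            point[k],
            float(np.quantile(v, alpha)) if v else np.nan,
            float(np.quantile(v, 1 - alpha)) if v else np.nan,
        )
        for k, v in draws.items()
    }
    return {"components": cis, "n_boot": n_boot, "n_skipped": skipped, "ci_level": ci_level}


def _component_table(fit: PathSystemFit) -> dict[str, float]:
    comp: dict[str, float] = {}
    for term, dec in decompose_serial(fit).items():
        comp[f"total[{term}]"] = dec.total.estimate
        comp[f"direct[{term}]"] = dec.direct.estimate
        comp[f"total_indirect[{term}]"] = dec.total_indirect.estimate
        for k, e in dec.indirect.items():
            comp[f"{k}[{term}]"] = e.estimate
    return comp


# ---------------------------------------------------------------------------
# covariate-adjusted regressions & interaction tests
# ---------------------------------------------------------------------------

def fit_adjusted_regressions(
    table: pd.DataFrame,
    lifestyle: str = "libra_score",
    bag: str = "bag",
    cognition: str = "cognition",
    covariates: Sequence[str] = ("age", "sex", "education", "glucose_status"),
) -> dict[str, dict[str, PathEdge]]:
    """The three covariate-adjusted regressions preceding the path system.

    1. lifestyle -> brain-age gap,
    2. brain-age gap -> cognition,
    3. lifestyle (+ its square) -> cognition (curvilinearity check),

    each with standardized continuous variables, so coefficients are
    standardized betas.  The quadratic term is the square of the standardized
    lifestyle score (not re-standardized).
    """
    out: dict[str, dict[str, PathEdge]] = {}
    cov = _expand_covariates(table, covariates)

    def run(label: str, yname: str, xdef: dict[str, np.ndarray]) -> None:
        cols = {**xdef, **{c: cov[c].to_numpy() for c in cov.columns}}
        frame = pd.DataFrame(cols, index=table.index)
        y = table[yname].to_numpy(dtype=float)
        mask = np.isfinite(y) & np.isfinite(frame.to_numpy(dtype=float)).all(axis=1)
        ys = y[mask]
        ys = (ys - ys.mean()) / ys.std(ddof=1)
        names = ["intercept", *frame.columns]
        X = np.column_stack([np.ones(mask.sum()), frame.to_numpy(dtype=float)[mask]])
        coef, covm = _ols_normal(ys, X, names)
        out[label] = {
            nm: PathEdge(nm, yname, float(coef[i]), float(np.sqrt(covm[i, i])))
            for i, nm in enumerate(names)
            if nm in xdef
        }

    def z(colname: str) -> np.ndarray:
        x = table[colname].to_numpy(dtype=float)
        m, s = np.nanmean(x), np.nanstd(x, ddof=1)
        return (x - m) / s

    zl = z(lifestyle)
    run("lifestyle_to_bag", bag, {lifestyle: zl})
    run("bag_to_cognition", cognition, {bag: z(bag)})
    run("lifestyle_to_cognition", cognition, {lifestyle: zl, f"{lifestyle}^2": zl**2})
    return out


@dataclass
class InteractionTest:
    group: str
    chi2: float
    df: int
    p: float


def test_group_interaction(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    group: str,
    covariates: Sequence[str] = (),
    exposure_type: str = "continuous",
) -> InteractionTest:
    """Wald chi-square test of exposure-by-group effect modification.

    Fits ``outcome ~ exposure * group + covariates`` (outcome standardized)
    and tests the block of exposure-by-group product terms; df equals the
    number of product terms.  Multi-level groups are supported via dummies.
    """
    used = [outcome, exposure, group, *covariates]
    data = table[used].dropna()
    g = data[group]
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ValueError(f"group variable {group!r} is constant")

    data = standardize_variables(data, [outcome])
    expo = _exposure_columns(data, _SimpleSpec(exposure, exposure_type))
    gdum = pd.DataFrame(
        {f"{group}[{lev}]": (g == lev).to_numpy(dtype=float) for lev in levels[1:]},
        index=data.index,
    )
    inter = pd.DataFrame(
        {
            f"{e}:{gc}": expo[e].to_numpy() * gdum[gc].to_numpy()
            for e in expo.columns
            for gc in gdum.columns
        },
        index=data.index,
    )
    cov = _expand_covariates(data, covariates)
    design = pd.concat([expo, gdum, inter, cov], axis=1)
    names = ["intercept", *design.columns]
    X = np.column_stack([np.ones(len(data)), design.to_numpy(dtype=float)])
    coef, covm = _ols_normal(data[outcome].to_numpy(dtype=float), X, names)
    idx = [names.index(c) for c in inter.columns]
    b = coef[idx]
    V = covm[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return InteractionTest(group=group, chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


class _SimpleSpec:
    """Duck-typed minimal spec for exposure-column construction."""

    def __init__(self, exposure: str, exposure_type: str) -> None:
        self.exposure = exposure
        self.exposure_type = exposure_type
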