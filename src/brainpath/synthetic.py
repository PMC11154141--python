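"""Synthetic cohort generator for the lifestyle → brain → cognition pipeline.

Real deep-phenotyping cohorts with MRI are not publicly redistributable, so the
package ships a generator that emulates the *statistical structure* the
analysis assumes: a middle-aged population (40-75 y) with an oversampling of
type 2 diabetes, eleven raw lifestyle/health measurements that dichotomise
into LIBRA factors, whole-brain MRI scalars with realistic age trends, a
whole-brain connectivity scalar, and three cognitive-domain z-scores.

The generative model is linear-Gaussian on standardized latents::

    risk   r  = w_age * z(age) + noise                 (age-linked latent risk)
    factors   ~ Bernoulli(sigmoid(logit(p_k) +/- r))   (conditionally independent)
    L* = standardized LIBRA weighted sum of the factors
    B  = c_LB * L* + noise                             (brain-age substrate, SD 1)
    A* = age + s * B                                   (effective brain age, years)
    volumes, CMB, WMH = smooth functions of A* + measurement noise
    C  = c_LC * L* + c_BC * B + noise                  (connectivity, SD 1)
    G  = c_dir * L* + c_BG * B + c_CG * C + noise      (latent cognition, SD 1)
    domain z-scores = 0.92 * G + domain noise, re-standardized

so every standardized structural coefficient injected through
``path_coefficients`` is exactly known, and the mediation estimands can be
verified against ground truth.  The substrate scale ``s`` (11 years) and the
small volume measurement noise are chosen so that a whole-brain-volume age
model reaches R^2 ~ 0.45 and its residual is dominated by ``B`` — i.e. the
fitted brain-age gap is a nearly unattenuated proxy of the substrate.

Cognition carries no direct age effect by default, so that a configuration
with all structural coefficients zero yields lifestyle scores and cognition
that are exactly independent (a null model for calibration tests); the
age-link of factor prevalences stays on regardless.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import libra

__all__ = [
    "DEFAULT_PATH_COEFFICIENTS",
    "DEFAULT_FACTOR_PREVALENCES",
    "GeneratorConfig",
    "ToyConnectome",
    "generate_cohort",
    "generate_connectome",
    "average_node_degree",
    "generate_path_dataset",
    "write_cohort",
    "load_generator_config",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


#: Standardized structural effects, defaulting to the regime estimated in
#: population studies of lifestyle, brain age and cognition: a tertile-3-vs-1
#: lifestyle contrast of about -0.20 SD on cognition, ~18% of it mediated by
#: the brain-age substrate.
DEFAULT_PATH_COEFFICIENTS: dict[str, float] = {
    "lifestyle_to_substrate": 0.13,
    "lifestyle_to_connectivity": -0.05,
    "substrate_to_connectivity": -0.40,
    "substrate_to_cognition": -0.13,
    "connectivity_to_cognition": 0.06,
    "lifestyle_to_cognition": -0.07,
}

#: Target marginal prevalence of each dichotomised LIBRA factor.
DEFAULT_FACTOR_PREVALENCES: dict[str, float] = {
    "mediterranean_diet": 0.25,
    "low_moderate_alcohol": 0.55,
    "physical_inactivity": 0.45,
    "smoking": 0.13,
    "obesity": 0.20,
    "hypertension": 0.40,
    "high_cholesterol": 0.15,
    "heart_disease": 0.10,
    "chronic_kidney_disease": 0.06,
    "depression": 0.04,
}

_DEFAULT_NOISE_SD: dict[str, float] = {
    # Feature-specific measurement noise, scaled so each informative volume
    # carries ~3.5 years of age-equivalent error individually but ~2 years
    # when combined: no single scalar suffices, so model building has to
    # aggregate several features, as with real morphometry.
    "csf": 7.5,
    "gm": 7.0,
    "wm": 12.0,
    "log_wmh": 0.08,
    "node_degree": 2.5,  # scale of the standardized connectivity latent, in degree units
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults define the reference study conditions; ``path_coefficients`` and
    ``factor_prevalences`` accept partial overrides.
    """

    n_participants: int = 1000
    age_range: tuple[float, float] = (40.0, 75.0)
    seed: int = 0
    path_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    factor_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_PREVALENCES)
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    t2dm_oversampling_fraction: float = 0.20
    substrate_scale_years: float = 11.0
    vascular_scale_years: float = 5.0  # vessel-specific ageing beyond the shared substrate
    risk_age_loading: float = 0.35
    age_cognition_slope: float = 0.0   # per-SD-age effect on latent cognition
    domain_loading: float = 0.92       # loading of each domain z-score on latent cognition
    #: optional (male, female) lifestyle->substrate coefficients; overrides the shared one
    sex_specific_lifestyle_substrate: tuple[float, float] | None = None
    missing_rate: float = 0.0          # optional MCAR masking of raw lifestyle fields

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        coeffs = {**DEFAULT_PATH_COEFFICIENTS, **dict(self.path_coefficients)}
        unknown = set(coeffs) - set(DEFAULT_PATH_COEFFICIENTS)
        if unknown:
            raise ConfigurationError(f"path_coefficients: unknown keys {sorted(unknown)}")
        for k, v in coeffs.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"path_coefficients[{k}] must be finite")
        prevs = {**DEFAULT_FACTOR_PREVALENCES, **dict(self.factor_prevalences)}
        unknown = set(prevs) - set(DEFAULT_FACTOR_PREVALENCES)
        if unknown:
            raise ConfigurationError(f"factor_prevalences: unknown keys {sorted(unknown)}")
        for k, p in prevs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"factor_prevalences[{k}] must lie in [0, 1]")
        if not 0.0 <= self.t2dm_oversampling_fraction <= 1.0:
            raise ConfigurationError("t2dm_oversampling_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "path_coefficients", coeffs)
        object.__setattr__(self, "factor_prevalences", prevs)
        object.__setattr__(self, "noise_sd", {**_DEFAULT_NOISE_SD, **dict(self.noise_sd)})


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete synthetic participant table.

    Deterministic given ``config`` (including its seed).  Returns one row per
    participant with demographics, raw lifestyle measurements, brain scalars,
    domain cognition z-scores and scan-to-testing interval; the column
    dictionary ships as ``brainpath/data/cohort_schema.json``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    coeffs = dict(config.path_coefficients)
    prevs = dict(config.factor_prevalences)
    noise = dict(config.noise_sd)

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    z_age = (age - age.mean()) / (age.std(ddof=1) if n > 1 else 1.0)

    sex = np.where(rng.random(n) < 0.501, "male", "female")

    # Age-linked latent risk drives factor prevalences and sampling strata.
    w = config.risk_age_loading
    risk = w * z_age + np.sqrt(max(1 - w * w, 0.0)) * rng.standard_normal(n)

    # Education: ordinal from a risk-linked latent, fixed population shares.
    edu_latent = 0.30 * risk + rng.standard_normal(n)
    q_low, q_med = np.quantile(edu_latent, [0.40, 0.69]) if n >= 3 else (np.inf, np.inf)
    education = np.where(edu_latent >= q_med, "low", np.where(edu_latent >= q_low, "medium", "high"))

    # Glucose metabolism status with T2DM oversampling.
    f = config.t2dm_oversampling_fraction
    p_t2dm = _sigmoid(_logit(f) + 0.8 * risk) if 0 < f < 1 else np.full(n, float(f))
    is_t2dm = rng.random(n) < p_t2dm
    p_pre = _sigmoid(_logit(0.185) + 0.5 * risk)
    is_pre = (~is_t2dm) & (rng.random(n) < p_pre)
    is_other = (~is_t2dm) & (~is_pre) & (rng.random(n) < 0.008)
    glucose_status = np.select(
        [is_t2dm, is_pre, is_other], ["t2dm", "prediabetes", "other"], default="normal"
    )

    def bern(factor: str, loading: float) -> np.ndarray:
        p = prevs[factor]
        if p in (0.0, 1.0):
            return np.full(n, bool(p))
        return rng.random(n) < _sigmoid(_logit(p) + loading * risk)

    # --- raw lifestyle measurements, consistent with their dichotomisation ---
    diet_ok = bern("mediterranean_diet", -0.5)
    diet_score = np.where(diet_ok, rng.integers(6, 10, n), rng.integers(0, 6, n))

    alc_ok = bern("low_moderate_alcohol", -0.3)
    abstain = rng.random(n) < 0.5
    alcohol = np.where(
        alc_ok,
        rng.uniform(5, 69.9, n),
        np.where(abstain, 0.0, rng.uniform(70, 300, n)),
    ).round(1)

    inactive = bern("physical_inactivity", 0.5)
    mvpa = np.where(inactive, rng.uniform(0, 149.9, n), rng.uniform(150, 600, n)).round(0)

    smokes = bern("smoking", 0.4)
    smoking_status = np.where(smokes, "current", np.where(rng.random(n) < 0.5, "former", "never"))

    obese = bern("obesity", 0.5)
    bmi = np.where(
        obese, 30.0 + rng.exponential(2.5, n), np.clip(rng.normal(25.5, 2.5, n), 18.5, 29.9)
    ).round(1)

    hyper = bern("hypertension", 0.5)
    on_med = hyper & (rng.random(n) < 0.6)
    sbp = np.where(
        hyper & ~on_med,
        140 + np.abs(rng.normal(0, 12, n)),
        np.where(on_med, rng.normal(133, 12, n), np.clip(rng.normal(124, 8, n), 90, 139.4)),
    ).round(0)
    dbp = np.where(
        hyper & ~on_med, rng.normal(84, 8, n), np.clip(rng.normal(76, 6, n), 50, 89.4)
    ).round(0)

    high_chol = bern("high_cholesterol", 0.3)
    cholesterol = np.where(
        high_chol, 6.5 + rng.exponential(0.7, n), np.clip(rng.normal(5.2, 0.7, n), 2.5, 6.4)
    ).round(2)

    diabetes_med = np.select(
        [is_t2dm, is_other], [rng.random(n) < 0.8, rng.random(n) < 0.9], default=False
    )
    fasting_glucose = np.select(
        [is_t2dm, is_pre, is_other],
        [
            np.clip(rng.normal(8.2, 1.2, n), 4.0, None),
            np.clip(rng.normal(6.3, 0.4, n), 5.6, 6.9),
            np.clip(rng.normal(8.0, 1.5, n), 4.0, None),
        ],
        default=np.clip(rng.normal(5.2, 0.4, n), 3.5, 6.9),
    ).round(1)
    ogtt = np.select(
        [is_t2dm, is_pre, is_other],
        [
            np.clip(rng.normal(12.5, 2.5, n), 7.0, None),
            np.clip(rng.normal(8.5, 1.2, n), 7.8, 11.0),
            np.clip(rng.normal(10.0, 2.0, n), 5.0, None),
        ],
        default=np.clip(rng.normal(5.8, 1.3, n), 3.0, 7.7),
    ).round(1)

    heart_disease = bern("heart_disease", 0.6).astype(int)

    ckd = bern("chronic_kidney_disease", 0.5)
    low_egfr = ckd & (rng.random(n) < 0.7)
    egfr = np.where(
        low_egfr, np.clip(rng.normal(48, 8, n), 15, 59.4), np.clip(rng.normal(88, 12, n), 60.5, 130)
    ).round(0)
    albuminuria = (ckd & (~low_egfr | (rng.random(n) < 0.3))).astype(int)

    depressed = bern("depression", 0.5)
    phq9 = np.where(depressed, np.clip(10 + rng.poisson(4, n), 10, 27), rng.binomial(9, 0.15, n))
    mini_depression = (depressed & (rng.random(n) < 0.5)).astype(int)

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age.round(1),
            "sex": sex,
            "education": education,
            "glucose_status": glucose_status,
            "diet_score": diet_score,
            "alcohol_g_week": alcohol,
            "mvpa_min_week": mvpa,
            "smoking_status": smoking_status,
            "bmi": bmi,
            "sbp": sbp,
            "dbp": dbp,
            "antihypertensive_med": on_med.astype(int),
            "total_cholesterol": cholesterol,
            "fasting_glucose": fasting_glucose,
            "ogtt_glucose": ogtt,
            "diabetes_med": np.asarray(diabetes_med, dtype=int),
            "heart_disease": heart_disease,
            "egfr": egfr,
            "albuminuria": albuminuria,
            "phq9": phq9,
            "mini_depression": mini_depression,
        }
    )

    # --- lifestyle burden: the realized LIBRA score, standardized ---
    scored = libra.dichotomize_cohort(table)
    weights = libra.DEFAULT_WEIGHTS
    present = (scored[list(weights)] == libra.PRESENT).to_numpy(dtype=float)
    lib = present @ np.array(list(weights.values()))
    lib_sd = lib.std(ddof=1) if n > 1 and lib.std(ddof=1) > 0 else 1.0
    l_star = (lib - lib.mean()) / lib_sd

    # --- brain-age substrate and MRI scalars ---
    if config.sex_specific_lifestyle_substrate is not None:
        c_m, c_f = config.sex_specific_lifestyle_substrate
        c_lb = np.where(sex == "male", c_m, c_f)
    else:
        c_lb = np.full(n, coeffs["lifestyle_to_substrate"])
    substrate = c_lb * l_star + np.sqrt(np.clip(1 - c_lb**2, 0.05, None)) * rng.standard_normal(n)

    eff_age = age + config.substrate_scale_years * substrate
    a = eff_age - 57.5
    # Vascular features age along a partially distinct axis: the shared
    # substrate plus a vessel-specific deviation, so lesion load carries age
    # information not reducible to the atrophy markers.
    a_vasc = a + config.vascular_scale_years * rng.standard_normal(n)
    # CSF expansion and lesion load accelerate with effective age (quadratic);
    # grey-matter atrophy is close to linear over 40-75 y.
    csf = 180 + 2.2 * a + 0.030 * a**2 + rng.normal(0, noise["csf"], n)
    gm = 660 - 2.0 * a + rng.normal(0, noise["gm"], n)
    wm = 480 - 0.5 * a + rng.normal(0, noise["wm"], n)
    log_wmh = np.clip(
        0.8 + 0.050 * a_vasc + 0.0012 * a_vasc**2 + rng.normal(0, noise["log_wmh"], n), 0, None
    )
    wmh = np.expm1(log_wmh)

    cmb_present = rng.random(n) < _sigmoid(-2.2 + 0.045 * a_vasc)
    cmb_count = np.where(cmb_present, 1 + rng.poisson(1.2, n), 0)
    inf_present = rng.random(n) < _sigmoid(-3.2 + 0.030 * a_vasc)
    infarct_count = np.where(inf_present, 1 + rng.poisson(0.3, n), 0)

    # --- connectivity and cognition on the standardized structural scale ---
    c2 = coeffs["lifestyle_to_connectivity"]
    c3 = coeffs["substrate_to_connectivity"]
    c1 = float(np.mean(c_lb))
    var_c = c2**2 + c3**2 + 2 * c2 * c3 * c1
    conn = (
        c2 * l_star
        + c3 * substrate
        + np.sqrt(max(1 - var_c, 0.05)) * rng.standard_normal(n)
    )
    node_degree = 25.0 - 0.02 * (age - 57.5) + noise["node_degree"] * conn

    c_dir = coeffs["lifestyle_to_cognition"]
    c4 = coeffs["substrate_to_cognition"]
    c5 = coeffs["connectivity_to_cognition"]
    cov_lb = c1
    cov_lc = c2 + c3 * c1
    cov_bc = c3 + c2 * c1
    beta = np.array([c_dir, c4, c5])
    sigma = np.array([[1, cov_lb, cov_lc], [cov_lb, 1, cov_bc], [cov_lc, cov_bc, 1]])
    var_g = float(beta @ sigma @ beta)
    cognition = (
        c_dir * l_star
        + c4 * substrate
        + c5 * conn
        + config.age_cognition_slope * z_age
        + np.sqrt(max(1 - var_g, 0.05)) * rng.standard_normal(n)
    )

    lam = config.domain_loading
    domains = {}
    for name in ("z_memory", "z_speed", "z_executive"):
        d = lam * cognition + np.sqrt(max(1 - lam * lam, 0.0)) * rng.standard_normal(n)
        if n > 1 and d.std(ddof=1) > 0:
            d = (d - d.mean()) / d.std(ddof=1)
        domains[name] = d.round(4)

    table = table.assign(
        csf_ml=csf.round(1),
        gm_ml=gm.round(1),
        wm_ml=wm.round(1),
        wmh_ml=wmh.round(2),
        cmb_count=cmb_count.astype(int),
        lacunar_infarct_count=infarct_count.astype(int),
        node_degree=node_degree.round(2),
        **domains,
        months_since_mri=rng.uniform(0, 6, n).round(1),
    )

    if config.missing_rate > 0:
        maskable = [
            "diet_score", "alcohol_g_week", "mvpa_min_week", "bmi", "sbp", "dbp",
            "total_cholesterol", "fasting_glucose", "egfr", "phq9",
        ]
        mask = rng.random((n, len(maskable))) < config.missing_rate
        for j, colname in enumerate(maskable):
            col = table[colname].astype(float)
            col[mask[:, j]] = np.nan
            table[colname] = col

    return table


# ---------------------------------------------------------------------------
# Toy structural connectomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyConnectome:
    """Symmetric non-negative integer tract-count matrix over brain regions."""

    tract_counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.tract_counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("tract_counts must be a square matrix")
        if not np.array_equal(m, m.T):
            raise ValueError("tract_counts must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("tract_counts must have a zero diagonal")
        if np.any(m < 0):
            raise ValueError("tract_counts must be non-negative")

    @property
    def n_regions(self) -> int:
        return int(self.tract_counts.shape[0])


def generate_connectome(n_regions: int = 94, density: float = 0.3, seed: int = 0) -> ToyConnectome:
    """Random toy connectome: G(n, p) topology with geometric tract counts."""
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    graph = nx.gnp_random_graph(n_regions, density, seed=int(seed))
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_regions, n_regions), dtype=int)
    for i, j in graph.edges:
        c = int(rng.geometric(0.3))  # >= 1 tract per retained connection
        counts[i, j] = counts[j, i] = c
    return ToyConnectome(counts)


def average_node_degree(connectome: ToyConnectome, min_tracts: int = 2) -> float:
    """Whole-brain mean node degree after removing sparse connections.

    Connections with fewer than ``min_tracts`` tracts are treated as absent
    (a noise-suppression rule for deterministic tractography); the degree of
    each region is then counted and averaged over all regions.
    """
    adj = connectome.tract_counts >= min_tracts
    np.fill_diagonal(adj, False)
    return float(adj.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Exact linear-Gaussian benchmark
# ---------------------------------------------------------------------------

def generate_path_dataset(
    n: int,
    coefficients: Mapping[str, float] | None = None,
    seed: int = 0,
    sex_specific_lifestyle_substrate: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Known-truth serial two-mediator dataset on the exact standardized scale.

    Unlike :func:`generate_cohort`, the mediators here are observed directly
    (no brain-age model stands between the substrate and its measurement), so
    the injected standardized coefficients are the exact estimands of the path
    engine.  Used for confidence-interval coverage, power and type-I-error
    studies.  Columns: ``lifestyle``, ``bag``, ``connectivity``,
    ``cognition``, plus inert ``age`` and ``sex`` covariate columns.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    coeffs = {**DEFAULT_PATH_COEFFICIENTS, **(dict(coefficients) if coefficients else {})}
    rng = np.random.default_rng(seed)
    life = rng.standard_normal(n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    if sex_specific_lifestyle_substrate is not None:
        c_m, c_f = sex_specific_lifestyle_substrate
        c1 = np.where(sex == "male", c_m, c_f)
    else:
        c1 = np.full(n, coeffs["lifestyle_to_substrate"])
    bag = c1 * life + np.sqrt(np.clip(1 - c1**2, 0.01, None)) * rng.standard_normal(n)
    c2, c3 = coeffs["lifestyle_to_connectivity"], coeffs["substrate_to_connectivity"]
    c1m = float(np.mean(c1))
    var_c = c2**2 + c3**2 + 2 * c2 * c3 * c1m
    conn = c2 * life + c3 * bag + np.sqrt(max(1 - var_c, 0.01)) * rng.standard_normal(n)
    cd, c4, c5 = (
        coeffs["lifestyle_to_cognition"],
        coeffs["substrate_to_cognition"],
        coeffs["connectivity_to_cognition"],
    )
    cov_lb, cov_lc, cov_bc = c1m, c2 + c3 * c1m, c3 + c2 * c1m
    beta = np.array([cd, c4, c5])
    sigma = np.array([[1, cov_lb, cov_lc], [cov_lb, 1, cov_bc], [cov_lc, cov_bc, 1]])
    var_g = float(beta @ sigma @ beta)
    cog = (
        cd * life + c4 * bag + c5 * conn
        + np.sqrt(max(1 - var_g, 0.01)) * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "lifestyle": life,
            "bag": bag,
            "connectivity": conn,
            "cognition": cog,
            "age": rng.uniform(40, 75, n),
            "sex": sex,
        }
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path: str | Path, config: GeneratorConfig | None = None) -> None:
    """Write the cohort as UTF-8 comma-separated text; seed metadata alongside."""
    path = Path(path)
    table.to_csv(path, index=False)
    if config is not None:
        meta = dataclasses.asdict(config)
        meta["path_coefficients"] = dict(meta["path_coefficients"])
        meta["factor_prevalences"] = dict(meta["factor_prevalences"])
        meta["noise_sd"] = dict(meta["noise_sd"])
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=list))


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a GeneratorConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError("generator config file must contain a mapping")
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    if raw.get("sex_specific_lifestyle_substrate") is not None:
        raw["sex_specific_lifestyle_substrate"] = tuple(raw["sex_specific_lifestyle_substrate"])
    try:
        return GeneratorConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
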