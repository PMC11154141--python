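"""End-to-end study pipeline: LIBRA scoring -> brain age -> mediation.

Runs the full analysis chain on a phenotype table (real or synthetic):
lifestyle risk scoring and tertile split, brain-age model building and gap
computation, composite cognition, covariate-adjusted regressions, single- and
serial two-mediator decompositions for combined cognition and each cognitive
domain, and the sensitivity analyses (modified risk score without diabetes;
diabetes-status and sex interaction tests).

Two covariate sets are carried through, matching common practice: the
pre-path regressions adjust for age, sex, education and glucose status (the
sampling-design variable), while the path systems adjust for age, sex,
education and the imaging-to-testing interval.  Both are configurable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import brainage, libra, mediation, synthetic

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "PipelineError",
    "compute_composite_cognition",
    "run_full_analysis",
    "run_sensitivity",
]

logger = logging.getLogger("brainpath")

DOMAIN_COLUMNS = ("z_memory", "z_speed", "z_executive")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class AnalysisConfig:
    """Options for a full pipeline run."""

    input_path: str | None = None                     # CSV phenotype table; or generate:
    generator: synthetic.GeneratorConfig | None = None
    weights_path: str | None = None                   # LIBRA weights YAML (shipped default)
    seed: int = 0
    lasso_folds: int = 10
    parsimony_tolerance: float = 0.01
    include_connectivity_in_brainage: bool = False
    mediator_order: tuple[str, ...] = ("bag", "node_degree")
    inference: str = "delta"                          # or "bootstrap"
    n_boot: int = 1000
    regression_covariates: tuple[str, ...] = ("age", "sex", "education", "glucose_status")
    path_covariates: tuple[str, ...] = ("age", "sex", "education", "months_since_mri")
    min_complete_cases: int = 200
    output_dir: str | None = None


@dataclass
class StudyReport:
    """Machine-readable results of a full run."""

    seed: int
    n_input: int
    n_analytic: int
    cohort_summary: dict
    model_comparison: list[dict]
    selected_model: str
    regressions: dict
    decompositions: dict          # outcome label -> exposure term -> decomposition dict
    domain_n: dict
    sensitivity: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None   # analytic table with derived columns

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("table")
        return d


def compute_composite_cognition(domains: pd.DataFrame) -> pd.Series:
    """Average the three domain z-scores row-wise and re-standardize.

    Rows missing any domain score are excluded (NaN) and counted by the
    caller; the returned composite has mean 0 and SD 1 over complete rows.
    """
    missing = [c for c in DOMAIN_COLUMNS if c not in domains.columns]
    if missing:
        raise ValueError(f"missing domain score columns: {missing}")
    raw = domains[list(DOMAIN_COLUMNS)].mean(axis=1, skipna=False)
    sd = raw.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("composite cognition has zero variance")
    return (raw - raw.mean()) / sd


def _prepare_table(config: AnalysisConfig) -> pd.DataFrame:
    if (config.input_path is None) == (config.generator is None):
        raise PipelineError("input", "provide exactly one of input_path or generator config")
    if config.generator is not None:
        return synthetic.generate_cohort(config.generator)
    path = Path(config.input_path)
    if not path.exists():
        raise PipelineError("input", f"input table not found: {path}")
    return pd.read_csv(path)


def run_full_analysis(config: AnalysisConfig) -> StudyReport:
    """Execute the complete chain and (optionally) write the report to disk.

    Fully reproducible given the configuration (including seeds); any stage
    failure raises :class:`PipelineError` tagged with the stage, and partial
    outputs in the output directory are removed.
    """
    t0 = time.perf_counter()
    table = _prepare_table(config)
    n_input = len(table)

    # --- LIBRA stage -------------------------------------------------------
    try:
        weights = libra.load_weights(config.weights_path)
        scored = libra.score_cohort(table, weights=weights)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("libra", str(exc)) from exc
    work = table.copy()
    work["libra_score"] = scored["libra_score"]
    work["libra_tertile"] = scored["libra_tertile"]

    # complete-case on factors: participants with any unavailable factor are
    # dropped from the analytic sample (unassessed factors excepted)
    assessed = [f for f in libra.FACTORS if f != "cognitive_activity"]
    complete = (scored[assessed] != libra.UNAVAILABLE).all(axis=1)
    work = work[complete].reset_index(drop=True)
    n_analytic = len(work)
    if n_analytic < config.min_complete_cases:
        warnings.warn(
            f"analytic sample n={n_analytic} below the configured minimum "
            f"{config.min_complete_cases}; results may be unstable",
            stacklevel=2,
        )
    if n_analytic < 50:
        raise PipelineError("libra", f"too few complete cases (n={n_analytic})")
    # re-split tertiles on the analytic sample
    work["libra_tertile"] = libra.assign_tertiles(work["libra_score"])
    logger.info("libra stage: n_analytic=%d", n_analytic)

    # --- brain-age stage ---------------------------------------------------
    try:
        features = brainage.preprocess_features(work)
        age = work["age"].to_numpy(dtype=float)
        model_cols = ["csf", "gm", "wm", "log_wmh", "cmb_presence", "infarct_presence"]
        if config.include_connectivity_in_brainage:
            model_cols.append("node_degree")
        ranking = brainage.rank_candidates(features[model_cols], age)
        if not ranking:
            raise ValueError("no feature significantly associated with age")
        stepwise = brainage.build_stepwise_models(ranking, features, age)
        mains = [t.feature for t in ranking]
        quads = [t.feature for t in ranking if t.quadratic]
        lasso = brainage.fit_lasso_model(
            features, age, mains, quads, n_folds=config.lasso_folds, seed=config.seed
        )
        fits = [*stepwise, lasso]
        selected = brainage.compare_models(fits, config.parsimony_tolerance)
        bag = brainage.compute_bag(selected, features, age)
        work["bag"] = bag.bag
        work["predicted_age"] = bag.predicted_age
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("brain_age", str(exc)) from exc
    logger.info(
        "brain-age stage: selected %s (R2=%.3f, RMSE=%.2f), corr(BAG, age)=%.3f",
        selected.label, selected.r2, selected.rmse, bag.bag_age_correlation,
    )

    # --- cognition & regressions ------------------------------------------
    try:
        work["cognition"] = compute_composite_cognition(work)
        regs = mediation.fit_adjusted_regressions(
            work, covariates=config.regression_covariates
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("regressions", str(exc)) from exc

    # --- mediation stage ---------------------------------------------------
    m1, m2 = config.mediator_order
    decomps: dict[str, dict] = {}
    domain_n: dict[str, int] = {}
    try:
        outcomes = {"cognition": "cognition"} | {
            {"z_memory": "memory", "z_speed": "processing_speed", "z_executive": "executive"}[c]: c
            for c in DOMAIN_COLUMNS
        }
        for label, column in outcomes.items():
            spec = mediation.PathModelSpec(
                exposure="libra_tertile",
                outcome=column,
                mediators=(m1, m2),
                covariates=config.path_covariates,
                exposure_type="tertile",
            )
            fit = mediation.fit_path_system(spec, work)
            domain_n[label] = fit.n
            dec = mediation.decompose_serial(fit)
            block = {term: d.to_dict() for term, d in dec.items()}
            if config.inference == "bootstrap":
                block["bootstrap"] = mediation.bootstrap_inference(
                    spec, work, n_boot=config.n_boot, seed=config.seed
                )
            decomps[label] = block
        # single-mediator (BAG only) model on combined cognition
        spec1 = mediation.PathModelSpec(
            exposure="libra_tertile",
            outcome="cognition",
            mediators=(m1,),
            covariates=config.path_covariates,
            exposure_type="tertile",
        )
        fit1 = mediation.fit_path_system(spec1, work)
        decomps["cognition_single_mediator"] = {
            term: d.to_dict() for term, d in mediation.decompose_serial(fit1).items()
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("mediation", str(exc)) from exc

    report = StudyReport(
        seed=config.seed,
        n_input=n_input,
        n_analytic=n_analytic,
        cohort_summary=_summarize_cohort(work),
        model_comparison=[f.to_dict() for f in fits],
        selected_model=selected.label,
        regressions={
            block: {nm: {"beta": e.beta, "se": e.se, "z": e.z, "p": e.p} for nm, e in rows.items()}
            for block, rows in regs.items()
        },
        decompositions=decomps,
        domain_n=domain_n,
        table=work,
    )
    logger.info("full analysis finished in %.1fs", time.perf_counter() - t0)

    if config.output_dir is not None:
        _write_report(report, config)
    return report


def run_sensitivity(config: AnalysisConfig, report: StudyReport) -> dict:
    """Sensitivity analyses on a completed run.

    1. Modified risk score excluding diabetes, with glucose status adjusted
       for separately; total effect compared with the original.
    2. Diabetes-status interaction with the lifestyle->BAG path (Wald chi2).
    3. Sex interaction with the lifestyle->BAG path.
    """
    work = report.table
    if work is None:
        raise PipelineError("sensitivity", "run_full_analysis must be executed first")
    weights = libra.load_weights(config.weights_path)
    out: dict = {}
    try:
        modified = libra.score_cohort(work, weights=weights, exclude=("type2_diabetes",))
        mod = work.copy()
        mod["libra_score"] = modified["libra_score"]
        mod["libra_tertile"] = libra.assign_tertiles(mod["libra_score"])
        spec = mediation.PathModelSpec(
            exposure="libra_tertile",
            outcome="cognition",
            mediators=(config.mediator_order[0],),
            covariates=tuple(config.path_covariates) + ("glucose_status",),
            exposure_type="tertile",
        )
        fit = mediation.fit_path_system(spec, mod)
        dec = mediation.decompose_serial(fit)
        top = "libra_tertile[T3]"
        orig = report.decompositions["cognition_single_mediator"][top]
        out["modified_libra"] = {
            "decomposition": {t: d.to_dict() for t, d in dec.items()},
            "total_original": orig["total"]["estimate"],
            "total_modified": dec[top].total.estimate,
            "pm_original_pct": orig["proportion_mediated_overall_pct"],
            "pm_modified_pct": dec[top].proportion_mediated_overall,
        }

        t2dm = (work["glucose_status"] == "t2dm").astype(int)
        itest = mediation.test_group_interaction(
            work.assign(_t2dm=t2dm),
            outcome="bag",
            exposure="libra_score",
            group="_t2dm",
            covariates=("age", "sex"),
        )
        out["t2dm_interaction"] = dataclasses.asdict(itest)
        stest = mediation.test_group_interaction(
            work,
            outcome="bag",
            exposure="libra_score",
            group="sex",
            covariates=("age",),
        )
        out["sex_interaction"] = dataclasses.asdict(stest)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("sensitivity", str(exc)) from exc
    report.sensitivity = out
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _summarize_cohort(work: pd.DataFrame) -> dict:
    def by_tertile(col: str):
        g = work.groupby("libra_tertile")[col]
        return {int(k): [round(float(v.mean()), 3), round(float(v.std(ddof=1)), 3)] for k, v in g}

    return {
        "n": int(len(work)),
        "n_per_tertile": {int(k): int(v) for k, v in work["libra_tertile"].value_counts().items()},
        "age_mean_sd": [round(float(work["age"].mean()), 2), round(float(work["age"].std(ddof=1)), 2)],
        "pct_male": round(100 * float((work["sex"] == "male").mean()), 1),
        "pct_t2dm": round(100 * float((work["glucose_status"] == "t2dm").mean()), 1),
        "libra_by_tertile": by_tertile("libra_score"),
        "bag_by_tertile": by_tertile("bag") if "bag" in work else {},
    }


def _write_report(report: StudyReport, config: AnalysisConfig) -> None:
    outdir = Path(config.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        pd.DataFrame(report.model_comparison).drop(columns=["coefficients"]).to_csv(
            outdir / "model_comparison.csv", index=False
        )
        rows = []
        for outcome, block in report.decompositions.items():
            for term, dec in block.items():
                if term == "bootstrap":
                    continue
                for comp in ("total", "direct", "total_indirect"):
                    rows.append(
                        {
                            "outcome": outcome,
                            "exposure_term": term,
                            "component": comp,
                            **dec[comp],
                        }
                    )
                for k, v in dec["indirect"].items():
                    rows.append(
                        {"outcome": outcome, "exposure_term": term, "component": k, **v}
                    )
        pd.DataFrame(rows).to_csv(outdir / "decompositions.csv", index=False)
        report.table.to_csv(outdir / "analytic_table.csv", index=False)
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise PipelineError("report", str(exc)) from exc
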