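"""File schemas, configuration and the end-to-end analysis driver.

Trial files are comma-separated UTF-8 with header
``child_id,display_size,exposure_ms,masked,score`` (milliseconds on disk,
seconds in memory).  Cohort files carry ``child_id,age,va_span,
reading_speed`` plus any fitted or true parameter columns.

:func:`run_pipeline` reproduces the full analysis from one of three
sources: (a) trial + cohort files, (b) a structural simulation, or (c)
summary moments (the published Table 1/2 values ship as the default),
and always runs screening -> descriptives -> correlations -> the three
regression models -> mediation, writing a JSON report plus a text
rendering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlation_matrix, ols_fit, partial_correlation
from .mediation import mediation_analysis
from .screening import ScreeningConfig, zscore_outlier_screen
from .synthetic_data import (
    TABLE1_MOMENTS,
    CohortConfig,
    CohortMoments,
    generate_cohort_moment_exact,
    generate_cohort_structural,
)
from .tva_core import DisplayCondition
from .tva_fit import FitConfig, TrialRecord, average_fit_quality, fit_quality, fit_tva

logger = logging.getLogger("vaspan")

__all__ = [
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
    "render_report_text",
]

TRIAL_COLUMNS = ["child_id", "display_size", "exposure_ms", "masked", "score"]

ANALYSIS_VARIABLES = ["age", "va_span", "C", "K", "reading_speed"]
MODELS = {
    "model1_va_span": ("va_span", ["age", "C", "K"]),
    "model2_reading_speed_va": ("reading_speed", ["age", "va_span"]),
    "model3_reading_speed_tva": ("reading_speed", ["age", "C", "K"]),
}


def write_trials(trials: list[TrialRecord], path: str | Path) -> None:
    rows = [
        dict(
            child_id=t.child_id,
            display_size=t.condition.n,
            exposure_ms=round(t.condition.exposure * 1000.0, 6),
            masked=int(t.condition.masked),
            score=t.score,
        )
        for t in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial CSV; malformed rows are rejected with line numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} missing columns: {missing}")
    trials: list[TrialRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            n = int(row["display_size"])
            exposure = float(row["exposure_ms"]) / 1000.0
            masked = bool(int(row["masked"]))
            score = int(row["score"])
            cond = DisplayCondition(n=n, exposure=exposure, masked=masked)
            trials.append(TrialRecord(str(row["child_id"]), cond, score))
        except (ValueError, TypeError) as e:
            errors.append(f"line {line}: {e}")
    if errors:
        raise ValueError(f"malformed rows in {path}: " + "; ".join(errors[:10]))
    return trials


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "child_id" not in df.columns:
        raise ValueError(f"cohort file {path} must have a child_id column")
    return df


@dataclass
class PipelineConfig:
    """One config object drives the whole analysis.

    ``mode`` is "files", "structural" or "moments".  A single ``seed``
    is fanned out to the stages by fixed offsets.
    """

    mode: str = "moments"
    seed: int = 0
    trials_path: str | None = None
    cohort_path: str | None = None
    n_children: int = 47
    bootstrap_samples: int = 1000
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    moments: CohortMoments = field(default_factory=lambda: TABLE1_MOMENTS)
    mediation_x: str = "C"
    mediation_m: str = "va_span"
    mediation_y: str = "reading_speed"
    mediation_covariates: tuple[str, ...] = ("age",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in (
            "mode",
            "seed",
            "trials_path",
            "cohort_path",
            "n_children",
            "bootstrap_samples",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "screening" in raw:
            kwargs["screening"] = ScreeningConfig(**raw["screening"])
        if "cohort" in raw:
            kwargs["cohort_config"] = CohortConfig(**raw["cohort"])
        return cls(**kwargs)


def _seed_for(config: PipelineConfig, stage: str) -> np.random.Generator:
    offsets = {"cohort": 1, "fit": 2, "mediation": 3}
    return np.random.default_rng((config.seed * 10 + offsets[stage]) % (2**31))


def _descriptives(cohort: pd.DataFrame, variables: list[str]) -> dict:
    out = {}
    n = len(cohort)
    for v in variables:
        x = cohort[v].to_numpy(dtype=float)
        half = 1.96 * x.std(ddof=1) / math.sqrt(n)
        out[v] = dict(
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)),
            ci95=[float(x.mean() - half), float(x.mean() + half)],
            range=[float(x.min()), float(x.max())],
        )
    return out


def _fit_cohort_trials(
    trials: list[TrialRecord], fit_config: FitConfig | None = None
) -> pd.DataFrame:
    """Fit every child's trials; returns child_id, C, K, t0, mu, fit r."""
    by_child: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_child.setdefault(t.child_id, []).append(t)
    rows = []
    for cid in sorted(by_child):
        fit = fit_tva(by_child[cid], fit_config)
        rows.append(
            dict(
                child_id=cid,
                C=fit.params.C,
                K=fit.params.K,
                t0=fit.params.t0,
                mu=fit.params.mu,
                fit_r=fit_quality(fit),
                converged=fit.converged,
            )
        )
    return pd.DataFrame(rows)


def _regression_block(fit) -> dict:
    return dict(
        response=fit.response,
        predictors=fit.predictors,
        coefficients={k: float(v) for k, v in fit.params.items()},
        standard_errors={k: float(v) for k, v in fit.bse.items()},
        t_values={k: float(v) for k, v in fit.tvalues.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        standardized={k: float(v) for k, v in fit.standardized.items()},
        r_squared=fit.r_squared,
        f_statistic=fit.f_statistic,
        f_pvalue=fit.f_pvalue,
        df=[fit.df_model, fit.df_resid],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the report as a dict."""
    stage = "input"
    try:
        if config.mode == "moments":
            # the published cohort was screened before its moments were
            # tabulated, so the emulated cohort is drawn post-screen
            cohort = generate_cohort_moment_exact(
                config.moments,
                _seed_for(config, "cohort"),
                max_abs_z=config.screening.z_threshold,
            )
            fit_summary = None
        elif config.mode == "structural":
            cohort, trials = generate_cohort_structural(
                config.cohort_config, config.n_children, _seed_for(config, "cohort")
            )
            stage = "tva_fit"
            fits = _fit_cohort_trials(trials)
            cohort = cohort.merge(fits, on="child_id")
            fit_summary = dict(
                mean_fit_r=average_fit_quality(fits["fit_r"].to_numpy()),
                n_converged=int(fits["converged"].sum()),
            )
        elif config.mode == "files":
            if not config.trials_path or not config.cohort_path:
                raise ValueError("files mode needs trials_path and cohort_path")
            cohort = read_cohort(config.cohort_path)
            trials = read_trials(config.trials_path)
            stage = "tva_fit"
            fits = _fit_cohort_trials(trials)
            cohort = cohort.merge(fits, on="child_id")
            fit_summary = dict(
                mean_fit_r=average_fit_quality(fits["fit_r"].to_numpy()),
                n_converged=int(fits["converged"].sum()),
            )
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

        stage = "screening"
        kept, excluded, screen_report = zscore_outlier_screen(cohort, config.screening)

        stage = "descriptives"
        descriptives = _descriptives(kept, ANALYSIS_VARIABLES)

        stage = "correlations"
        corr = correlation_matrix(kept, ANALYSIS_VARIABLES)
        partials = {}
        non_age = [v for v in ANALYSIS_VARIABLES if v != "age"]
        for i, v1 in enumerate(non_age):
            for v2 in non_age[i + 1 :]:
                partials[f"{v1}|{v2}"] = partial_correlation(kept, v1, v2, "age")

        stage = "regressions"
        regressions = {
            name: _regression_block(ols_fit(kept, resp, preds))
            for name, (resp, preds) in MODELS.items()
        }

        stage = "mediation"
        med = mediation_analysis(
            kept,
            config.mediation_x,
            config.mediation_m,
            config.mediation_y,
            list(config.mediation_covariates),
            B=config.bootstrap_samples,
            rng=_seed_for(config, "mediation"),
        )
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    cfg_hash = hashlib.sha256(
        json.dumps(
            dict(mode=config.mode, seed=config.seed, n=config.n_children,
                 B=config.bootstrap_samples),
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]

    report = dict(
        provenance=dict(seed=config.seed, mode=config.mode,
                        config_hash=cfg_hash, version=__version__),
        n_input=len(cohort),
        n_kept=len(kept),
        screening=dict(
            excluded=[
                dict(child_id=r.child_id, rule=r.rule, variable=r.variable,
                     value=r.value, statistic=r.statistic)
                for r in screen_report
            ]
        ),
        tva_fit=fit_summary,
        descriptives=descriptives,
        correlations=dict(
            variables=corr.variables,
            r=corr.r.round(10).values.tolist(),
            p=corr.p.values.tolist(),
            partial_controlling_age=partials,
        ),
        regressions=regressions,
        mediation=dict(
            x=config.mediation_x,
            m=config.mediation_m,
            y=config.mediation_y,
            covariates=list(config.mediation_covariates),
            paths=dict(
                a=dict(coef=med.paths.a.coef, se=med.paths.a.se, p=med.paths.a.p),
                b=dict(coef=med.paths.b.coef, se=med.paths.b.se, p=med.paths.b.p),
                c=dict(coef=med.paths.c.coef, se=med.paths.c.se, p=med.paths.c.p),
                c_prime=dict(coef=med.paths.c_prime.coef, se=med.paths.c_prime.se,
                             p=med.paths.c_prime.p),
            ),
            verdict=med.paths.verdict,
            indirect=med.indirect,
            indirect_ci95=list(med.indirect_ci),
            kappa2=med.kappa2,
            kappa2_ci95=list(med.kappa2_ci),
            bootstrap_samples=med.n_bootstrap,
            dropped_resamples=med.n_dropped,
        ),
    )
    return report


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def render_report_text(report: dict) -> str:
    """Human-readable rendering of the JSON report (4 significant digits)."""
    lines = []
    prov = report["provenance"]
    lines.append(f"vaspan analysis report (v{prov['version']}, mode={prov['mode']}, "
                 f"seed={prov['seed']})")
    lines.append(f"children: {report['n_input']} in, {report['n_kept']} kept")
    lines.append("")
    lines.append("Descriptives (mean [95% CI] range):")
    for v, d in report["descriptives"].items():
        lines.append(
            f"  {v:14s} {_fmt(d['mean'])} [{_fmt(d['ci95'][0])}, {_fmt(d['ci95'][1])}] "
            f"({_fmt(d['range'][0])}-{_fmt(d['range'][1])})"
        )
    lines.append("")
    lines.append("Correlations:")
    vs = report["correlations"]["variables"]
    header = "              " + "".join(f"{v:>14s}" for v in vs)
    lines.append(header)
    for v, row in zip(vs, report["correlations"]["r"]):
        lines.append(f"  {v:12s}" + "".join(f"{x:14.2f}" for x in row))
    lines.append("")
    for name, reg in report["regressions"].items():
        lines.append(
            f"{name}: {reg['response']} ~ {' + '.join(reg['predictors'])}  "
            f"R2={_fmt(reg['r_squared'])}, F({reg['df'][0]},{reg['df'][1]})="
            f"{_fmt(reg['f_statistic'])}"
        )
        for term, coef in reg["coefficients"].items():
            lines.append(
                f"    {term:12s} b={_fmt(coef)}  SE={_fmt(reg['standard_errors'][term])}"
                f"  p={_fmt(reg['p_values'][term])}"
            )
    lines.append("")
    med = report["mediation"]
    lines.append(
        f"Mediation {med['x']} -> {med['m']} -> {med['y']} "
        f"(covariates: {', '.join(med['covariates'])})"
    )
    for pth in ("a", "b", "c", "c_prime"):
        p = med["paths"][pth]
        lines.append(f"    {pth:8s} {_fmt(p['coef'])} ({_fmt(p['se'])})  p={_fmt(p['p'])}")
    lines.append(f"    verdict: {med['verdict']} mediation")
    lines.append(
        f"    indirect a*b = {_fmt(med['indirect'])}  "
        f"BCa95 [{_fmt(med['indirect_ci95'][0])}, {_fmt(med['indirect_ci95'][1])}]"
    )
    lines.append(
        f"    kappa2 = {_fmt(med['kappa2'])}  "
        f"BCa95 [{_fmt(med['kappa2_ci95'][0])}, {_fmt(med['kappa2_ci95'][1])}]"
    )
    return "\n".join(lines) + "\n"
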