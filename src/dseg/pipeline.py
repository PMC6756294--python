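"""Umbrella orchestration: synthetic generation through prediction.

Stages (in order): ``generate`` -> ``stats`` -> ``predict`` -> ``report``.
Each stage writes plain-text outputs (TSV/CSV/JSON) into the run directory;
a re-run with an unchanged config hash reuses cached upstream outputs when
only downstream stages are requested.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

import dseg
from dseg.io import RunManifest, config_hash, write_spectra_tsv
from dseg.longitudinal import fit_lme_change, regress_slopes
from dseg.prediction import fit_cox, loo_cv_classify, zscore_covariates
from dseg.synthetic import DOMAINS, SyntheticConfig, generate_cohort

__all__ = ["run_pipeline", "write_report", "validate_report", "STAGES"]

STAGES = ("generate", "stats", "predict", "report")

THETA_WINDOW_YEARS = 3.0
COGNITION_WINDOW_YEARS = 5.0


def _stage_outputs(out: Path) -> dict[str, list[Path]]:
    return {
        "generate": [out / "cohort.csv", out / "subjects.csv"],
        "stats": [out / "stats.json"],
        "predict": [out / "prediction.json"],
        "report": [out / "report.json", out / "report.txt"],
    }


def run_pipeline(
    config: SyntheticConfig,
    out_dir,
    stages: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Execute the requested stages, reusing cached upstream outputs.

    ``seed`` overrides the config's rng seed.  Raises on the first failing
    stage, naming it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "rng_seed": int(seed)})
    requested = tuple(stages) if stages else STAGES
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    chash = config_hash(asdict(config))
    manifest = RunManifest(config_hash=chash, seed=config.rng_seed, version=dseg.__version__)
    outputs = _stage_outputs(out)

    def cached(stage: str) -> bool:
        return stage not in requested and all(p.exists() for p in outputs[stage])

    try:
        # ---- generate -------------------------------------------------
        if cached("generate"):
            cohort = pd.read_csv(out / "cohort.csv")
            subjects = pd.read_csv(out / "subjects.csv")
            manifest.add_stage("generate", outputs["generate"], cached=True)
        else:
            data = generate_cohort(config)
            cohort, subjects = data.cohort, data.subjects
            cohort.to_csv(out / "cohort.csv", index=False)
            subjects.to_csv(out / "subjects.csv", index=False)
            extra = []
            if data.model is not None:
                data.model.to_json(out / "model.json")
                write_spectra_tsv(out / "spectra.tsv", data.spectra)
                extra = [out / "model.json", out / "spectra.tsv"]
            manifest.add_stage(
                "generate",
                outputs["generate"] + extra,
                n_subjects=int(subjects.shape[0]),
                n_converters=int(subjects["converted"].sum()),
            )
        if "generate" in requested and requested == ("generate",):
            manifest.validate()
            manifest.to_json(out / "manifest.json")
            return manifest

        # ---- stats ----------------------------------------------------
        if cached("stats"):
            stats = json.loads((out / "stats.json").read_text())
            manifest.add_stage("stats", outputs["stats"], cached=True)
        else:
            stats = _stats_stage(cohort, subjects)
            (out / "stats.json").write_text(json.dumps(stats, indent=2))
            manifest.add_stage("stats", outputs["stats"])

        # ---- predict --------------------------------------------------
        if cached("predict"):
            prediction = json.loads((out / "prediction.json").read_text())
            manifest.add_stage("predict", outputs["predict"], cached=True)
        else:
            prediction = _predict_stage(subjects)
            (out / "prediction.json").write_text(json.dumps(prediction, indent=2))
            manifest.add_stage("predict", outputs["predict"])

        # ---- report ---------------------------------------------------
        results = {"lme": stats["lme"], "slope_regressions": stats["slope_regressions"],
                   "cox": prediction.get("cox", {}), "classification": prediction.get("lda", {})}
        text, payload = write_report(results)
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        (out / "report.txt").write_text(text)
        manifest.add_stage("report", outputs["report"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {_failing_stage(manifest)}: {exc}") from exc

    manifest.validate()
    manifest.to_json(out / "manifest.json")
    return manifest


def _failing_stage(manifest: RunManifest) -> str:
    done = [s["name"] for s in manifest.stages]
    for stage in STAGES:
        if stage not in done:
            return stage
    return "report"


def _stats_stage(cohort: pd.DataFrame, subjects: pd.DataFrame) -> dict:
    lme_out = {}
    slopes = {}
    theta_long = cohort.dropna(subset=["theta"])[["subject_id", "visit_time", "theta"]]
    fits = {}
    fit_theta = fit_lme_change(theta_long, "theta", max_time=THETA_WINDOW_YEARS)
    fits["theta"] = fit_theta
    for domain in DOMAINS:
        fits[domain] = fit_lme_change(cohort, domain, max_time=COGNITION_WINDOW_YEARS)
    for name, fit in fits.items():
        lme_out[name] = {
            "fixed_slope": fit.fixed_slope,
            "slope_se": fit.slope_se,
            "wald_stat": fit.wald_stat,
            "wald_p": fit.wald_p,
            "n_subjects": fit.n_subjects,
            "random_slope_dropped": fit.random_slope_dropped,
        }
        slopes[name] = fit.subject_slopes

    subj = subjects.set_index("subject_id")
    covs = subj[["age_baseline", "premorbid_iq", "sex"]]
    regs = {}
    # slope regressions only for outcomes with significant change over time
    for domain in DOMAINS:
        if fits[domain].wald_p >= 0.05:
            regs[domain] = {"skipped": True, "reason": "no significant change over time"}
            continue
        fit = regress_slopes(
            slopes[domain],
            subj["theta_baseline"],
            slopes["theta"],
            covs,
            outcome_name=domain,
        )
        regs[domain] = {
            "coefficients": {k: float(v) for k, v in fit.params.items()},
            "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
            "r_squared": fit.r_squared,
            "n": fit.n,
        }
    return {"lme": lme_out, "slope_regressions": regs}


def _predict_stage(subjects: pd.DataFrame) -> dict:
    df = subjects.copy()
    zdf, _ = zscore_covariates(df, ["theta_baseline", "theta_slope", "age_baseline", "premorbid_iq"])
    cox = fit_cox(zdf, ["theta_baseline"])
    cox_multi = fit_cox(zdf, ["theta_baseline", "theta_slope", "age_baseline", "premorbid_iq", "sex"])

    y = df["converted"].astype(int).to_numpy()
    feats = {
        "theta_baseline": ["theta_baseline"],
        "theta_slope": ["theta_slope"],
        "combined": ["theta_baseline", "theta_slope", "age_baseline", "sex", "premorbid_iq"],
    }
    lda = {}
    for name, cols in feats.items():
        report = loo_cv_classify(zdf[[c for c in cols if c in zdf] or cols].to_numpy(float), y)
        lda[name] = report.to_dict()
    return {
        "cox": {
            "univariate_theta_baseline": _cox_to_dict(cox),
            "multivariable": _cox_to_dict(cox_multi),
        },
        "lda": lda,
    }


def _cox_to_dict(fit) -> dict:
    return {
        name: {
            "coef": float(row["coef"]),
            "hr": float(row["hr"]),
            "ci": [float(row["hr_ci_low"]), float(row["hr_ci_high"])],
            "p": float(row["p"]),
        }
        for name, row in fit.summary.iterrows()
    }


REPORT_SCHEMA = {
    "lme": dict,
    "slope_regressions": dict,
    "cox": dict,
    "classification": dict,
}


def validate_report(payload: dict) -> None:
    """Check the machine report against the shipped structural schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in payload:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(payload[key], typ):
            raise ValueError(f"report section {key!r} must be a {typ.__name__}")


def write_report(results: dict) -> tuple[str, dict]:
    """Render a human-readable summary and the machine JSON payload.

    Sections with no content (e.g. an empty prediction stage) are omitted
    from the text output; the JSON always carries all four keys.
    """
    payload = {
        "lme": results.get("lme", {}),
        "slope_regressions": results.get("slope_regressions", {}),
        "cox": results.get("cox", {}),
        "classification": results.get("classification", {}),
    }
    validate_report(payload)
    lines = ["Pipeline report", "==============="]
    if payload["lme"]:
        lines += ["", "Annualised change (LME fixed slopes)", "-" * 36]
        for name, fit in payload["lme"].items():
            lines.append(
                f"{name:>8}: slope={fit['fixed_slope']:+.4f}/y  se={fit['slope_se']:.4f}"
                f"  Wald={fit['wald_stat']:.2f}  p={fit['wald_p']:.3g}"
            )
    if payload["slope_regressions"]:
        lines += ["", "Slope regressions on baseline/change in angle", "-" * 45]
        for name, reg in payload["slope_regressions"].items():
            if reg.get("skipped"):
                lines.append(f"{name:>8}: skipped ({reg['reason']})")
            else:
                coef = reg["coefficients"]
                lines.append(
                    f"{name:>8}: b(theta0)={coef.get('theta_baseline', float('nan')):+.4f}"
                    f"  b(dtheta)={coef.get('theta_slope', float('nan')):+.4f}"
                    f"  R2={reg['r_squared']:.3f}  n={reg['n']}"
                )
    if payload["cox"]:
        lines += ["", "Proportional-hazards models (per SD)", "-" * 36]
        for model_name, table in payload["cox"].items():
            lines.append(f"{model_name}:")
            for cov, row in table.items():
                lines.append(
                    f"    {cov:>16}: HR={row['hr']:.3f} (95% CI {row['ci'][0]:.3f}-{row['ci'][1]:.3f})"
                    f"  p={row['p']:.3g}"
                )
    if payload["classification"]:
        lines += ["", "Leave-one-out discriminant classification", "-" * 41]
        for model_name, rep in payload["classification"].items():
            lines.append(
                f"{model_name:>16}: sens={rep['sensitivity']:.3f} spec={rep['specificity']:.3f}"
                f" acc={rep['accuracy']:.3f} BCR={rep['bcr']:.3f} AUC={rep['auc']:.3f}"
            )
    return "\n".join(lines) + "\n", payload
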