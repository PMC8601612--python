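"""End-to-end analysis: behavioral dispersion, model fits, group statistics.

Reproduces the analysis chain of a two-group delayed-estimation study on
real or synthetic trial tables:

1. circular SD (CSD) of response errors per subject x set size, compared by
   a two-way mixed ANOVA (set size within, group between);
2. per-subject maximum-likelihood fits of the observer models and AIC/BIC
   winner proportions per group;
3. group comparisons of the fitted VP parameters (two-sample t, Cohen's d);
4. Pearson correlations between fitted resource allocation variability
   (tau) and symptom scores.

Input format: delimited text with columns subject, group, set_size,
stimulus_deg, response_deg, period_deg (one row per trial; period may
differ between subjects but not within one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .circular import FeatureSpace, circular_sd
from .fitting import (
    FitConfig,
    SubjectDataset,
    best_model_table,
    fit_all_models,
    fits_to_frame,
    fits_to_json,
)
from .models import MODEL_NAMES
from .synthetic import (
    TASK_PRESETS,
    CohortConfig,
    TaskDesign,
    generate_cohort,
    write_cohort,
)

__all__ = [
    "GroupComparison",
    "SymptomCorrelation",
    "PipelineConfig",
    "read_trials",
    "csd_summary",
    "mixed_anova_csd",
    "compare_group_parameters",
    "correlate_symptoms",
    "run_pipeline",
]

REQUIRED_COLUMNS = [
    "subject",
    "group",
    "set_size",
    "stimulus_deg",
    "response_deg",
    "period_deg",
]

# positivity-constrained VP parameters compared on the log scale by default
LOG_COMPARE_PARAMS = ("J1_bar", "tau", "kappa_r", "J_slot")


@dataclass
class GroupComparison:
    """Two-sample comparison of one fitted parameter (sign: group2 - group1)."""

    parameter: str
    group1: str
    group2: str
    mean1: float
    sem1: float
    mean2: float
    sem2: float
    t: float
    df: float
    p: float
    cohen_d: float
    log_scale: bool
    n1: int
    n2: int


@dataclass
class SymptomCorrelation:
    scale: str
    r: float
    p: float
    n: int


def read_trials(path) -> list:
    """Parse a trial CSV into validated per-subject datasets.

    Every subject must use a single feature-space period; stimulus and
    response angles must lie in [0, period].  Schema violations raise with
    the offending rows named.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns {missing}")
    bad = df.index[
        (df["stimulus_deg"] < 0)
        | (df["stimulus_deg"] > df["period_deg"])
        | (df["response_deg"] < 0)
        | (df["response_deg"] > df["period_deg"])
    ]
    if len(bad):
        raise ValueError(f"angles outside [0, period] at rows {list(bad[:20])}")
    datasets = []
    for subject, sub in df.groupby("subject", sort=True):
        periods = sub["period_deg"].unique()
        if len(periods) != 1:
            raise ValueError(
                f"subject {subject!r} mixes periods {sorted(periods)} "
                f"(rows {list(sub.index[:20])})"
            )
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {subject!r} has multiple group labels {groups}")
        datasets.append(
            SubjectDataset(subject, groups[0], FeatureSpace(float(periods[0])), sub)
        )
    return datasets


def csd_summary(datasets) -> tuple:
    """(per subject x set size CSD table, per group x set size mean +- SEM)."""
    rows = []
    for ds in datasets:
        for N in ds.set_sizes:
            err = ds.trials.loc[ds.trials["set_size"] == N, "error_deg"]
            rows.append(
                {
                    "subject": ds.subject_id,
                    "group": ds.group,
                    "set_size": int(N),
                    "n_trials": len(err),
                    "csd_deg": circular_sd(err.to_numpy(), ds.space),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["group", "set_size"])["csd_deg"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return table, summary


def mixed_anova_csd(csd_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way mixed ANOVA on CSD: set size within, group between.

    Requires a complete balanced table (every subject at every level).
    Returns one row per effect with F, df, p and partial eta-squared.
    """
    counts = csd_table.groupby("subject")["set_size"].nunique()
    levels = csd_table["set_size"].nunique()
    incomplete = counts[counts != levels]
    if len(incomplete):
        raise ValueError(
            f"subjects missing set-size cells: {list(incomplete.index[:20])}"
        )
    aov = pg.mixed_anova(
        data=csd_table,
        dv="csd_deg",
        within="set_size",
        subject="subject",
        between="group",
    )
    out = aov.rename(
        columns={"Source": "effect", "p-unc": "p", "p_unc": "p", "np2": "partial_eta_sq"}
    )
    return out[["effect", "DF1", "DF2", "F", "p", "partial_eta_sq"]]


def _cohen_d(x1, x2):
    n1, n2 = len(x1), len(x2)
    sp = np.sqrt(
        ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1))
        / (n1 + n2 - 2)
    )
    if sp == 0:
        return 0.0
    return float((np.mean(x2) - np.mean(x1)) / sp)


def compare_group_parameters(
    fits_frame: pd.DataFrame,
    parameters=("J1_bar", "a", "tau", "kappa_r"),
    groups=("HC", "SZ"),
    welch: bool = False,
    log_scale: bool | None = None,
) -> list:
    """Two-sample tests on fitted parameters, one GroupComparison each.

    ``fits_frame`` is the wide table from :func:`fits_to_frame`, filtered to
    one model.  Positivity-constrained parameters are tested on the log
    scale by default (they are approximately log-normal across subjects);
    pass log_scale=False for raw-scale tests.  Default is the pooled
    two-sample t (df = n1 + n2 - 2); welch=True for unequal variances.
    Means/SEMs are reported on the natural scale either way.
    """
    g1, g2 = groups
    out = []
    for param in parameters:
        col = f"param_{param}"
        if col not in fits_frame.columns:
            raise ValueError(f"no fitted column {col!r} in fits frame")
        x1 = fits_frame.loc[fits_frame["group"] == g1, col].dropna().to_numpy(float)
        x2 = fits_frame.loc[fits_frame["group"] == g2, col].dropna().to_numpy(float)
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError(f"need >= 2 subjects per group for {param}")
        use_log = (
            param in LOG_COMPARE_PARAMS and np.all(x1 > 0) and np.all(x2 > 0)
            if log_scale is None
            else log_scale
        )
        t1, t2 = (np.log(x1), np.log(x2)) if use_log else (x1, x2)
        res = stats.ttest_ind(t2, t1, equal_var=not welch)
        df = (
            len(x1) + len(x2) - 2
            if not welch
            else float(res.df)
        )
        out.append(
            GroupComparison(
                parameter=param,
                group1=g1,
                group2=g2,
                mean1=float(np.mean(x1)),
                sem1=float(np.std(x1, ddof=1) / np.sqrt(len(x1))),
                mean2=float(np.mean(x2)),
                sem2=float(np.std(x2, ddof=1) / np.sqrt(len(x2))),
                t=float(res.statistic),
                df=float(df),
                p=float(res.pvalue),
                cohen_d=_cohen_d(t1, t2),
                log_scale=bool(use_log),
                n1=len(x1),
                n2=len(x2),
            )
        )
    return out


def correlate_symptoms(tau_by_subject: pd.Series, scores: pd.DataFrame) -> list:
    """Pearson r between fitted tau and each symptom scale.

    ``tau_by_subject`` indexed by subject id; ``scores`` has a 'subject'
    column plus one column per scale.  Missing scores are dropped pairwise;
    each scale needs >= 3 paired observations.  Zero-variance input yields
    r = nan flagged by p = nan.
    """
    out = []
    merged = scores.set_index("subject")
    for scale in [c for c in merged.columns]:
        paired = pd.concat(
            [tau_by_subject.rename("tau"), merged[scale].rename("score")],
            axis=1,
            join="inner",
        ).dropna()
        n = len(paired)
        if n < 3:
            raise ValueError(f"scale {scale!r} has {n} paired observations (< 3)")
        if paired["tau"].nunique() == 1 or paired["score"].nunique() == 1:
            out.append(SymptomCorrelation(scale, float("nan"), float("nan"), n))
            continue
        r, p = stats.pearsonr(paired["tau"], paired["score"])
        out.append(SymptomCorrelation(scale, float(r), float(p), n))
    return out


@dataclass
class PipelineConfig:
    """Full-run settings.

    Either ``data`` (trial CSV path) or ``preset`` (synthetic preset name,
    currently 'paper-color': the 61/60-subject color cohort) must be set.
    """

    data: str | None = None
    symptoms: str | None = None
    preset: str | None = None
    models: tuple = MODEL_NAMES
    restarts: int = 20
    maxiter: int = 400
    seed: int = 0
    out_dir: str | None = None
    tau_effect_d: float = 0.7
    n_hc: int = 61
    n_sz: int = 60
    trials_per_level: int = 80


def _cohort_from_preset(config: PipelineConfig):
    if config.preset != "paper-color":
        raise ValueError(f"unknown preset {config.preset!r}")
    design = TASK_PRESETS["color-main"]
    if config.trials_per_level != design.trials_per_level:
        design = TaskDesign(
            design.period_deg, design.set_sizes, config.trials_per_level, design.n_wheel
        )
    cc = CohortConfig(
        n_hc=config.n_hc,
        n_sz=config.n_sz,
        design=design,
        tau_effect_d=config.tau_effect_d,
    )
    return generate_cohort(cc, seed=config.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the report.

    The report bundle holds the CSD tables, ANOVA, per-subject fits, model
    comparison proportions, VP group comparisons and symptom correlations,
    plus an echo of every setting in effect.  Reruns with the same config
    and seed are bit-identical.
    """
    stage = "load"
    try:
        symptoms = None
        if config.preset is not None:
            cohort = _cohort_from_preset(config)
            datasets = cohort.datasets
            symptoms = cohort.symptoms
        elif config.data is not None:
            datasets = read_trials(config.data)
            cohort = None
        else:
            raise ValueError("config must set either 'data' or 'preset'")
        if config.symptoms is not None:
            symptoms = pd.read_csv(config.symptoms)

        stage = "csd"
        csd_table, csd_groups = csd_summary(datasets)
        anova = (
            mixed_anova_csd(csd_table)
            if csd_table["set_size"].nunique() > 1 and csd_table["group"].nunique() > 1
            else None
        )

        stage = "fit"
        fit_config = FitConfig(
            restarts=config.restarts, seed=config.seed, maxiter=config.maxiter
        )
        fits = []
        for ds in datasets:
            fits.extend(fit_all_models(ds, models=config.models, config=fit_config))
        fits_frame = fits_to_frame(fits)

        stage = "compare"
        winners, proportions = best_model_table(fits)

        stage = "group-tests"
        comparisons = []
        vp_frame = fits_frame[fits_frame["model"] == "VP"]
        if "VP" in config.models and vp_frame["group"].nunique() == 2:
            groups = sorted(vp_frame["group"].unique())
            comparisons = compare_group_parameters(vp_frame, groups=groups)

        stage = "symptoms"
        correlations = []
        if symptoms is not None and "VP" in config.models:
            tau = vp_frame.set_index("subject")["param_tau"]
            sz_subjects = set(symptoms["subject"])
            correlations = correlate_symptoms(
                tau[tau.index.isin(sz_subjects)], symptoms
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_subjects": len(datasets),
        "csd_group_summary": csd_groups.to_dict(orient="records"),
        "csd_anova": anova.to_dict(orient="records") if anova is not None else None,
        "model_winner_proportions": proportions.to_dict(orient="records"),
        "group_comparisons": [asdict(c) for c in comparisons],
        "symptom_correlations": [asdict(c) for c in correlations],
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csd_table.to_csv(out / "csd_by_subject.csv", index=False)
        fits_frame.to_csv(out / "fits.csv", index=False)
        fits_to_json(fits, out / "fits.json")
        winners.to_csv(out / "model_winners.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        if config.preset is not None:
            write_cohort(
                cohort,
                out / "trials.csv",
                truth_path=out / "ground_truth.json",
                symptoms_path=out / "symptoms.csv",
            )
    report["fits"] = fits_frame
    report["csd_table"] = csd_table
    report["winners"] = winners
    return report
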