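"""Synthetic task designs, subjects and two-group cohorts.

The study this package emulates measured 61 healthy controls (HC) and 60
people with schizophrenia (SZ) on a color delayed-estimation task (set
sizes 1 and 3, 80 trials each, 180 colors equally spaced on a 360 deg
wheel), plus control designs with set sizes 2/4/6 in color (360 deg) and
orientation (180 deg) spaces.  The subject data are not public, so this
module generates cohorts with the study's statistical structure: per-subject
observer-model parameters drawn log-normally around group means, a group
difference confined to the resource allocation variability tau, and symptom
scores (BPRS/SANS/SAPS-like) linearly coupled to tau with calibrated
Pearson correlations.

All randomness flows through integer seeds / numpy Generators; a fixed seed
reproduces a cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .circular import FeatureSpace, circular_sd
from .fitting import SubjectDataset
from .models import get_model, simulate_responses

__all__ = [
    "TaskDesign",
    "TASK_PRESETS",
    "GroupParams",
    "SymptomScale",
    "CohortConfig",
    "Cohort",
    "generate_task_trials",
    "generate_subject",
    "generate_cohort",
    "csd_vs_tau_simulation",
    "write_cohort",
]


@dataclass(frozen=True)
class TaskDesign:
    """A delayed-estimation task layout.

    trials_per_level trials at each set-size level; stimuli drawn uniformly
    from n_wheel equally spaced values on the feature space (sampled without
    replacement within a trial), probe uniform over the items.
    """

    period_deg: float
    set_sizes: tuple
    trials_per_level: int
    n_wheel: int = 180

    @property
    def space(self) -> FeatureSpace:
        return FeatureSpace(self.period_deg)

    @property
    def n_trials(self) -> int:
        return self.trials_per_level * len(self.set_sizes)

    @property
    def wheel_deg(self) -> np.ndarray:
        return np.arange(self.n_wheel) * (self.period_deg / self.n_wheel)


TASK_PRESETS = {
    # main color task: 2 blocks x 80 trials, set sizes 1 and 3
    "color-main": TaskDesign(360.0, (1, 3), 80, 180),
    # high-set-size color control: levels 2/4/6
    "color-high": TaskDesign(360.0, (2, 4, 6), 80, 180),
    # orientation control: levels 2/4/6 on a 180 deg space
    "orientation": TaskDesign(180.0, (2, 4, 6), 80, 180),
}


def generate_task_trials(design: TaskDesign, seed=None) -> pd.DataFrame:
    """Trial table: set_size, item stimuli (deg, lattice values), probe index.

    Columns: trial, set_size, probe_index, stimulus_deg (the probed item),
    item_stimuli_deg (semicolon-joined values of all items).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wheel = design.wheel_deg
    rows = []
    t = 0
    for N in design.set_sizes:
        for _ in range(design.trials_per_level):
            items = rng.choice(wheel, size=N, replace=N > len(wheel))
            probe = int(rng.integers(N))
            rows.append(
                {
                    "trial": t,
                    "set_size": int(N),
                    "probe_index": probe,
                    "stimulus_deg": float(items[probe]),
                    "item_stimuli_deg": ";".join(f"{v:g}" for v in items),
                }
            )
            t += 1
    return pd.DataFrame(rows)


def generate_subject(
    model, params, design: TaskDesign, seed=None, subject_id="sim", group="SIM"
) -> SubjectDataset:
    """Simulate one subject: task trials plus model-generated responses."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = model if not isinstance(model, str) else get_model(model, design.set_sizes)
    trials = generate_task_trials(design, rng)
    space = design.space
    stim_rad = space.to_rad(trials["stimulus_deg"].to_numpy())
    resp = simulate_responses(
        spec, params, list(zip(trials["set_size"], stim_rad)), seed=rng
    )
    resp_deg = np.mod(space.to_deg(resp), design.period_deg)
    table = trials[["set_size", "stimulus_deg", "item_stimuli_deg"]].copy()
    table["response_deg"] = resp_deg
    return SubjectDataset(subject_id, group, space, table)


@dataclass(frozen=True)
class GroupParams:
    """Log-normal population distribution of VP parameters for one group.

    ``mean`` maps parameter -> population mean on the natural scale;
    ``sigma_log`` maps parameter -> SD of the underlying normal on the log
    scale.  Draws are exp(N(mu, sigma)) with mu = ln(mean) - sigma^2/2 so the
    natural-scale mean is exact.
    """

    mean: dict = field(
        default_factory=lambda: {"J1_bar": 60.0, "a": 1.0, "tau": 15.0, "kappa_r": 150.0}
    )
    sigma_log: dict = field(
        default_factory=lambda: {"J1_bar": 0.5, "a": 0.3, "tau": 0.75, "kappa_r": 0.5}
    )

    def draw(self, rng, n) -> pd.DataFrame:
        cols = {}
        for name, m in self.mean.items():
            s = self.sigma_log[name]
            cols[name] = np.exp(rng.normal(np.log(m) - s**2 / 2.0, s, size=n))
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SymptomScale:
    """score = alpha + beta * tau + N(0, sigma), truncated at 0.

    beta is calibrated from the target Pearson r and the population SD of
    tau in the scored group so the marginal mean/SD match ``mean``/``sd``.
    Defaults below mirror the clinical scales of the emulated study.
    """

    name: str
    target_r: float
    mean: float
    sd: float


DEFAULT_SCALES = (
    SymptomScale("BPRS", 0.259, 27.25, 6.27),
    SymptomScale("SANS", 0.302, 24.43, 11.45),
    SymptomScale("SAPS", -0.121, 5.77, 7.02),
)


def _tau_scale_factor(d: float, sigma_log: float) -> float:
    """Multiplicative tau shift giving raw-scale Cohen's d between groups.

    For lognormal groups differing only by a factor f, solves
    (f - 1) = d * sqrt(e^{s^2} - 1) * sqrt((1 + f^2) / 2).
    """
    if d == 0:
        return 1.0
    cv = np.sqrt(np.exp(sigma_log**2) - 1.0)

    def g(f):
        return (f - 1.0) - d * cv * np.sqrt((1.0 + f * f) / 2.0)

    if d > 0:
        # as f -> inf the deficit grows once d*cv/sqrt(2) >= 1: no solution
        if g(1e3) < 0:
            raise ValueError(
                f"tau_effect_d={d:g} is infeasible for sigma_log={sigma_log:g} "
                f"(max attainable d is ~{np.sqrt(2.0) / cv:.2f})"
            )
        return brentq(g, 1.0, 1e3)
    return 1.0 / _tau_scale_factor(-d, sigma_log)


@dataclass
class CohortConfig:
    """Two-group synthetic cohort layout.

    The groups share every parameter distribution except tau, which is
    scaled in the second (patient-like) group to reach ``tau_effect_d``
    (Cohen's d on the natural tau scale).  Symptom scores exist for the
    patient-like group only.
    """

    n_hc: int = 61
    n_sz: int = 60
    model: str = "VP"
    design: TaskDesign = field(default_factory=lambda: TASK_PRESETS["color-main"])
    hc_params: GroupParams = field(default_factory=GroupParams)
    tau_effect_d: float = 0.7
    scales: tuple = DEFAULT_SCALES
    extra_params: dict = field(default_factory=dict)  # e.g. K for VPcap


@dataclass
class Cohort:
    datasets: list
    true_params: pd.DataFrame
    symptoms: pd.DataFrame
    achieved_r: dict
    config: CohortConfig
    seed: int


def _symptom_scores(tau, scales, rng):
    """Generate per-subject scores coupled to tau; returns (df, achieved r)."""
    tau = np.asarray(tau)
    out = {}
    achieved = {}
    sd_tau = float(np.std(tau, ddof=1))
    for sc in scales:
        if abs(sc.target_r) >= 1:
            raise ValueError(f"target correlation |r| must be < 1 for {sc.name}")
        if sd_tau == 0:
            raise ValueError("tau has zero variance; cannot couple scores")
        beta = sc.target_r * sc.sd / sd_tau
        sigma = sc.sd * np.sqrt(1.0 - sc.target_r**2)
        alpha = sc.mean - beta * float(np.mean(tau))
        score = alpha + beta * tau + rng.normal(0.0, sigma, size=tau.size)
        score = np.maximum(score, 0.0)
        out[sc.name] = score
        achieved[sc.name] = float(np.corrcoef(tau, score)[0, 1])
    return pd.DataFrame(out), achieved


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Draw a full two-group cohort with ground truth and symptom table."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    groups = []
    f = _tau_scale_factor(config.tau_effect_d, config.hc_params.sigma_log["tau"])
    for group, n in (("HC", config.n_hc), ("SZ", config.n_sz)):
        draws = config.hc_params.draw(rng, n)
        if group == "SZ":
            draws["tau"] = draws["tau"] * f
        draws.insert(0, "group", group)
        groups.append(draws)
    truth = pd.concat(groups, ignore_index=True)
    truth.insert(0, "subject", [f"{g}{i:03d}" for i, g in enumerate(truth["group"])])

    datasets = []
    for row in truth.itertuples(index=False):
        params = {k: getattr(row, k) for k in config.hc_params.mean}
        params.update(config.extra_params)
        datasets.append(
            generate_subject(
                get_model(config.model, config.design.set_sizes),
                params,
                config.design,
                seed=rng,
                subject_id=row.subject,
                group=row.group,
            )
        )

    sz = truth[truth["group"] == "SZ"]
    symptoms, achieved = _symptom_scores(sz["tau"].to_numpy(), config.scales, rng)
    symptoms.insert(0, "subject", sz["subject"].to_numpy())
    return Cohort(datasets, truth, symptoms, achieved, config, seed)


def csd_vs_tau_simulation(
    tau_grid=(2.0, 5.0, 10.0, 20.0, 40.0, 80.0),
    J1_grid=(20.0, 60.0, 180.0),
    a: float = 1.0,
    kappa_r: float = 150.0,
    n_per_cell: int = 4000,
    set_sizes=(1, 3),
    seed: int = 0,
    n_blocks: int = 8,
) -> pd.DataFrame:
    """Simulated circular SD of VP responses over a (tau, J1_bar) grid.

    For each (set size, J1_bar, tau) cell, n_per_cell responses are drawn
    from the VP observer and summarized by their CSD (degrees) plus a
    Monte-Carlo standard error from n_blocks block splits.  Larger tau at
    fixed resources yields larger response dispersion.
    """
    tau_grid, J1_grid = list(tau_grid), list(J1_grid)
    if not tau_grid or not J1_grid:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    spec = get_model("VP", set_sizes)
    space = FeatureSpace(360.0)
    rows = []
    for N in set_sizes:
        for J1 in J1_grid:
            for tau in tau_grid:
                params = dict(J1_bar=J1, a=a, tau=tau, kappa_r=kappa_r)
                resp = simulate_responses(
                    spec, params, [(N, 0.0)] * n_per_cell, seed=rng
                )
                err = space.to_deg(resp)
                csd = circular_sd(err, space)
                blocks = [
                    circular_sd(b, space)
                    for b in np.array_split(err, n_blocks)
                ]
                se = float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))
                rows.append(
                    {
                        "set_size": N,
                        "J1_bar": J1,
                        "tau": tau,
                        "csd_deg": csd,
                        "csd_se": se,
                        "n": n_per_cell,
                    }
                )
    return pd.DataFrame(rows)


def cohort_trials_frame(cohort: Cohort) -> pd.DataFrame:
    """All trials of a cohort in the pipeline's delimited-text schema."""
    frames = []
    for ds in cohort.datasets:
        df = ds.trials.copy()
        df.insert(0, "subject", ds.subject_id)
        df.insert(1, "group", ds.group)
        df["period_deg"] = ds.space.period_deg
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: Cohort, trials_path, truth_path=None, symptoms_path=None):
    """Write trials CSV (+ optional ground-truth JSON and symptom CSV)."""
    cohort_trials_frame(cohort).to_csv(trials_path, index=False)
    if symptoms_path is not None:
        cohort.symptoms.to_csv(symptoms_path, index=False)
    if truth_path is not None:
        payload = {
            "seed": cohort.seed,
            "achieved_r": cohort.achieved_r,
            "config": {
                "n_hc": cohort.config.n_hc,
                "n_sz": cohort.config.n_sz,
                "model": cohort.config.model,
                "tau_effect_d": cohort.config.tau_effect_d,
                "design": asdict(cohort.config.design),
                "hc_params": asdict(cohort.config.hc_params),
                "scales": [asdict(s) for s in cohort.config.scales],
            },
            "true_params": cohort.true_params.to_dict(orient="list"),
        }
        with open(truth_path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
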