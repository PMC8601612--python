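"""Per-subject maximum-likelihood fitting and model comparison.

Each observer model is fit to one subject's trials by multi-start
Nelder-Mead on transformed coordinates (log scale for the positive
precision-type parameters, identity for the decay exponent and bias terms),
with Latin-hypercube restarts plus one data-informed start.  Integer
capacity K is profiled out by an exhaustive grid with a continuous fit per
K; for IL, MIX and VPcap the likelihood is constant once K reaches the
largest set size, so the grid stops there (exact, not an approximation).

Model comparison uses AIC = -2 logL + 2k and BIC = -2 logL + k ln(n) per
subject, with ties broken by parameter count and then by a fixed model
order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .circular import FeatureSpace, bessel_ratio, circ_diff, _TABLES
from .models import K_MAX, MODEL_NAMES, ModelSpec, error_pdf, get_model

__all__ = [
    "SubjectDataset",
    "FitConfig",
    "FitResult",
    "negative_log_likelihood",
    "fit_mle",
    "fit_all_models",
    "information_criteria",
    "best_model_table",
    "fits_to_frame",
    "fits_to_json",
]

MIN_TRIALS_PER_SET_SIZE = 20

# fixed order used for deterministic tie-breaking in model comparison
_MODEL_ORDER = {name: i for i, name in enumerate(MODEL_NAMES)}


class SubjectDataset:
    """One subject's delayed-estimation trials.

    Holds trial rows (set size, stimulus and response in degrees) plus the
    derived signed circular error, and caches per-set-size radian arrays for
    the likelihood.  ``min_trials`` is the per-set-size floor required for
    fitting (checked by :func:`fit_mle`, configurable there).
    """

    def __init__(self, subject_id, group, space: FeatureSpace, trials: pd.DataFrame):
        required = {"set_size", "stimulus_deg", "response_deg"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        trials = trials.reset_index(drop=True).copy()
        trials["error_deg"] = circ_diff(
            trials["response_deg"].to_numpy(),
            trials["stimulus_deg"].to_numpy(),
            space,
        )
        self.subject_id = subject_id
        self.group = group
        self.space = space
        self.trials = trials
        self._by_N = {}
        for N, sub in trials.groupby("set_size"):
            self._by_N[int(N)] = (
                space.to_rad(sub["error_deg"].to_numpy()),
                space.to_rad(sub["stimulus_deg"].to_numpy()),
            )

    @property
    def set_sizes(self):
        return tuple(sorted(self._by_N))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def errors_rad(self, N: int):
        return self._by_N[int(N)][0]

    def stimuli_rad(self, N: int):
        return self._by_N[int(N)][1]


@dataclass
class FitConfig:
    """Settings for one maximum-likelihood fit.

    restarts: Latin-hypercube starts per (model, K) in addition to the
        data-informed start; published studies rarely report optimizer
        settings, so these are package defaults surfaced here.
    maxiter: Nelder-Mead iteration cap per start.
    converge_tol: best two starts must agree within this many log-likelihood
        units for the fit to be flagged converged.
    min_trials: per-set-size trial floor.
    bounds: optional per-parameter (lo, hi) overrides.
    """

    restarts: int = 20
    seed: int = 0
    maxiter: int = 400
    converge_tol: float = 0.5
    min_trials: int = MIN_TRIALS_PER_SET_SIZE
    n_quad: int = 50
    bounds: dict = field(default_factory=dict)


@dataclass
class FitResult:
    """MLE outcome for one subject x model."""

    subject_id: object
    group: object
    model: str
    params: dict
    log_likelihood: float
    n_trials: int
    k_params: int
    aic: float
    bic: float
    restarts: int
    converged: bool
    seed: int
    nfev: int = 0

    def to_dict(self):
        d = asdict(self)
        d["params"] = dict(self.params)
        return d


def negative_log_likelihood(model, params, dataset: SubjectDataset, n_quad=None) -> float:
    """-sum_t ln p_model(error_t | N_t, stimulus_t, params).

    Returns +inf (never NaN) if any trial has non-positive or non-finite
    density under the parameters.  n_quad overrides the VP-family
    quadrature resolution.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model, dataset.set_sizes)
    total = 0.0
    for N in dataset.set_sizes:
        err = dataset.errors_rad(N)
        stim = dataset.stimuli_rad(N) if spec.needs_stimulus else None
        try:
            dens = error_pdf(spec, err, N, params, stimulus=stim, n_quad=n_quad)
        except FloatingPointError:
            return math.inf
        if not np.all(np.isfinite(dens)) or np.any(dens <= 0.0):
            return math.inf
        total -= float(np.sum(np.log(dens)))
    return total


def information_criteria(logL: float, k: int, n: int):
    """(AIC, BIC) = (-2 logL + 2k, -2 logL + k ln n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * logL + 2.0 * k, -2.0 * logL + k * math.log(n)


def _untransform(spec: ModelSpec, x, bounds):
    """Optimizer -> natural coordinates, clipped to bounds."""
    out = {}
    for i, name in enumerate(spec.param_names):
        lo, hi = bounds[name]
        v = math.exp(min(x[i], 700.0)) if spec.log_scale(name) else x[i]
        out[name] = min(max(v, lo), hi)
    return out


def _data_informed_start(spec: ModelSpec, dataset: SubjectDataset, bounds):
    """A single heuristic start from the per-set-size error concentration."""
    kappa_hat = {}
    for N in dataset.set_sizes:
        err = dataset.errors_rad(N)
        R = min(float(np.abs(np.mean(np.exp(1j * err)))), 0.999)
        kappa_hat[N] = float(_TABLES.A_inv(np.atleast_1d(R))[0])
    n_min, n_max = min(kappa_hat), max(kappa_hat)
    k_small = max(kappa_hat[n_min], 1e-2)
    start = {}
    for name in spec.param_names:
        lo, hi = bounds[name]
        if name == "kappa_r":
            v = 2.0 * k_small
        elif name == "J1_bar":
            v = max(2.0 * k_small, 1.0)
        elif name == "a":
            v = 1.0
        elif name == "tau":
            v = max(k_small, 1.0)
        elif name == "J_slot":
            v = max(k_small, 1.0)
        elif name.startswith("kappa_N"):
            v = 2.0 * max(kappa_hat[int(name[7:])], 1e-2)
        else:  # bias amplitudes / phases
            v = 0.0
        start[name] = min(max(v, lo), hi)
    return np.array(
        [math.log(start[n]) if spec.log_scale(n) else start[n] for n in spec.param_names]
    )


def _fit_continuous(spec, dataset, bounds, starts, maxiter, fixed=None, n_quad=None):
    """Nelder-Mead from each start; returns (best_params, best_logL, per-start
    objective list, total nfev)."""
    fixed = fixed or {}

    def objective(x):
        params = _untransform(spec, x, bounds)
        params.update(fixed)
        return negative_log_likelihood(spec, params, dataset, n_quad=n_quad)

    best = (math.inf, None)
    values = []
    nfev = 0
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4},
        )
        nfev += res.nfev
        values.append(float(res.fun))
        if res.fun < best[0]:
            best = (float(res.fun), res.x)
    params = _untransform(spec, best[1], bounds)
    params.update(fixed)
    return params, -best[0], sorted(values), nfev


def _k_grid(spec: ModelSpec, dataset: SubjectDataset):
    max_N = max(dataset.set_sizes)
    if spec.name in ("IL", "MIX", "VPcap"):
        # likelihood saturates once K >= max set size
        return list(range(1, min(spec.k_max, max_N) + 1))
    return list(range(1, spec.k_max + 1))


def fit_mle(model, dataset: SubjectDataset, config: FitConfig | None = None) -> FitResult:
    """Maximum-likelihood fit of one model to one subject.

    Continuous parameters are optimized by multi-start Nelder-Mead on
    transformed coordinates; capacity K by exhaustive grid.  Reproducible
    for a fixed config.seed.  If every start fails the result carries
    converged=False with the best effort found.
    """
    config = config or FitConfig()
    spec = model if isinstance(model, ModelSpec) else get_model(model, dataset.set_sizes)
    for N in dataset.set_sizes:
        if len(dataset.errors_rad(N)) < config.min_trials:
            raise ValueError(
                f"set size {N} has fewer than {config.min_trials} trials"
            )
    bounds = {**spec.bounds, **{k: v for k, v in config.bounds.items() if k in spec.bounds}}

    dim = len(spec.param_names)
    sampler = qmc.LatinHypercube(d=dim, seed=config.seed)
    lo = np.array([
        math.log(bounds[n][0]) if spec.log_scale(n) else bounds[n][0]
        for n in spec.param_names
    ])
    hi = np.array([
        math.log(bounds[n][1]) if spec.log_scale(n) else bounds[n][1]
        for n in spec.param_names
    ])
    lhs = (
        qmc.scale(sampler.random(config.restarts), lo, hi)
        if config.restarts > 0
        else []
    )
    starts = [_data_informed_start(spec, dataset, bounds)] + list(lhs)

    best = None
    total_nfev = 0
    for K in (_k_grid(spec, dataset) if spec.has_capacity else [None]):
        fixed = {"K": K} if K is not None else {}
        params, logL, values, nfev = _fit_continuous(
            spec, dataset, bounds, starts, config.maxiter, fixed=fixed,
            n_quad=config.n_quad,
        )
        total_nfev += nfev
        if best is None or logL > best[1]:
            best = (params, logL, values)

    params, logL, values = best
    converged = (
        math.isfinite(logL)
        and len(values) >= 2
        and (values[1] - values[0]) <= config.converge_tol
    ) or (math.isfinite(logL) and len(values) == 1)
    aic, bic = information_criteria(logL, spec.n_params, dataset.n_trials)
    return FitResult(
        subject_id=dataset.subject_id,
        group=dataset.group,
        model=spec.name,
        params=params,
        log_likelihood=logL,
        n_trials=dataset.n_trials,
        k_params=spec.n_params,
        aic=aic,
        bic=bic,
        restarts=len(starts),
        converged=bool(converged),
        seed=config.seed,
        nfev=total_nfev,
    )


def fit_all_models(dataset, models=MODEL_NAMES, config=None, n_harmonics=2):
    """Fit each named model to the subject; returns a list of FitResult."""
    config = config or FitConfig()
    return [
        fit_mle(get_model(m, dataset.set_sizes, n_harmonics=n_harmonics), dataset, config)
        for m in models
    ]


def _winner(rows, crit):
    return min(rows, key=lambda r: (getattr(r, crit), r.k_params, _MODEL_ORDER[r.model]))


def best_model_table(fits):
    """Per-subject winning model and per-group winner proportions.

    Requires a FitResult for every (subject, model) pair; the winner
    minimizes the criterion, with exact ties broken by fewer parameters and
    then fixed model-name order.  Returns (winners, proportions) DataFrames,
    each covering both AIC and BIC.
    """
    by_subject = {}
    for f in fits:
        by_subject.setdefault(f.subject_id, []).append(f)
    models_seen = sorted({f.model for f in fits}, key=_MODEL_ORDER.get)
    gaps = {
        s: sorted(set(models_seen) - {f.model for f in rows}, key=_MODEL_ORDER.get)
        for s, rows in by_subject.items()
        if {f.model for f in rows} != set(models_seen)
    }
    if gaps:
        raise ValueError(f"missing fits for subjects: {gaps}")

    winners = pd.DataFrame(
        [
            {
                "subject": s,
                "group": rows[0].group,
                "aic_winner": _winner(rows, "aic").model,
                "bic_winner": _winner(rows, "bic").model,
            }
            for s, rows in sorted(by_subject.items(), key=lambda kv: str(kv[0]))
        ]
    )
    records = []
    for group, sub in winners.groupby("group"):
        for model in models_seen:
            records.append(
                {
                    "group": group,
                    "model": model,
                    "aic_prop": float((sub["aic_winner"] == model).mean()),
                    "bic_prop": float((sub["bic_winner"] == model).mean()),
                }
            )
    return winners, pd.DataFrame(records)


def fits_to_frame(fits) -> pd.DataFrame:
    """One row per subject x model; parameters as their own columns."""
    rows = []
    for f in fits:
        row = {
            "subject": f.subject_id,
            "group": f.group,
            "model": f.model,
            "log_likelihood": f.log_likelihood,
            "n_trials": f.n_trials,
            "k_params": f.k_params,
            "aic": f.aic,
            "bic": f.bic,
            "restarts": f.restarts,
            "converged": f.converged,
            "seed": f.seed,
        }
        row.update({f"param_{k}": v for k, v in f.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def fits_to_json(fits, path):
    """Full diagnostics as JSON (list of FitResult dicts)."""
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fits], fh, indent=1, default=float)
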