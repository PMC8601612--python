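"""Generative observer models for delayed-estimation working memory.

Seven models of how a reported feature value deviates from the true value
of the probed item, all expressed as densities of the signed circular
response error (internal radians) given the set size N:

IL      item limit: fixed capacity K, fixed response concentration kappa_r;
        probing an unstored item yields a uniform random guess.
MIX     as IL but with a separate concentration per set size.
SA      slots-plus-averaging: K discrete slots each worth J_slot of
        precision, spread as evenly as possible over the items.
cosSA   SA with a stimulus-dependent periodic response bias.
EP      equal precision: continuous resource J1_bar * N^-a per item, same
        on every trial.
VP      variable precision: the per-trial resource J is gamma-distributed
        with mean J1_bar * N^-a and scale tau.
VPcap   VP with an explicit item limit K on top.

Models with a sensory stage convolve the sensory von Mises noise
(concentration from the Fisher-information resource J) with the choice
stage VM(kappa_r) via the moment-matched rule in :mod:`vpwm.circular`.
Each model exposes a density and a forward sampler drawn from the identical
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .circular import (
    TWO_PI,
    J_to_kappa,
    vm_convolve_kappa,
    vm_pdf,
    vm_sample,
    wrap_angle,
)

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "get_model",
    "resource_decay",
    "il_error_pdf",
    "mix_error_pdf",
    "sa_error_pdf",
    "cossa_error_pdf",
    "ep_error_pdf",
    "vp_error_pdf",
    "vpcap_error_pdf",
    "error_pdf",
    "simulate_responses",
]

MODEL_NAMES = ("IL", "MIX", "SA", "cosSA", "EP", "VP", "VPcap")

K_MAX = 8
N_QUAD = 100  # Gauss-Legendre nodes for the VP gamma marginalization

DEFAULT_BOUNDS = {
    "J1_bar": (0.5, 500.0),
    "a": (0.0, 5.0),
    "tau": (0.1, 200.0),
    "kappa_r": (1.0, 500.0),
    "J_slot": (0.5, 200.0),
    "kappa_N": (1.0, 500.0),
    "amp": (-0.35, 0.35),   # bias harmonic amplitude, radians
    "phase": (-np.pi, np.pi),
}

_LOG_SCALE_PARAMS = ("J1_bar", "tau", "kappa_r", "J_slot", "kappa_N")


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one observer model.

    ``param_names`` lists the continuous parameters in optimization order
    (capacity K is handled separately by exhaustive grid).  ``bounds`` maps
    each continuous parameter to (lower, upper).  ``needs_stimulus`` is True
    only for cosSA, whose bias depends on the probed stimulus value.
    """

    name: str
    param_names: tuple
    bounds: dict
    has_capacity: bool
    needs_stimulus: bool = False
    set_sizes: tuple = ()
    n_harmonics: int = 0
    k_max: int = K_MAX

    @property
    def n_params(self) -> int:
        """Total free-parameter count (continuous + capacity if present)."""
        return len(self.param_names) + (1 if self.has_capacity else 0)

    def log_scale(self, name: str) -> bool:
        """Whether the parameter is optimized on a log scale."""
        return name.startswith("kappa_N") or name in _LOG_SCALE_PARAMS


def get_model(
    name: str,
    set_sizes=(1, 3),
    n_harmonics: int = 2,
    k_max: int = K_MAX,
) -> ModelSpec:
    """Build the ModelSpec for one of the seven models.

    MIX needs the task's set-size levels (one concentration each); cosSA
    needs the number of bias harmonics (default 2: amplitude and phase per
    harmonic).
    """
    set_sizes = tuple(sorted(int(n) for n in set_sizes))
    b = DEFAULT_BOUNDS
    if name == "IL":
        return ModelSpec("IL", ("kappa_r",), {"kappa_r": b["kappa_r"]},
                         True, set_sizes=set_sizes, k_max=k_max)
    if name == "MIX":
        names = tuple(f"kappa_N{n}" for n in set_sizes)
        return ModelSpec("MIX", names, {p: b["kappa_N"] for p in names},
                         True, set_sizes=set_sizes, k_max=k_max)
    if name == "SA":
        names = ("J_slot", "kappa_r")
        return ModelSpec("SA", names, {p: b[p] for p in names},
                         True, set_sizes=set_sizes, k_max=k_max)
    if name == "cosSA":
        names = ["J_slot", "kappa_r"]
        bounds = {"J_slot": b["J_slot"], "kappa_r": b["kappa_r"]}
        for h in range(1, n_harmonics + 1):
            names += [f"amp_{h}", f"phase_{h}"]
            bounds[f"amp_{h}"] = b["amp"]
            bounds[f"phase_{h}"] = b["phase"]
        return ModelSpec("cosSA", tuple(names), bounds, True,
                         needs_stimulus=True, set_sizes=set_sizes,
                         n_harmonics=n_harmonics, k_max=k_max)
    if name == "EP":
        names = ("J1_bar", "a", "kappa_r")
        return ModelSpec("EP", names, {p: b[p] for p in names},
                         False, set_sizes=set_sizes)
    if name == "VP":
        names = ("J1_bar", "a", "tau", "kappa_r")
        return ModelSpec("VP", names, {p: b[p] for p in names},
                         False, set_sizes=set_sizes)
    if name == "VPcap":
        names = ("J1_bar", "a", "tau", "kappa_r")
        return ModelSpec("VPcap", names, {p: b[p] for p in names},
                         True, set_sizes=set_sizes, k_max=k_max)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def resource_decay(J1_bar: float, a: float, N) -> float:
    """Mean resource per item: J_bar(N) = J1_bar * N**(-a)."""
    if J1_bar <= 0:
        raise ValueError("J1_bar must be > 0")
    if a < 0:
        raise ValueError("a must be >= 0")
    N = np.asarray(N, dtype=float)
    if np.any(N < 1):
        raise ValueError("set size must be >= 1")
    return J1_bar * N ** (-a)


def _check_capacity(K, k_max=K_MAX):
    if not float(K).is_integer() or not (1 <= K <= k_max):
        raise ValueError(f"K must be an integer in [1, {k_max}], got {K}")
    return int(K)


def _guess_mix(dens_stored, p_stored):
    return p_stored * dens_stored + (1.0 - p_stored) / TWO_PI


def il_error_pdf(error, N: int, params) -> np.ndarray:
    """Item-limit density: (1-g) VM(kappa_r) + g/(2 pi), g = max(0, 1-K/N)."""
    K = _check_capacity(params["K"])
    p_stored = min(1.0, K / N)
    return _guess_mix(vm_pdf(error, 0.0, params["kappa_r"]), p_stored)


def mix_error_pdf(error, N: int, params) -> np.ndarray:
    """IL with a set-size-specific response concentration kappa_N."""
    K = _check_capacity(params["K"])
    key = f"kappa_N{int(N)}"
    if key not in params:
        raise ValueError(
            f"MIX model has no concentration for set size {N} "
            f"(available: {[k for k in params if k.startswith('kappa_N')]})"
        )
    p_stored = min(1.0, K / N)
    return _guess_mix(vm_pdf(error, 0.0, params[key]), p_stored)


def _sa_components(N: int, K: int, J_slot: float, kappa_r: float):
    """(weights, convolved concentrations) of the SA mixture at set size N."""
    if J_slot <= 0:
        raise ValueError("J_slot must be > 0")
    if N > K:
        kc = vm_convolve_kappa(J_to_kappa(J_slot), kappa_r)
        return [(K / N, kc), (1.0 - K / N, 0.0)]
    s_low = K // N
    p_high = (K % N) / N
    comps = []
    if p_high > 0:
        kc_hi = vm_convolve_kappa(J_to_kappa((s_low + 1) * J_slot), kappa_r)
        comps.append((p_high, kc_hi))
    kc_lo = vm_convolve_kappa(J_to_kappa(s_low * J_slot), kappa_r)
    comps.append((1.0 - p_high, kc_lo))
    return comps


def sa_error_pdf(error, N: int, params) -> np.ndarray:
    """Slots-plus-averaging density.

    With N > K a probed item holds one slot with probability K/N and none
    otherwise (uniform guess).  With N <= K the K slots are spread as evenly
    as possible: K mod N items get floor(K/N)+1 slots, the rest floor(K/N);
    an item with s slots is encoded with precision s * J_slot, convolved
    with the choice stage kappa_r.
    """
    K = _check_capacity(params["K"])
    error = np.asarray(error, dtype=float)
    dens = np.zeros_like(error, dtype=float)
    for w, kc in _sa_components(N, K, params["J_slot"], params["kappa_r"]):
        dens += w * vm_pdf(error, 0.0, kc)
    return dens


def _bias(stimulus, params, n_harmonics: int):
    """Periodic response bias b(s) = sum_h amp_h * sin(h*s + phase_h), rad."""
    stimulus = np.asarray(stimulus, dtype=float)
    b = np.zeros_like(stimulus)
    for h in range(1, n_harmonics + 1):
        b += params[f"amp_{h}"] * np.sin(h * stimulus + params[f"phase_{h}"])
    return b


def cossa_error_pdf(error, stimulus, N: int, params, n_harmonics: int = 2):
    """SA with VM components recentered on the stimulus-dependent bias."""
    if stimulus is None:
        raise ValueError("cosSA requires the probed stimulus value")
    K = _check_capacity(params["K"])
    error = np.asarray(error, dtype=float)
    shifted = error - _bias(stimulus, params, n_harmonics)
    dens = np.zeros_like(error, dtype=float)
    for w, kc in _sa_components(N, K, params["J_slot"], params["kappa_r"]):
        dens += w * vm_pdf(shifted, 0.0, kc)
    return dens


def ep_error_pdf(error, N: int, params) -> np.ndarray:
    """Equal-precision density: one VM at the convolved concentration."""
    J_bar = resource_decay(params["J1_bar"], params["a"], N)
    kc = vm_convolve_kappa(J_to_kappa(J_bar), params["kappa_r"])
    return vm_pdf(error, 0.0, kc)


def _gl_quantiles(n: int):
    """Gauss-Legendre nodes/weights mapped to (0, 1); cached."""
    if n not in _gl_quantiles._cache:
        x, w = np.polynomial.legendre.leggauss(n)
        _gl_quantiles._cache[n] = ((x + 1.0) / 2.0, w / 2.0)
    return _gl_quantiles._cache[n]


_gl_quantiles._cache = {}


def _vp_component_kappas(N, J1_bar, a, tau, kappa_r, n_quad):
    """Quadrature weights and convolved concentrations for the VP mixture.

    The gamma over J is integrated on its quantile scale (u in (0,1),
    J = Q_gamma(u)), which stays accurate for small shape J_bar/tau.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    J_bar = resource_decay(J1_bar, a, N)
    u, w = _gl_quantiles(n_quad)
    J = gamma_dist.ppf(u, a=J_bar / tau, scale=tau)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError(
            f"gamma quantiles non-finite at shape={J_bar / tau:g}, scale={tau:g}"
        )
    kc = vm_convolve_kappa(J_to_kappa(J), kappa_r)
    return w, kc


def vp_error_pdf(error, N: int, params, n_quad: int = N_QUAD) -> np.ndarray:
    """Variable-precision density.

    Marginalizes the von Mises error over the gamma distribution of the
    per-trial resource J (mean J1_bar * N^-a, scale tau) by fixed-node
    Gauss-Legendre quadrature on the gamma quantile scale.
    """
    w, kc = _vp_component_kappas(
        N, params["J1_bar"], params["a"], params["tau"], params["kappa_r"], n_quad
    )
    error = np.atleast_1d(np.asarray(error, dtype=float))
    dens = w @ vm_pdf(error[None, :], 0.0, kc[:, None])
    if not np.all(np.isfinite(dens)):
        raise FloatingPointError("VP quadrature produced non-finite density")
    return dens


def vpcap_error_pdf(error, N: int, params, n_quad: int = N_QUAD) -> np.ndarray:
    """VP with capacity K: min(1, K/N) VP + max(0, 1-K/N) uniform."""
    K = _check_capacity(params["K"])
    p_stored = min(1.0, K / N)
    return _guess_mix(vp_error_pdf(error, N, params, n_quad=n_quad), p_stored)


def error_pdf(model: ModelSpec, error, N: int, params, stimulus=None, n_quad=None):
    """Dispatch to the named model's error density (errors in radians).

    n_quad overrides the VP-family quadrature resolution (default 100
    nodes); the other models ignore it.
    """
    name = model.name if isinstance(model, ModelSpec) else model
    nq = N_QUAD if n_quad is None else n_quad
    if name == "IL":
        return il_error_pdf(error, N, params)
    if name == "MIX":
        return mix_error_pdf(error, N, params)
    if name == "SA":
        return sa_error_pdf(error, N, params)
    if name == "cosSA":
        nh = model.n_harmonics if isinstance(model, ModelSpec) else 2
        return cossa_error_pdf(error, stimulus, N, params, n_harmonics=nh)
    if name == "EP":
        return ep_error_pdf(error, N, params)
    if name == "VP":
        return vp_error_pdf(error, N, params, n_quad=nq)
    if name == "VPcap":
        return vpcap_error_pdf(error, N, params, n_quad=nq)
    raise ValueError(f"unknown model {name!r}")


def simulate_responses(model, params, trials, seed=None):
    """Draw one response per trial from the model's generative process.

    ``trials`` is a sequence of (set_size, stimulus_rad) pairs; the return
    value is the array of response angles (radians, wrapped).  For VP-family
    models the resource J is drawn fresh on every trial — this is the
    across-trial allocation variability, which operates even at set size 1.
    Reproducible for a fixed seed.
    """
    name = model.name if isinstance(model, ModelSpec) else model
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = list(trials)
    n = len(trials)
    Ns = np.array([int(t[0]) for t in trials])
    stims = np.array([float(t[1]) for t in trials])
    responses = np.empty(n)

    for N in np.unique(Ns):
        idx = np.where(Ns == N)[0]
        m = idx.size
        s = stims[idx]
        if name in ("IL", "MIX"):
            K = _check_capacity(params["K"])
            kappa = params["kappa_r"] if name == "IL" else params[f"kappa_N{int(N)}"]
            stored = rng.random(m) < min(1.0, K / N)
            err = np.where(
                stored,
                vm_sample(0.0, kappa, m, rng),
                rng.uniform(-np.pi, np.pi, m),
            )
        elif name in ("SA", "cosSA"):
            K = _check_capacity(params["K"])
            comps = _sa_components(N, K, params["J_slot"], params["kappa_r"])
            weights = np.array([w for w, _ in comps])
            kcs = np.array([kc for _, kc in comps])
            which = rng.choice(len(comps), size=m, p=weights)
            err = wrap_angle(rng.vonmises(0.0, kcs[which]))
            if name == "cosSA":
                nh = model.n_harmonics if isinstance(model, ModelSpec) else 2
                err = err + _bias(s, params, nh)
        elif name == "EP":
            J_bar = resource_decay(params["J1_bar"], params["a"], N)
            kc = vm_convolve_kappa(J_to_kappa(J_bar), params["kappa_r"])
            err = vm_sample(0.0, kc, m, rng)
        elif name in ("VP", "VPcap"):
            J_bar = resource_decay(params["J1_bar"], params["a"], N)
            tau = params["tau"]
            if tau <= 0:
                raise ValueError("tau must be > 0")
            J = rng.gamma(shape=J_bar / tau, scale=tau, size=m)
            kc = vm_convolve_kappa(J_to_kappa(J), params["kappa_r"])
            err = wrap_angle(rng.vonmises(0.0, kc))
            if name == "VPcap":
                K = _check_capacity(params["K"])
                guess = rng.random(m) >= min(1.0, K / N)
                err[guess] = rng.uniform(-np.pi, np.pi, guess.sum())
        else:
            raise ValueError(f"unknown model {name!r}")
        responses[idx] = wrap_angle(s + err)
    return responses
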