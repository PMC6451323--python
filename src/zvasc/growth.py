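"""Growth models for developing vascular volume.

Vascular volume in the embryo rises slowly, accelerates to a peak growth
rate around day one of development, then saturates. Classical saturating
models (Gompertz, logistic, Weibull, Richards) underfit the early hours;
models built on a logarithmic rescaling of time — the scaled cumulative
log-logistic and log-normal models — capture the full course. Both carry
an offset ``A`` (volume already formed at the start of observation, the
lower asymptote) and a scale ``V_L`` (asymptotic added volume), plus two
shape parameters:

    log-logistic:  V(t) = A + V_L / (1 + (t/α)^(−β))
    log-normal:    V(t) = A + V_L · Φ((ln t − µ)/σ)

with Φ the standard normal CDF, α > 0 the time scale, β > 0 the shape,
and µ, σ the mean and s.d. of log time. The comparison models use the
same A/V_L asymptote semantics:

    Gompertz:  A + V_L · exp(−exp(−k(t−t_i)))
    logistic:  A + V_L / (1 + exp(−k(t−t_i)))
    Weibull:   A + V_L · (1 − exp(−(t/λ)^k))
    Richards:  A + V_L · (1 + ν·exp(−k(t−t_i)))^(−1/ν)

Fitting minimizes the residual sum of squares with Levenberg–Marquardt on
log-transformed positive parameters, from a data-driven initialization
plus seeded multiplicative-jitter restarts; model comparison ranks fits
by RSS. Growth-rate curves dV/dt are analytic, and peak growth times use
closed forms where they exist (log-logistic, log-normal, Gompertz,
logistic) and a numeric argmax otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthFit",
    "MODELS",
    "model_value",
    "model_rate",
    "fit_growth_model",
    "compare_models",
    "peak_growth_time",
]

N_RESTARTS_DEFAULT = 10
_JITTER_SD = 0.3  # multiplicative log-normal jitter on restart initializations


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------

def _ll_value(t, A, V_L, alpha, beta):
    return A + V_L / (1.0 + (t / alpha) ** (-beta))


def _ll_rate(t, A, V_L, alpha, beta):
    u = (t / alpha) ** beta
    return V_L * (beta / alpha) * (t / alpha) ** (beta - 1.0) / (1.0 + u) ** 2


def _ll_peak(A, V_L, alpha, beta):
    if beta <= 1.0:
        return None  # rate is monotone decreasing: no interior maximum
    return alpha * ((beta - 1.0) / (beta + 1.0)) ** (1.0 / beta)


def _ln_value(t, A, V_L, mu, sigma):
    return A + V_L * stats.norm.cdf((np.log(t) - mu) / sigma)


def _ln_rate(t, A, V_L, mu, sigma):
    z = (np.log(t) - mu) / sigma
    return V_L * np.exp(-0.5 * z * z) / (t * sigma * math.sqrt(2.0 * math.pi))


def _ln_peak(A, V_L, mu, sigma):
    return math.exp(mu - sigma * sigma)


def _gompertz_value(t, A, V_L, k, t_i):
    return A + V_L * np.exp(-np.exp(-k * (t - t_i)))


def _gompertz_rate(t, A, V_L, k, t_i):
    e = np.exp(-k * (t - t_i))
    return V_L * k * e * np.exp(-e)


def _logistic_value(t, A, V_L, k, t_i):
    return A + V_L / (1.0 + np.exp(-k * (t - t_i)))


def _logistic_rate(t, A, V_L, k, t_i):
    e = np.exp(-k * (t - t_i))
    return V_L * k * e / (1.0 + e) ** 2


def _weibull_value(t, A, V_L, lam, k):
    return A + V_L * (1.0 - np.exp(-((t / lam) ** k)))


def _weibull_rate(t, A, V_L, lam, k):
    u = (t / lam) ** k
    return V_L * (k / lam) * (t / lam) ** (k - 1.0) * np.exp(-u)


def _richards_value(t, A, V_L, k, t_i, nu):
    return A + V_L * (1.0 + nu * np.exp(-k * (t - t_i))) ** (-1.0 / nu)


def _richards_rate(t, A, V_L, k, t_i, nu):
    e = np.exp(-k * (t - t_i))
    return V_L * k * e * (1.0 + nu * e) ** (-1.0 / nu - 1.0)


@dataclass(frozen=True)
class _ModelDef:
    param_names: tuple
    value: callable
    rate: callable
    positive: tuple  # parameters constrained > 0 (fit in log space)
    peak: callable | None = None


MODELS: dict[str, _ModelDef] = {
    "log_logistic": _ModelDef(
        ("A", "V_L", "alpha", "beta"), _ll_value, _ll_rate,
        ("V_L", "alpha", "beta"), _ll_peak,
    ),
    "log_normal": _ModelDef(
        ("A", "V_L", "mu", "sigma"), _ln_value, _ln_rate,
        ("V_L", "sigma"), _ln_peak,
    ),
    "gompertz": _ModelDef(
        ("A", "V_L", "k", "t_i"), _gompertz_value, _gompertz_rate,
        ("V_L", "k"), lambda A, V_L, k, t_i: t_i,
    ),
    "logistic": _ModelDef(
        ("A", "V_L", "k", "t_i"), _logistic_value, _logistic_rate,
        ("V_L", "k"), lambda A, V_L, k, t_i: t_i,
    ),
    "weibull": _ModelDef(
        ("A", "V_L", "lam", "k"), _weibull_value, _weibull_rate,
        ("V_L", "lam", "k"), None,
    ),
    "richards": _ModelDef(
        ("A", "V_L", "k", "t_i", "nu"), _richards_value, _richards_rate,
        ("V_L", "k", "nu"), None,
    ),
}

_LOG_TIME_MODELS = ("log_logistic", "log_normal")


def _check_params(model_id: str, params: dict) -> None:
    mdef = _models_get(model_id)
    missing = set(mdef.param_names) - set(params)
    if missing:
        raise ValueError(f"{model_id}: missing parameters {sorted(missing)}")
    for name in mdef.positive:
        if not params[name] > 0:
            raise ValueError(f"{model_id}: parameter {name} must be > 0")


def _models_get(model_id: str) -> _ModelDef:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model {model_id!r}; choose from {sorted(MODELS)}"
        ) from None


def model_value(model_id: str, params: dict, t) -> np.ndarray:
    """Cumulative volume V(t) for a growth model.

    ``t`` is in hours post fertilization and must be > 0 for the
    log-time models.
    """
    _check_params(model_id, params)
    mdef = MODELS[model_id]
    t = np.asarray(t, dtype=np.float64)
    if model_id in _LOG_TIME_MODELS and np.any(t <= 0):
        raise ValueError(f"{model_id} requires t > 0")
    return mdef.value(t, *(params[n] for n in mdef.param_names))


def model_rate(model_id: str, params: dict, t) -> np.ndarray:
    """Growth rate dV/dt (analytic derivative of :func:`model_value`)."""
    _check_params(model_id, params)
    mdef = MODELS[model_id]
    t = np.asarray(t, dtype=np.float64)
    if model_id in _LOG_TIME_MODELS and np.any(t <= 0):
        raise ValueError(f"{model_id} requires t > 0")
    return mdef.rate(t, *(params[n] for n in mdef.param_names))


def peak_growth_time(model_id: str, params: dict):
    """Time of maximal growth rate, t* = argmax dV/dt.

    Closed forms: log-logistic t* = α((β−1)/(β+1))^(1/β) (requires
    β > 1, otherwise the rate decreases monotonically and ``None`` is
    returned with a boundary warning semantics left to the caller);
    log-normal t* = exp(µ − σ²); Gompertz and logistic t* = t_i.
    Weibull and Richards use a numeric argmax of the rate.
    """
    _check_params(model_id, params)
    mdef = MODELS[model_id]
    args = tuple(params[n] for n in mdef.param_names)
    if mdef.peak is not None:
        return mdef.peak(*args)
    return _numeric_peak(model_id, params)


def _numeric_peak(model_id: str, params: dict, t_lo=1e-3, t_hi=1e4) -> float:
    """Grid scan + bounded refinement of argmax dV/dt."""
    grid = np.geomspace(t_lo, t_hi, 2000)
    rates = model_rate(model_id, params, grid)
    k = int(np.argmax(rates))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -model_rate(model_id, params, t),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GrowthFit:
    """A fitted growth model: parameters, RSS and convergence status."""

    model_id: str
    params: dict
    rss: float
    n_obs: int
    converged: bool
    n_restarts_used: int = 0
    residuals: np.ndarray | None = field(default=None, repr=False)
    flags: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(MODELS[self.model_id].param_names)


def _to_internal(mdef: _ModelDef, params: np.ndarray) -> np.ndarray:
    out = params.copy()
    for i, n in enumerate(mdef.param_names):
        if n in mdef.positive:
            out[i] = np.log(max(params[i], 1e-300))
    return out


def _from_internal(mdef: _ModelDef, theta: np.ndarray) -> np.ndarray:
    out = theta.copy()
    for i, n in enumerate(mdef.param_names):
        if n in mdef.positive:
            out[i] = np.exp(min(theta[i], 700.0))
    return out


def _initial_params(model_id: str, t: np.ndarray, v: np.ndarray) -> dict:
    """Data-driven starting point: asymptotes from the range, time scales
    from the half-rise, shapes from the interquartile rise span."""
    A0 = float(v.min())
    VL0 = float(max(v.max() - v.min(), 1e-8 * max(abs(v.max()), 1.0), 1e-12))

    def rise_time(q):
        # first time the series crosses A0 + q*VL0, linearly interpolated
        target = A0 + q * VL0
        above = np.nonzero(v >= target)[0]
        if len(above) == 0:
            return t[-1]
        k = above[0]
        if k == 0 or v[k] == v[k - 1]:
            return t[k]
        frac = (target - v[k - 1]) / (v[k] - v[k - 1])
        return t[k - 1] + frac * (t[k] - t[k - 1])

    t50 = max(rise_time(0.5), 1e-6)
    t25 = max(rise_time(0.25), 1e-6)
    t75 = max(rise_time(0.75), t25 * (1 + 1e-6))

    if model_id == "log_logistic":
        beta0 = math.log(9.0) / max(math.log(t75 / t25), 1e-3)
        return {"A": A0, "V_L": VL0, "alpha": t50, "beta": beta0}
    if model_id == "log_normal":
        sigma0 = max(math.log(t75 / t25) / (2 * 0.6745), 1e-3)
        return {"A": A0, "V_L": VL0, "mu": math.log(t50), "sigma": sigma0}
    # non-log-time models: slope scale from the central rise
    k0 = max(VL0 / max(2.0 * (t75 - t25), 1e-6) * 4.0 / VL0, 1e-3)
    if model_id in ("gompertz", "logistic"):
        return {"A": A0, "V_L": VL0, "k": k0, "t_i": t50}
    if model_id == "weibull":
        k_shape = math.log(9.0) / max(math.log(t75 / t25), 1e-3)
        lam0 = t50 / (math.log(2.0) ** (1.0 / max(k_shape, 1e-3)))
        return {"A": A0, "V_L": VL0, "lam": lam0, "k": k_shape}
    if model_id == "richards":
        return {"A": A0, "V_L": VL0, "k": k0, "t_i": t50, "nu": 1.0}
    raise ValueError(f"unknown model {model_id!r}")


def fit_growth_model(
    series,
    model_id: str,
    init: dict | None = None,
    n_restarts: int = N_RESTARTS_DEFAULT,
    seed: int = 0,
) -> GrowthFit:
    """Nonlinear least-squares fit of a growth model to a volume series.

    ``series`` is anything with ``times`` and ``volumes`` attributes (a
    :class:`zvasc.quantify.VolumeSeries`) or a ``(times, volumes)`` pair.
    Positive parameters are log-transformed so Levenberg–Marquardt runs
    unconstrained; the data-driven initialization is refined from
    ``n_restarts`` multiplicatively jittered starting points (fixed
    ``seed``) and the lowest-RSS solution is kept. Non-convergence never
    raises: the best attempt is returned with ``converged=False``.
    """
    t, v = _series_arrays(series)
    mdef = _models_get(model_id)
    n_free = len(mdef.param_names)
    if len(t) <= n_free:
        raise ValueError(
            f"need more than {n_free} observations to fit {model_id}, got {len(t)}"
        )
    if model_id in _LOG_TIME_MODELS and np.any(t <= 0):
        raise ValueError(f"{model_id} requires strictly positive times")

    base = dict(init) if init is not None else _initial_params(model_id, t, v)
    _check_params(model_id, base)
    base_vec = np.array([base[n] for n in mdef.param_names], dtype=np.float64)
    rng = np.random.default_rng(seed)

    def residual(theta):
        p = _from_internal(mdef, theta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            pred = mdef.value(t, *p)
        pred = np.nan_to_num(pred, nan=1e12, posinf=1e12, neginf=-1e12)
        return pred - v

    best = None
    n_used = 0
    for trial in range(n_restarts + 1):
        vec = base_vec.copy()
        if trial > 0:
            jitter = rng.lognormal(0.0, _JITTER_SD, size=vec.shape)
            vec = np.where(vec != 0, vec * jitter, rng.normal(0.0, _JITTER_SD, vec.shape))
            # keep positive parameters positive under jitter
            for i, name in enumerate(mdef.param_names):
                if name in mdef.positive and vec[i] <= 0:
                    vec[i] = abs(base_vec[i]) * jitter[i] + 1e-9
        theta0 = _to_internal(mdef, vec)
        try:
            res = optimize.least_squares(residual, theta0, method="lm", xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12, max_nfev=5000)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15 * (1 + best[0]):
            best = (rss, res, trial)
        n_used = trial
        # a near-perfect fit needs no further restarts
        if best[0] <= 1e-20 * max(1.0, float(np.sum(v**2))):
            break

    if best is None:
        return GrowthFit(model_id, base, float(np.sum((v - v.mean()) ** 2)),
                         len(t), False, n_used, flags=["all_restarts_failed"])

    rss, res, _ = best
    p = _from_internal(mdef, res.x)
    params = {n: float(val) for n, val in zip(mdef.param_names, p)}
    flags = []
    v_span = float(v.max() - v.min())
    if params["V_L"] <= 1e-6 * max(abs(v).max(), 1.0) or (
        v_span > 0 and params["V_L"] < 1e-3 * v_span
    ) or v_span == 0:
        flags.append("V_L_boundary")
    converged = bool(res.success) and np.all(np.isfinite(p))
    return GrowthFit(model_id, params, rss, len(t), converged, n_used,
                     residuals=res.fun.copy(), flags=flags)


def compare_models(
    series,
    model_ids,
    n_restarts: int = N_RESTARTS_DEFAULT,
    seed: int = 0,
) -> list[GrowthFit]:
    """Fit several growth models and rank them by residual sum of squares.

    A small RSS indicates a good fit; the returned list is sorted
    ascending so the best-supported model comes first. Unconverged fits
    keep their flag and participate with their best attained RSS.
    """
    model_ids = list(model_ids)
    if len(model_ids) < 2:
        raise ValueError("model comparison needs at least 2 models")
    fits = [
        fit_growth_model(series, m, n_restarts=n_restarts, seed=seed)
        for m in model_ids
    ]
    return sorted(fits, key=lambda f: f.rss)


def _series_arrays(series):
    if hasattr(series, "times") and hasattr(series, "volumes"):
        t, v = series.times, series.volumes
    else:
        t, v = series
    t = np.asarray(t, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and volumes must be parallel 1D arrays")
    return t, v
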