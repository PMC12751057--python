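"""Global fitting of multi-trace stopped-flow data by numerical integration.

The objective is the total sum of squared residuals over all traces, with
per-trace additive baselines profiled out analytically and optional
1/sigma^2 weighting when traces carry different noise levels.  Rate
constants (and optional per-wavelength amplitude scales) are optimised in
log10 space by trust-region least squares with seeded multistarts, which
enforces positivity and tames the >5 orders of magnitude spanned by the
rate constants.

Confidence regions follow the SSR-ratio construction: a parameter pair is
pinned on a grid, all remaining free parameters are re-optimised at each
node, and the boundary is drawn where SSR/SSR_min crosses an F-distribution
quantile, so the threshold adapts to the number of data points and
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .eqfits import FitResult
from .observables import ObservableMap, Trace, default_observable_maps, project_trace
from .schemes import (
    IntegrationError,
    KineticScheme,
    RateConstantSet,
    simulate_timecourse,
)

__all__ = [
    "GlobalFitProblem",
    "ConfidenceRegion",
    "global_fit",
    "fitspace_contour",
    "contour_from_residual",
]

_LN10 = math.log(10.0)
#: rate-constant search bounds in natural units, applied in log10 space
_DEFAULT_BOUNDS = (1e-8, 1e8)
#: condition-number threshold beyond which a direction is called flat
_COND_LIMIT = 1e8
_RATE_NAMES = ("k1", "k2", "k3", "k5")


@dataclass(frozen=True)
class GlobalFitProblem:
    """Definition of one global fit.

    ``free`` names the optimised parameters: rate labels (k1, k2, k3, k5),
    "kd_app" in place of k2 under the (k1, KD) parameterisation, and
    optionally "amp_<wavelength>" multiplicative response-amplitude scales.
    ``init`` supplies starting values and the fixed values of any rate not
    freed.  Per-trace additive baselines are nuisance parameters profiled
    analytically whenever ``fit_offsets`` is true.
    """

    scheme: KineticScheme
    traces: tuple[Trace, ...]
    free: tuple[str, ...]
    init: RateConstantSet
    maps: Mapping[int, ObservableMap] | None = None
    fit_offsets: bool = True
    bounds: Mapping[str, tuple[float, float]] | None = None
    parameterisation: str = "rates"  # "rates" | "k1_kd"

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("problem must contain at least one trace")
        if self.parameterisation not in ("rates", "k1_kd"):
            raise ValueError("parameterisation must be 'rates' or 'k1_kd'")
        for name in self.free:
            if name in _RATE_NAMES or name == "kd_app" or name.startswith("amp_"):
                continue
            raise ValueError(f"unknown free parameter {name!r}")
        if self.parameterisation == "k1_kd" and "k2" in self.free:
            raise ValueError("under k1_kd parameterisation free k2 must be kd_app")

    def trace_map(self, trace: Trace) -> ObservableMap:
        maps = self.maps if self.maps is not None else default_observable_maps(
            trace.conditions.path_length
        )
        wl = int(trace.wavelength)
        if wl not in maps:
            raise KeyError(f"no observable map for wavelength {wl} nm")
        return maps[wl]

    def initial_values(self) -> dict[str, float]:
        vals: dict[str, float] = {}
        init = self.init.as_dict()
        for name in self.free:
            if name.startswith("amp_"):
                vals[name] = 1.0
            elif name == "kd_app":
                vals[name] = self.init.kd_app
            else:
                if name not in init:
                    raise ValueError(f"init provides no value for free rate {name}")
                vals[name] = init[name]
        return vals

    def param_bounds(self, name: str) -> tuple[float, float]:
        if self.bounds and name in self.bounds:
            return self.bounds[name]
        if name.startswith("amp_"):
            return (1e-3, 1e3)
        return _DEFAULT_BOUNDS


@dataclass(frozen=True)
class ConfidenceRegion:
    """SSR-ratio surface over a parameter-pair grid."""

    parameter_pair: tuple[str, str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    ssr_ratio: np.ndarray  # shape (len(grid_y), len(grid_x))
    threshold: float
    contained: np.ndarray
    valid: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        ratio = self.ssr_ratio[self.valid]
        if ratio.size and ratio.min() < 1.0 - 1e-9:
            raise ValueError("SSR ratio below 1 indicates the best fit was not optimal")


def _rates_from_values(problem: GlobalFitProblem, values: Mapping[str, float]) -> RateConstantSet:
    merged = problem.init.as_dict()
    for name, val in values.items():
        if name in _RATE_NAMES:
            merged[name] = val
    if "kd_app" in values:
        k1 = merged["k1"]
        merged["k2"] = values["kd_app"] * k1
    return RateConstantSet(**{k: merged.get(k) for k in ("k1", "k2", "k3", "k5")})


def _trace_weights(traces: Sequence[Trace]) -> list[float]:
    sigmas = [tr.noise_sigma for tr in traces]
    positive = [s for s in sigmas if s > 0]
    fallback = float(np.median(positive)) if positive else 1.0
    return [1.0 / (s if s > 0 else fallback) for s in sigmas]


def _make_residual_fn(problem: GlobalFitProblem):
    """Residual vector as a function of the free-parameter values (natural units)."""
    weights = _trace_weights(problem.traces)
    maps = [problem.trace_map(tr) for tr in problem.traces]

    def residual(values: Mapping[str, float]) -> np.ndarray:
        rates = _rates_from_values(problem, values)
        parts: list[np.ndarray] = []
        for trace, omap, w in zip(problem.traces, maps, weights):
            tc = simulate_timecourse(problem.scheme, rates, trace.conditions, trace.time)
            model = project_trace(tc, omap).signal
            amp_name = f"amp_{int(trace.wavelength)}"
            if amp_name in values:
                model = model * values[amp_name]
            diff = trace.signal - model
            if problem.fit_offsets:
                diff = diff - diff.mean()
            parts.append(w * diff)
        return np.concatenate(parts)

    return residual


def _pack(problem: GlobalFitProblem, names: Sequence[str], values: Mapping[str, float]) -> np.ndarray:
    return np.array([math.log10(values[n]) for n in names])


def _unpack(names: Sequence[str], x: np.ndarray) -> dict[str, float]:
    return {n: 10.0 ** xi for n, xi in zip(names, x)}


def _optimise(problem: GlobalFitProblem, residual, names, x0, seed, n_starts,
              **ls_kwargs):
    lo = np.array([math.log10(problem.param_bounds(n)[0]) for n in names])
    hi = np.array([math.log10(problem.param_bounds(n)[1]) for n in names])
    x0 = np.clip(x0, lo, hi)

    def fun(x: np.ndarray) -> np.ndarray:
        try:
            return residual(_unpack(names, x))
        except IntegrationError:
            return np.full(_n_obs_cache[0], 1e6)

    _n_obs_cache = [residual(_unpack(names, x0)).size]

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.clip(x0 + rng.uniform(-0.5, 0.5, size=x0.size), lo, hi))

    defaults = dict(method="trf", x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    defaults.update(ls_kwargs)
    best = None
    for start in starts:
        res = least_squares(fun, start, bounds=(lo, hi), **defaults)
        if best is None or res.cost < best.cost:
            best = res
    return best


def _count_params(problem: GlobalFitProblem) -> int:
    p = len(problem.free)
    if problem.fit_offsets:
        p += len(problem.traces)
    return p


def global_fit(
    problem: GlobalFitProblem,
    seed: int = 0,
    *,
    n_starts: int = 5,
    **ls_kwargs,
) -> FitResult:
    """Fit the free parameters of ``problem`` by total-SSR minimisation.

    Returns a FitResult whose estimates are in natural units (uM^-1 s^-1 /
    s^-1), with the derived KD_app = k2/k1, the profiled per-trace offsets,
    and any flat (unidentifiable) parameter directions recorded in the
    diagnostics.
    """
    residual = _make_residual_fn(problem)
    names = list(problem.free)
    if not names:
        raise ValueError("problem has no free parameters")
    x0 = _pack(problem, names, problem.initial_values())
    res = _optimise(problem, residual, names, x0, seed, n_starts, **ls_kwargs)

    values = _unpack(names, res.x)
    r = residual(values)
    ssr = float(np.dot(r, r))
    n = r.size
    p = _count_params(problem)
    dof = max(n - p, 1)
    s2 = ssr / dof

    # curvature in log space; map standard errors back via the chain rule
    jac = res.jac
    jtj = jac.T @ jac
    sv = np.linalg.svd(jac, compute_uv=False) if jac.size else np.array([0.0])
    flat: list[str] = []
    # a direction is flat when its curvature is negligible against either the
    # best-curved direction or the residual scale (a zero jacobian appears as
    # pure finite-difference noise, so an absolute floor is needed too)
    sv_floor = max(sv.max() / _COND_LIMIT, 1e-3 * math.sqrt(ssr / max(n, 1)))
    if sv.size and sv.min() <= sv_floor:
        _, _, vt = np.linalg.svd(jac)
        for i, s in enumerate(sv):
            if s <= sv_floor:
                for j, name in enumerate(names):
                    if abs(vt[i, j]) > 0.3 and name not in flat:
                        flat.append(name)
    stderr: dict[str, float] = {}
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        for i, name in enumerate(names):
            var = cov_log[i, i]
            if var < 0 or not np.isfinite(var):
                stderr[name] = float("nan")
            else:
                stderr[name] = math.sqrt(var) * _LN10 * values[name]
    except np.linalg.LinAlgError:
        stderr = {name: float("nan") for name in names}
    # enormous relative errors flag flatness even when the jacobian is not
    # rank-deficient in the numerical sense
    for name in names:
        err_log = stderr.get(name, float("nan"))
        if name not in flat and (
            not np.isfinite(err_log) or err_log > 10.0 * abs(values[name])
        ):
            flat.append(name)

    rates = _rates_from_values(problem, values)
    diagnostics = {
        "message": f"least_squares status {res.status}",
        "unidentifiable": flat,
        "n_starts": n_starts,
        "rates": rates.as_dict(),
        "dof": dof,
    }
    if rates.k1 > 0:
        diagnostics["kd_app"] = rates.kd_app
    converged = bool(res.status > 0)
    return FitResult(
        model_id=f"global:{problem.scheme.variant.value}",
        estimates=values,
        standard_errors=stderr,
        ssr=ssr,
        n_points=n,
        converged=converged,
        residuals=r,
        diagnostics=diagnostics,
    )


def ssr_ratio_threshold(confidence: float, n_obs: int, n_params: int) -> float:
    """F-quantile SSR-ratio boundary for a two-parameter confidence region."""
    dof = n_obs - n_params
    if dof <= 0:
        raise ValueError("more parameters than observations")
    return 1.0 + 2.0 / dof * float(f_dist.ppf(confidence, 2, dof))


def contour_from_residual(
    residual_fn,
    x_best: np.ndarray,
    pair_idx: tuple[int, int],
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    *,
    confidence: float,
    n_obs: int,
    n_params: int,
    pair_names: tuple[str, str] = ("p0", "p1"),
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConfidenceRegion:
    """Generic SSR-ratio contour engine over a fixed parameter pair.

    ``residual_fn`` maps a full parameter vector (in whatever engine space
    the caller uses) to a residual vector; ``x_best`` is the converged
    optimum.  At every grid node the pair coordinates are pinned and the
    remaining coordinates re-optimised starting from the optimum.  Failed
    re-optimisations are marked invalid, never interpolated.
    """
    x_best = np.asarray(x_best, float)
    i, j = pair_idx
    rest = [k for k in range(x_best.size) if k not in (i, j)]
    r0 = residual_fn(x_best)
    ssr_min = float(np.dot(r0, r0))
    if ssr_min <= 0:
        raise ValueError("SSR at the optimum is zero; ratios are undefined")
    threshold = ssr_ratio_threshold(confidence, n_obs, n_params)

    ratio = np.full((grid_y.size, grid_x.size), np.nan)
    valid = np.zeros_like(ratio, dtype=bool)
    for a, gy in enumerate(grid_y):
        for b, gx in enumerate(grid_x):
            x = x_best.copy()
            x[i], x[j] = gx, gy
            try:
                if rest:
                    def sub(xr):
                        xx = x.copy()
                        xx[rest] = xr
                        return residual_fn(xx)
                    if bounds is not None:
                        sub_bounds = (bounds[0][rest], bounds[1][rest])
                        res = least_squares(
                            sub, np.clip(x_best[rest], *sub_bounds),
                            bounds=sub_bounds, method="trf", xtol=1e-12, ftol=1e-12,
                        )
                    else:
                        res = least_squares(sub, x_best[rest], method="lm" if len(rest) <= r0.size else "trf")
                    ssr = 2.0 * float(res.cost)
                else:
                    r = residual_fn(x)
                    ssr = float(np.dot(r, r))
            except (IntegrationError, ValueError):
                continue
            ratio[a, b] = ssr / ssr_min
            valid[a, b] = True
    # numerical re-optimisation can land a hair below the global SSR_min
    ratio[valid & (ratio < 1.0)] = 1.0
    contained = valid & (ratio <= threshold)
    return ConfidenceRegion(
        parameter_pair=pair_names,
        grid_x=np.asarray(grid_x, float),
        grid_y=np.asarray(grid_y, float),
        ssr_ratio=ratio,
        threshold=threshold,
        contained=contained,
        valid=valid,
        confidence=confidence,
    )


def fitspace_contour(
    problem: GlobalFitProblem,
    best_fit: FitResult,
    pair: tuple[str, str],
    grid_spec: Mapping[str, object],
    confidence: float = 0.95,
) -> ConfidenceRegion:
    """SSR-ratio confidence contour for a pair of free parameters.

    ``grid_spec`` maps each pair member to either an explicit array of
    natural-unit values or a (lo, hi, n) triple expanded geometrically.
    """
    best_fit.require_converged()
    name_x, name_y = pair
    for name in pair:
        if name not in problem.free:
            raise ValueError(f"{name!r} is not a free parameter of the problem")

    def expand(spec) -> np.ndarray:
        if isinstance(spec, (tuple, list)) and len(spec) == 3 and np.isscalar(spec[0]):
            lo, hi, n = spec
            return np.geomspace(float(lo), float(hi), int(n))
        return np.asarray(spec, dtype=float)

    grid_x = expand(grid_spec[name_x])
    grid_y = expand(grid_spec[name_y])

    residual = _make_residual_fn(problem)
    names = list(problem.free)

    def residual_log(xlog: np.ndarray) -> np.ndarray:
        return residual(_unpack(names, xlog))

    x_best = _pack(problem, names, best_fit.estimates)
    lo = np.array([math.log10(problem.param_bounds(n)[0]) for n in names])
    hi = np.array([math.log10(problem.param_bounds(n)[1]) for n in names])
    region = contour_from_residual(
        residual_log,
        x_best,
        (names.index(name_x), names.index(name_y)),
        np.log10(grid_x),
        np.log10(grid_y),
        confidence=confidence,
        n_obs=best_fit.n_points,
        n_params=_count_params(problem),
        pair_names=pair,
        bounds=(lo, hi),
    )
    # report grids in natural units
    return ConfidenceRegion(
        parameter_pair=region.parameter_pair,
        grid_x=grid_x,
        grid_y=grid_y,
        ssr_ratio=region.ssr_ratio,
        threshold=region.threshold,
        contained=region.contained,
        valid=region.valid,
        confidence=confidence,
    )
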