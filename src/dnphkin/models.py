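"""Registry of the analytic rate / signal equations used across the package.

Each model couples a vectorised function ``f(x, **params)`` with parameter
metadata and a data-driven initial-guess heuristic, so that the synthetic
generator and the fitting layer share one definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = ["ModelSpec", "MODELS", "get_model"]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    func: Callable[..., np.ndarray]
    param_names: tuple[str, ...]
    #: parameters constrained strictly positive during fitting
    positive: tuple[str, ...]
    #: names of fixed (non-fitted) inputs the function requires
    fixed_inputs: tuple[str, ...]
    guess: Callable[[np.ndarray, np.ndarray, Mapping[str, float]], dict]
    #: validator for the predictor domain; raises ValueError on violation
    check_domain: Callable[[np.ndarray], None]

    def __call__(self, x, **kwargs) -> np.ndarray:
        return self.func(np.asarray(x, dtype=float), **kwargs)


def _nonneg(name: str):
    def check(x: np.ndarray) -> None:
        if np.any(x < 0):
            raise ValueError(f"{name} must be non-negative")
    return check


def _any_real(x: np.ndarray) -> None:
    if np.any(~np.isfinite(x)):
        raise ValueError("predictor values must be finite")


# --- steady-state rate laws -------------------------------------------------

def _michaelis_menten(s, kcat, km):
    """v/ET for a saturable substrate dependence (pseudo-first-order enzyme)."""
    return kcat * s / (km + s)


def _guess_saturation(x, y, fixed):
    vmax = float(np.max(y)) if np.max(y) > 0 else 1.0
    half = vmax / 2.0
    order = np.argsort(x)
    km = float(np.interp(half, np.asarray(y)[order], np.asarray(x)[order]))
    if not np.isfinite(km) or km <= 0:
        km = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    return {"kcat": vmax, "km": km}


def _tight_binding(s, kcat, km, et):
    """v/ET when enzyme is not negligible next to substrate (quadratic form)."""
    b = et + s + km
    disc = np.sqrt(np.maximum(b * b - 4.0 * et * s, 0.0))
    return kcat * (b - disc) / (2.0 * et)


def _guess_tight(x, y, fixed):
    g = _guess_saturation(x, y, fixed)
    return g


def _competitive_inhibition(s, kcat, ki, i, km):
    """v/ET with a competitive inhibitor at fixed concentration i.

    A single saturation curve at one inhibitor concentration only determines
    the apparent KM(1 + i/Ki), so the uninhibited Michaelis constant km is a
    fixed input and Ki is extracted from the apparent shift.
    """
    return kcat * s / (km * (1.0 + i / ki) + s)


def _guess_competitive(x, y, fixed):
    g = _guess_saturation(x, y, fixed)
    km = float(fixed.get("km", 1.0))
    i = float(fixed.get("i", 1.0))
    km_app = max(g.pop("km"), km * (1 + 1e-6))
    return {"kcat": g["kcat"], "ki": i / (km_app / km - 1.0)}


def _hill_ic50(i, ic50, h):
    """Fractional activity vi/v0 against inhibitor concentration."""
    return 1.0 / (1.0 + (i / ic50) ** h)


def _guess_hill(x, y, fixed):
    idx = int(np.argmin(np.abs(np.asarray(y) - 0.5)))
    ic50 = float(x[idx]) if x[idx] > 0 else float(np.median(x[x > 0]))
    return {"ic50": max(ic50, 1e-12), "h": 1.0}


def _linear_specificity(s, kcat_over_km):
    """v/ET = (kcat/KM) * S, valid only at S << KM."""
    return kcat_over_km * s


def _guess_linear(x, y, fixed):
    denom = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / denom if denom > 0 else 1.0
    return {"kcat_over_km": slope}


# --- pre-steady-state burst -------------------------------------------------

def _burst(t, a0, kburst, v, c):
    """Exponential burst followed by a linear steady-state phase.

    A constant baseline c is carried because projected traces include the
    time-invariant chromophore contribution of unreacted substrate.
    """
    return a0 * np.exp(-kburst * t) + v * t + c


def _guess_burst(t, y, fixed):
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    tail = slice(max(n - max(n // 4, 2), 0), n)
    v, intercept = np.polyfit(t[tail], y[tail], 1)
    a0 = float(y[0] - intercept)
    resid = y - (v * t + intercept)
    kburst = None
    if abs(a0) > 0:
        mask = np.sign(resid) == np.sign(a0)
        mask &= np.abs(resid) > 0.05 * abs(a0)
        if mask.sum() >= 3:
            slope = np.polyfit(t[mask], np.log(np.abs(resid[mask])), 1)[0]
            if slope < 0:
                kburst = -float(slope)
    if kburst is None or not np.isfinite(kburst):
        kburst = 1.0 / max(float(t[n // 2]), 1e-6)
    return {"a0": a0, "kburst": kburst, "v": float(v), "c": float(intercept)}


# --- linear free energy and calibrations ------------------------------------

def _bronsted(pka, beta_lg, log_c):
    """log10(kcat/KM) against leaving-group pKa."""
    return beta_lg * pka + log_c


def _guess_bronsted(x, y, fixed):
    slope, intercept = np.polyfit(x, y, 1)
    return {"beta_lg": float(slope), "log_c": float(intercept)}


def _pka_sigmoid(ph, pka, a_acid, a_base):
    """Single-pKa absorbance titration."""
    return a_acid + (a_base - a_acid) / (1.0 + 10.0 ** (pka - ph))


def _guess_pka(ph, a, fixed):
    order = np.argsort(ph)
    ph_s, a_s = np.asarray(ph)[order], np.asarray(a)[order]
    a_acid, a_base = float(a_s[0]), float(a_s[-1])
    mid = (a_acid + a_base) / 2.0
    pka = float(np.interp(mid, a_s, ph_s)) if a_base != a_acid else float(np.median(ph_s))
    return {"pka": pka, "a_acid": a_acid, "a_base": a_base}


def _standard_curve(conc, extinction, intercept, path_length):
    """Beer-Lambert standard curve; conc in M, extinction in M^-1 cm^-1."""
    return extinction * path_length * conc + intercept


def _guess_standard(x, y, fixed):
    slope, intercept = np.polyfit(x, y, 1)
    path = float(fixed.get("path_length", 1.0))
    return {"extinction": float(slope) / path, "intercept": float(intercept)}


MODELS: dict[str, ModelSpec] = {
    "michaelis_menten": ModelSpec(
        "michaelis_menten", _michaelis_menten, ("kcat", "km"), ("kcat", "km"),
        (), _guess_saturation, _nonneg("substrate concentration"),
    ),
    "burst": ModelSpec(
        "burst", _burst, ("a0", "kburst", "v", "c"), ("kburst",),
        (), _guess_burst, _nonneg("time"),
    ),
    "tight_binding": ModelSpec(
        "tight_binding", _tight_binding, ("kcat", "km"), ("kcat", "km"),
        ("et",), _guess_tight, _nonneg("substrate concentration"),
    ),
    "competitive_inhibition": ModelSpec(
        "competitive_inhibition", _competitive_inhibition,
        ("kcat", "ki"), ("kcat", "ki"),
        ("i", "km"), _guess_competitive, _nonneg("substrate concentration"),
    ),
    "hill_ic50": ModelSpec(
        "hill_ic50", _hill_ic50, ("ic50", "h"), ("ic50", "h"),
        (), _guess_hill, _nonneg("inhibitor concentration"),
    ),
    "linear_specificity": ModelSpec(
        "linear_specificity", _linear_specificity, ("kcat_over_km",),
        ("kcat_over_km",), (), _guess_linear, _nonneg("substrate concentration"),
    ),
    "bronsted": ModelSpec(
        "bronsted", _bronsted, ("beta_lg", "log_c"), (),
        (), _guess_bronsted, _any_real,
    ),
    "pka_sigmoid": ModelSpec(
        "pka_sigmoid", _pka_sigmoid, ("pka", "a_acid", "a_base"), (),
        (), _guess_pka, _any_real,
    ),
    "standard_curve": ModelSpec(
        "standard_curve", _standard_curve, ("extinction", "intercept"), (),
        ("path_length",), _guess_standard, _nonneg("concentration"),
    ),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        valid = ", ".join(sorted(MODELS))
        raise ValueError(f"unknown model_id {model_id!r}; expected one of: {valid}") from None
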